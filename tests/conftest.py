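"""Shared fixtures.

The two speed sweeps are the expensive shared inputs of the replication
tests: session-scoped so the gait-physics, dog, and *Batrachotomus* tests
reuse the same solved trajectories.
"""

import pytest


@pytest.fixture(scope="session")
def dog_sweep():
    """Dog gait atlas at c' = 3e-3 across walking-to-trotting speeds."""
    from paleogait.fixtures import DOG
    from paleogait.postprocess import sweep

    results = []
    atlas, transitions = sweep(
        DOG, [0.4, 0.6, 0.7, 0.8, 0.9, 1.2], c_prime=3e-3, seed=10,
        mesh_intervals=16, multistarts=4, modulation_window=(0.0, 0.6),
        results_out=results)
    return atlas, transitions, results


@pytest.fixture(scope="session")
def batra_sweep():
    """Batrachotomus gait atlas at c' = 3e-3 from slow walk to fast run."""
    from paleogait.fixtures import BATRACHOTOMUS
    from paleogait.postprocess import sweep

    results = []
    atlas, transitions = sweep(
        BATRACHOTOMUS, [0.25, 0.35, 0.5, 0.9, 1.1], c_prime=3e-3, seed=20,
        mesh_intervals=16, multistarts=4, modulation_window=(0.4, 1.0),
        results_out=results)
    return atlas, transitions, results
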