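"""Synthetic trackway generation with known ground truth.

Lays down the footprint pattern of a steady, symmetric quadrupedal gait:
pes midpoints at multiples of the stride length ``D`` on each side (right
side offset by ``D/2`` along travel), and each manus placed a distance

    d = mod(phi_L + LBx/D, 1) * D

cranial to its pes, which is the print geometry implied by a limb phase
``phi_L`` and horizontal glenoacetabular distance ``LBx``.  Prints are
straight two-landmark segments aligned with travel (the analysis uses only
tip/caudal/midpoint geometry), optionally rotated for the manus, then
jittered with isotropic Gaussian landmark noise.  Ground truth is returned
alongside so recovery can be tested exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .fixtures import body_models, trackway_table
from .trackways import Footprint, Trackway

__all__ = ["SyntheticTrackwaySpec", "make_trackway", "fixtures"]


@dataclass(frozen=True)
class SyntheticTrackwaySpec:
    """Parameters of a synthetic symmetric-gait trackway.

    Defaults emulate a moderate chirotheriid walking trackway: stride and
    print sizes in the mid-range of the published trackways, and 1 cm
    landmark noise, a typical digitization uncertainty for photographs of
    decimetre-scale prints.
    """

    phi_L: float = 0.5          # ipsilateral limb phase, fraction of stride
    D: float = 1.2              # stride length, m
    LBx: float = 0.74           # horizontal glenoacetabular distance, m
    n_strides: int = 8          # same-side stride count
    trackway_width: float = 0.3  # lateral distance between left/right pes lines, m
    pes_len: float = 0.26       # pes print length, m
    manus_len: float = 0.10     # manus print length, m
    landmark_noise_sd: float = 0.01  # isotropic landmark jitter SD, m
    missing_print_rate: float = 0.0  # per-print dropout probability
    manus_rotation: float = 0.0      # in-plane manus rotation, rad
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.D > 0:
            raise ValueError("stride length D must be > 0")
        if not 0 <= self.phi_L < 1:
            raise ValueError("phi_L must lie in [0, 1)")
        if self.landmark_noise_sd < 0:
            raise ValueError("landmark noise SD must be >= 0")
        if not 0 <= self.missing_print_rate < 1:
            raise ValueError("missing print rate must lie in [0, 1)")


def make_trackway(spec: SyntheticTrackwaySpec) -> tuple[Trackway, dict]:
    """Generate a synthetic trackway and its ground-truth record."""
    rng = np.random.default_rng(spec.seed)
    d = ((spec.phi_L + spec.LBx / spec.D) % 1.0) * spec.D
    phi_T = d / spec.D

    half_w = spec.trackway_width / 2.0
    sets: list[tuple[float, str, str, float]] = []  # (x_mid, limb, side, y)
    for k in range(spec.n_strides + 1):
        for side, x0, y in (("left", 0.0, half_w), ("right", -spec.D / 2.0, -half_w)):
            x_pes = x0 + k * spec.D
            sets.append((x_pes, "pes", side, y))
            sets.append((x_pes + d, "manus", side, y))

    overlap = d < (spec.pes_len + spec.manus_len) / 2.0
    notes = "manus overlaps its pes print" if overlap else ""

    prints: list[Footprint] = []
    next_id = 1
    for x_mid, limb, side, y in sorted(sets, key=lambda s: (s[0], s[1] == "manus")):
        if rng.random() < spec.missing_print_rate:
            continue
        length = spec.pes_len if limb == "pes" else spec.manus_len
        axis = np.array([1.0, 0.0])
        if limb == "manus" and spec.manus_rotation != 0.0:
            c, s = math.cos(spec.manus_rotation), math.sin(spec.manus_rotation)
            axis = np.array([c, s])
        mid = np.array([x_mid, y])
        tip = mid + 0.5 * length * axis
        caudal = mid - 0.5 * length * axis
        if spec.landmark_noise_sd > 0:
            tip = tip + rng.normal(0.0, spec.landmark_noise_sd, size=2)
            caudal = caudal + rng.normal(0.0, spec.landmark_noise_sd, size=2)
        prints.append(
            Footprint(print_id=next_id, limb=limb, side=side, tip=tip,
                      caudal=caudal, notes=notes if limb == "manus" else "")
        )
        next_id += 1

    truth = {
        "spec": asdict(spec),
        "d": d,
        "track_phase": phi_T,
        "stride": spec.D,
        "pes_length": spec.pes_len,
        "manus_length": spec.manus_len,
        "manus_pes_overlap": overlap,
    }
    return Trackway(name=f"synthetic-{spec.seed}", prints=prints), truth


def fixtures():
    """Shipped reference data: body models and the trackway summary table."""
    return body_models(), trackway_table()
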