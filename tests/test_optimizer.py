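import math

import numpy as np
import pandas as pd
import pytest

from paleogait.bodies import G
from paleogait.collocation import HalfCycleProblem
from paleogait.fixtures import BATRACHOTOMUS, DOG
from paleogait.optimize import (
    GaitTask,
    build_problem,
    constrain_track_phase,
    dimensionalize,
    initial_guess,
    interpolate_decision,
    nondimensional_body,
    stride_from_speed,
)
from paleogait.postprocess import (
    Transition,
    classify_grf_profile,
    detect_transitions,
    modulate_limb_phase,
    trackway_phase_trend,
)


class TestTaskSetup:
    def test_dimensionalize_reference_speed(self):
        task = GaitTask(body=BATRACHOTOMUS, U_H=0.4)
        U, D, T, c = dimensionalize(task)
        assert U == pytest.approx(0.4 * math.sqrt(G * 0.76), rel=1e-12)
        assert U == pytest.approx(1.092, abs=2e-3)
        assert T == pytest.approx(D / U)
        assert c > 0

    def test_default_stride_follows_speed_relation(self):
        task = GaitTask(body=DOG, U_H=0.4)
        assert task.D_H == pytest.approx((0.4 / 0.25) ** (1 / 1.67))
        assert task.D_H == pytest.approx(1.325, abs=2e-3)

    def test_speed_scales_with_sqrt_hip_height(self):
        import dataclasses
        tall = dataclasses.replace(DOG, LH=2 * DOG.LH, LB=2 * DOG.LB,
                                   LF=2 * DOG.LF, name="tall")
        U1, _, _, _ = dimensionalize(GaitTask(body=DOG, U_H=0.4))
        U2, _, _, _ = dimensionalize(GaitTask(body=tall, U_H=0.4))
        assert U2 == pytest.approx(math.sqrt(2) * U1)

    def test_penalty_scaling_is_period_invariant(self):
        # the same c' at different speeds maps to the same dimensional c
        c1 = dimensionalize(GaitTask(body=DOG, U_H=0.4, c_prime=3e-3))[3]
        c2 = dimensionalize(GaitTask(body=DOG, U_H=1.0, c_prime=3e-3))[3]
        assert c1 == pytest.approx(c2)

    def test_invalid_tasks_rejected(self):
        with pytest.raises(ValueError):
            GaitTask(body=DOG, U_H=-0.1)
        with pytest.raises(ValueError):
            GaitTask(body=DOG, U_H=0.4, mesh_intervals=5)
        with pytest.raises(ValueError):
            GaitTask(body=DOG, U_H=0.4, track_phase_target=1.2)

    def test_constrain_track_phase_wraps_target(self):
        task = GaitTask(body=DOG, U_H=0.4)
        assert constrain_track_phase(task, 0.3).track_phase_target == 0.3
        assert task.track_phase_target is None  # original untouched

    def test_nondimensional_body_scales(self):
        nd = nondimensional_body(BATRACHOTOMUS)
        assert nd.LH == 1.0 and nd.M == 1.0
        assert nd.I == pytest.approx(69.0 / (142.0 * 0.76**2))


@pytest.fixture(scope="module")
def problem_and_point():
    task = GaitTask(body=DOG, U_H=0.5, mesh_intervals=10)
    prob = build_problem(task)
    rng = np.random.default_rng(3)
    X = initial_guess(prob, rng, phi_L=0.25)
    X = X + rng.normal(0.0, 0.01, X.shape)
    lb, ub = prob.bounds()
    return prob, np.clip(X, lb + 1e-3, ub - 1e-3)


class TestTranscriptionDerivatives:
    """The analytic gradient and sparse Jacobians must agree with central
    finite differences at a generic (perturbed, infeasible) point."""

    def test_objective_gradient(self, problem_and_point):
        prob, X = problem_and_point
        g = prob.gradient(X)
        rng = np.random.default_rng(0)
        for i in rng.choice(len(X), 30, replace=False):
            Xp, Xm = X.copy(), X.copy()
            Xp[i] += 1e-6
            Xm[i] -= 1e-6
            fd = (prob.objective(Xp) - prob.objective(Xm)) / 2e-6
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-7)

    def test_defect_jacobian(self, problem_and_point):
        prob, X = problem_and_point
        J = prob.defects_jac(X).toarray()
        rng = np.random.default_rng(1)
        for i in rng.choice(len(X), 25, replace=False):
            Xp, Xm = X.copy(), X.copy()
            Xp[i] += 1e-6
            Xm[i] -= 1e-6
            fd = (prob.defects(Xp) - prob.defects(Xm)) / 2e-6
            assert np.abs(fd - J[:, i]).max() < 1e-7

    def test_path_jacobian(self, problem_and_point):
        prob, X = problem_and_point
        J = prob.path_jac(X).toarray()
        rng = np.random.default_rng(2)
        cols = list(rng.choice(len(X), 25, replace=False))
        cols += list(range(prob.K * 14, prob.n_vars))  # footfall columns
        for i in cols:
            Xp, Xm = X.copy(), X.copy()
            Xp[i] += 1e-6
            Xm[i] -= 1e-6
            fd = (prob.path(Xp) - prob.path(Xm)) / 2e-6
            assert np.abs(fd - J[:, i]).max() < 1e-7


class TestGuesses:
    def test_guess_within_bounds_and_supports_weight(self):
        prob = build_problem(GaitTask(body=BATRACHOTOMUS, U_H=0.5,
                                      mesh_intervals=12))
        rng = np.random.default_rng(5)
        for phi in (None, 0.25, 0.5):
            X = initial_guess(prob, rng, phi_L=phi)
            lb, ub = prob.bounds()
            assert (X >= lb).all() and (X <= ub).all()
            Q, _, p = prob.split(X)
            mean_force = Q[:, 6:10].sum(axis=1).mean()
            assert 0.4 < mean_force < 2.5  # order of one body weight
            # footfall branch relation holds exactly
            s0, s2 = HalfCycleProblem.guess_branches(Q)
            assert p[0] - p[1] == pytest.approx(s0 * prob.D / 2)
            assert p[2] - p[3] == pytest.approx(s2 * prob.D / 2)

    def test_guess_streams_are_reproducible(self):
        prob = build_problem(GaitTask(body=DOG, U_H=0.5, mesh_intervals=12))
        X1 = initial_guess(prob, np.random.default_rng(42))
        X2 = initial_guess(prob, np.random.default_rng(42))
        assert np.array_equal(X1, X2)

    def test_mesh_interpolation_preserves_endpoints(self):
        t1 = GaitTask(body=DOG, U_H=0.5, mesh_intervals=12)
        t2 = GaitTask(body=DOG, U_H=0.5, mesh_intervals=24)
        p1, p2 = build_problem(t1), build_problem(t2)
        X = initial_guess(p1, np.random.default_rng(0), phi_L=0.5)
        Xi = interpolate_decision(X, p1, p2)
        Q1, _, pf1 = p1.split(X)
        Q2, _, pf2 = p2.split(Xi)
        assert Q2[0] == pytest.approx(Q1[0])
        assert Q2[-1] == pytest.approx(Q1[-1])
        assert pf2 == pytest.approx(pf1)


class TestGRFClassification:
    def test_double_humped(self):
        t = np.linspace(0.0, 1.0, 201)
        F = np.sin(2 * np.pi * t) ** 2
        assert classify_grf_profile(t, F).label == "double-humped"

    def test_single_humped_symmetric(self):
        t = np.linspace(0.0, 1.0, 201)
        cls = classify_grf_profile(t, np.sin(np.pi * t))
        assert cls.label == "single-humped"
        assert cls.skew == pytest.approx(0.0, abs=0.01)

    def test_single_humped_with_positive_skew(self):
        t = np.linspace(0.0, 1.0, 401)
        F = np.sin(np.pi * t) * (1 + t)
        cls = classify_grf_profile(t, F)
        assert cls.n_peaks == 1
        # peak of sin(pi t)(1+t) sits at t ~ 0.566 (by direct maximization)
        assert cls.skew == pytest.approx(0.066, abs=0.01)
        assert cls.skew > 0

    def test_strong_skew_classified_as_skewed(self):
        t = np.linspace(0.0, 1.0, 401)
        F = np.maximum(0.0, np.sin(np.pi * t**3))
        cls = classify_grf_profile(t, F)
        assert cls.label == "skewed"

    def test_no_contact(self):
        t = np.linspace(0.0, 1.0, 50)
        assert classify_grf_profile(t, np.zeros_like(t)).label == "no-contact"


class TestPhaseBookkeeping:
    def test_modulation_window_selects_candidate(self):
        assert modulate_limb_phase(0.75, (0.0, 0.6)) == pytest.approx(0.25)
        assert modulate_limb_phase(0.25, (0.4, 1.0)) == pytest.approx(0.75)
        assert modulate_limb_phase(0.5, (0.4, 1.0)) == pytest.approx(0.5)

    def test_ambiguous_candidates_resolve_to_window_centre(self):
        # both 0.05 and 0.55 lie in (0, 0.6); nearest the centre wins
        assert modulate_limb_phase(0.05, (0.0, 0.6)) == pytest.approx(0.05)

    def test_transition_detection(self):
        atlas = pd.DataFrame(dict(
            U_H=[0.4, 0.5, 0.6, 0.7],
            phi_L=[0.5, 0.51, 0.74, 0.75],
            grf_hind=["double-humped"] * 2 + ["single-humped"] * 2,
            grf_fore=["double-humped"] * 2 + ["single-humped"] * 2,
        ))
        trans = detect_transitions(atlas)
        assert len(trans) == 1
        assert trans[0].lower_speed == 0.5 and trans[0].upper_speed == 0.6
        assert trans[0].speed == pytest.approx(0.55)

    def test_limb_phase_jump_mod_half(self):
        # 0.49 -> 0.51 is small; 0.49 -> 0.74 is a jump even modulo 0.5
        atlas = pd.DataFrame(dict(U_H=[0.4, 0.5], phi_L=[0.49, 0.51],
                                  grf_hind=["a", "a"], grf_fore=["b", "b"]))
        assert detect_transitions(atlas) == []

    def test_trackway_trend_interpolates_published_points(self):
        trend = trackway_phase_trend()
        assert trend(0.60) == pytest.approx(0.14, abs=0.03)
        assert trend(1.92) == pytest.approx(0.11, abs=1e-9)
        assert 0.0 <= trend(0.31) < 1.0


def test_transition_midpoint_property():
    tr = Transition(0.6, 0.9, "test")
    assert tr.speed == pytest.approx(0.75)
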