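"""Gait descriptors derived from optimized trajectories.

The half-cycle solution is unfolded to a full stride using the left/right
symmetry (each limb's second half-cycle equals its mirror limb's first),
and contact timing, limb phase, duty factors, track phase, ground-reaction
force shape classes and cost of transport are extracted.  Speed sweeps
aggregate these into a gait atlas with transition detection.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .bodies import G, BodyModel, hip_height, horizontal_gad
from .dynamics import LIMB_NAMES, MIRROR
from .fixtures import trackway_table


def _circ_dist(a: float, b: float) -> float:
    """Distance on the unit circle of phases."""
    d = abs(a - b) % 1.0
    return min(d, 1.0 - d)

#: contact detection threshold as a fraction of body weight; relaxed
#: complementarity leaves tiny nonzero forces outside stance
F_THRESHOLD_FRAC = 1e-3
#: additional per-limb threshold as a fraction of that limb's peak force;
#: with the complementarity relaxation, swing-phase residual forces scale
#: with the relaxation, not with body weight, so a relative floor is needed
REL_THRESHOLD_FRAC = 0.05


@dataclass(frozen=True)
class GRFClass:
    """Shape classification of one limb's ground-reaction force profile."""

    n_peaks: int
    skew: float
    label: str  # "double-humped" | "single-humped" | "skewed" | "no-contact"


def classify_grf_profile(
    t: np.ndarray,
    F: np.ndarray,
    skew_threshold: float = 0.1,
    prominence_frac: float = 0.05,
) -> GRFClass:
    """Classify a single contact's force profile.

    ``t``/``F`` sample one contact period (force ~0 at both ends).  Two or
    more interior local maxima give the double-humped "vaulting" class; one
    maximum is "single-humped" ("bouncing") unless the peak sits more than
    ``skew_threshold`` of the contact duration away from midstance, in
    which case the profile is "skewed".
    """
    t = np.asarray(t, dtype=float)
    F = np.asarray(F, dtype=float)
    if F.max() <= 0:
        return GRFClass(0, 0.0, "no-contact")
    peaks, _ = find_peaks(F, prominence=prominence_frac * F.max())
    n = int(len(peaks))
    duration = t[-1] - t[0]
    t_mid = t[0] + duration / 2.0
    if n >= 2:
        return GRFClass(n, 0.0, "double-humped")
    t_peak = t[peaks[0]] if n == 1 else t[np.argmax(F)]
    skew = float((t_peak - t_mid) / duration) if duration > 0 else 0.0
    label = "skewed" if abs(skew) > skew_threshold else "single-humped"
    return GRFClass(max(n, 1), skew, label)


@dataclass
class GaitSummary:
    """Derived gait descriptors for one optimized solution."""

    limb_phase: float                 # modulated into the window
    limb_phase_raw: float             # raw onset difference / T, in [0, 1)
    duty_factors: dict[str, float]
    track_phase: float
    cot: float                        # J / (M g D), work + penalty
    cot_work_only: float
    grf_classes: dict[str, GRFClass]
    gait_label: str
    modulation_window: tuple[float, float]
    double_contact: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for nm, df in self.duty_factors.items():
            if not 0.0 <= df <= 1.0:
                raise ValueError(f"duty factor of {nm} outside [0, 1]")
        if not 0.0 <= self.track_phase < 1.0:
            raise ValueError("track phase must lie in [0, 1)")


def full_cycle_forces(sol) -> tuple[np.ndarray, np.ndarray]:
    """Unfold half-cycle limb forces to one full stride.

    Returns ``(t_full, F_full)`` with ``F_full`` of shape ``(2(K-1), 4)``;
    sample ``K-1`` onward holds each limb's mirror-limb forces.
    """
    t, F = sol.t, sol.F
    Th = sol.T / 2.0
    t_full = np.concatenate([t[:-1], t[:-1] + Th])
    F_full = np.concatenate([F[:-1, :], F[:-1, MIRROR]], axis=0)
    return t_full, F_full


def _contact_mask(F: np.ndarray, threshold: float) -> np.ndarray:
    return F > threshold


def _onset_time(t: np.ndarray, F: np.ndarray, threshold: float, T: float) -> Optional[float]:
    """First rising crossing of the threshold in the periodic signal."""
    mask = _contact_mask(F, threshold)
    if mask.all() or not mask.any():
        return None
    n = len(t)
    for j in range(n):
        prev = (j - 1) % n
        if mask[j] and not mask[prev]:
            f0, f1 = F[prev], F[j]
            t0 = t[prev] if prev < j else t[prev] - T
            frac = (threshold - f0) / (f1 - f0) if f1 != f0 else 1.0
            return float((t0 + frac * (t[j] - t0)) % T)
    return None


def _duty_factor(t: np.ndarray, F: np.ndarray, threshold: float, T: float) -> float:
    """Fraction of the stride above threshold (periodic trapezoid count)."""
    mask = _contact_mask(F, threshold).astype(float)
    # treat samples as uniform: crossing refinement matters little at the
    # mesh sizes used and keeps the measure monotone in the threshold
    return float(np.clip(mask.mean(), 0.0, 1.0))


def modulate_limb_phase(
    phi_raw: float, window: tuple[float, float]
) -> float:
    """Resolve the planar left/right ambiguity of the limb phase.

    A planar model cannot distinguish lateral- from diagonal-sequence
    gaits, so the limb phase is determined modulo 0.5; the representative
    inside the configured window is reported (ties resolved toward the
    window centre).
    """
    lo, hi = window
    c0 = phi_raw % 0.5
    candidates = [c0, c0 + 0.5]
    inside = [c for c in candidates if lo < c < hi]
    if len(inside) == 1:
        return inside[0]
    centre = 0.5 * (lo + hi)
    pool = inside if inside else candidates
    return min(pool, key=lambda c: abs(c - centre))


def _rotate_contact(t_full, F, threshold, T):
    """Time/force samples of one contact, unwrapped to be contiguous."""
    mask = _contact_mask(F, threshold)
    if not mask.any():
        return None
    if mask.all():
        return t_full, F
    n = len(mask)
    # find a swing sample, rotate so the contact is contiguous
    start = int(np.argmin(mask))
    idx = (np.arange(n) + start) % n
    tt = t_full[idx] + np.where(np.arange(n) + start >= n, T, 0.0)
    FF = F[idx]
    sel = _contact_mask(FF, threshold)
    first, last = np.argmax(sel), n - 1 - np.argmax(sel[::-1])
    lo = max(first - 1, 0)
    hi = min(last + 1, n - 1)
    return tt[lo:hi + 1], FF[lo:hi + 1]


def _count_contacts(mask: np.ndarray) -> int:
    """Number of disjoint contact intervals in a periodic boolean mask."""
    if mask.all() or not mask.any():
        return int(mask.any())
    rises = np.sum(mask & ~np.roll(mask, 1))
    return int(rises)


def label_gait(phi_L: float, mean_duty: float) -> str:
    """Coarse gait name from limb phase and duty factor."""
    kind = "walk" if mean_duty > 0.5 else "run"
    if abs(phi_L - 0.5) <= 0.05:
        return "trot" if kind == "run" else "walking trot"
    if abs(phi_L - 0.25) <= 0.1:
        return f"lateral-sequence {kind}"
    if abs(phi_L - 0.75) <= 0.1:
        return f"diagonal-sequence singlefoot ({kind})"
    return f"symmetrical {kind} (phi_L={phi_L:.2f})"


def extract_gait(sol, modulation_window: tuple[float, float] = (0.0, 1.0)) -> GaitSummary:
    """Derive limb phase, duty factors, track phase, GRF classes and cost of
    transport from a :class:`~paleogait.optimize.GaitSolution`."""
    body = sol.task.body
    base_threshold = F_THRESHOLD_FRAC * body.M * G
    T = sol.T
    t_full, F_full = full_cycle_forces(sol)

    onsets = {}
    duties = {}
    double = {}
    classes = {}
    for i, nm in enumerate(LIMB_NAMES):
        Fi = F_full[:, i]
        threshold = max(base_threshold, REL_THRESHOLD_FRAC * Fi.max())
        onsets[nm] = _onset_time(t_full, Fi, threshold, T)
        duties[nm] = _duty_factor(t_full, Fi, threshold, T)
        double[nm] = _count_contacts(_contact_mask(Fi, threshold)) > 1
        contact = _rotate_contact(t_full, Fi, threshold, T)
        classes[nm] = (classify_grf_profile(*contact) if contact is not None
                       else GRFClass(0, 0.0, "no-contact"))

    if onsets["LH"] is not None and onsets["LF"] is not None:
        phi_raw = ((onsets["LF"] - onsets["LH"]) / T) % 1.0
    else:
        phi_raw = 0.5  # continuous contact: timing undefined, trot-like
    phi_L = modulate_limb_phase(phi_raw, modulation_window)

    # The footfall-based track phase shares the planar left/right labeling
    # ambiguity (relabeling the forelimbs shifts it by 0.5); report the
    # candidate consistent with the modulated limb phase via the analytic
    # symmetric-gait relation.
    track_phase = ((sol.footfalls[2] - sol.footfalls[0]) / sol.D) % 1.0
    expected = (phi_L + horizontal_gad(body) / sol.D) % 1.0
    alt = (track_phase + 0.5) % 1.0
    if _circ_dist(alt, expected) < _circ_dist(track_phase, expected):
        track_phase = alt
    MgD = body.M * G * sol.D
    mean_duty = float(np.mean(list(duties.values())))
    return GaitSummary(
        limb_phase=phi_L,
        limb_phase_raw=phi_raw,
        duty_factors=duties,
        track_phase=float(track_phase),
        cot=sol.J / MgD,
        cot_work_only=sol.work / MgD,
        grf_classes=classes,
        gait_label=label_gait(phi_L, mean_duty),
        modulation_window=modulation_window,
        double_contact=double,
    )


def cost_of_transport(sol, body: Optional[BodyModel] = None,
                      D: Optional[float] = None, work_only: bool = False) -> float:
    """Dimensionless locomotor cost ``J / (M g D)``."""
    body = body if body is not None else sol.task.body
    D = D if D is not None else sol.D
    J = sol.work if work_only else sol.J
    return J / (body.M * G * D)


def physics_residuals(sol) -> dict[str, float]:
    """Momentum bookkeeping of a solution, in relative terms.

    Integrates the ground reaction forces with the same Hermite-Simpson
    quadrature the transcription uses, so for a feasible periodic solution:
    mean vertical GRF equals body weight, net horizontal impulse vanishes,
    and the pitch rate returns to its initial value.
    """
    from .optimize import build_problem

    problem = build_problem(sol.task)
    ev = problem._eval(sol.X_nd)
    kin, kin_c, Q = ev["kin"], ev["kin_c"], ev["Q"]
    h = problem.h
    Th = problem.T / 2.0

    def hs_integral(node_vals, mid_vals):
        return float(h / 6.0 * (node_vals[:-1].sum() + 4.0 * mid_vals.sum()
                                + node_vals[1:].sum()))

    Fz = (Q[:, 6:10] * kin.uz).sum(axis=1)
    Fzc = (ev["Qc"][:, 6:10] * kin_c.uz).sum(axis=1)
    Fx = (Q[:, 6:10] * kin.ux).sum(axis=1)
    Fxc = (ev["Qc"][:, 6:10] * kin_c.ux).sum(axis=1)
    weight_impulse = Th  # M g T/2 in solver units
    return dict(
        weight_support_rel=hs_integral(Fz, Fzc) / weight_impulse - 1.0,
        horizontal_impulse_rel=hs_integral(Fx, Fxc) / weight_impulse,
        pitch_rate_change=float(abs(Q[-1, 5] - Q[0, 5])),
        max_defect=sol.max_defect,
        max_complementarity_nd=float(
            (Q[:, 6:10] * (kin.L - problem.max_length)).max()),
    )


# ---------------------------------------------------------------------------
# sweeps and transitions


def _phase_distance_mod_half(a: float, b: float) -> float:
    """Distance between limb phases under the 0.5 left/right ambiguity."""
    d = abs(a - b) % 0.5
    return min(d, 0.5 - d)


@dataclass(frozen=True)
class Transition:
    """A detected gait change between two adjacent sweep speeds."""

    lower_speed: float
    upper_speed: float
    reason: str

    @property
    def speed(self) -> float:
        return 0.5 * (self.lower_speed + self.upper_speed)


def detect_transitions(atlas: pd.DataFrame, phase_jump: float = 0.05) -> list[Transition]:
    """Scan adjacent sweep rows for limb-phase jumps or GRF class changes."""
    out: list[Transition] = []
    recs = list(atlas.sort_values("U_H").itertuples())
    for a, b in zip(recs, recs[1:]):
        reasons = []
        if _phase_distance_mod_half(a.phi_L, b.phi_L) > phase_jump:
            reasons.append(f"limb phase {a.phi_L:.2f} -> {b.phi_L:.2f}")
        for nm in ("grf_hind", "grf_fore"):
            if getattr(a, nm) != getattr(b, nm):
                reasons.append(f"{nm} {getattr(a, nm)} -> {getattr(b, nm)}")
        if reasons:
            out.append(Transition(a.U_H, b.U_H, "; ".join(reasons)))
    return out


def atlas_row(result) -> dict:
    """Flatten one fit result into a gait-atlas record."""
    g, s, t = result.gait, result.solution, result.task
    return dict(
        U_H=t.U_H,
        D_H=t.D_H,
        c_prime=t.c_prime,
        J=s.J,
        work=s.work,
        penalty=s.penalty,
        cot=g.cot,
        cot_work_only=g.cot_work_only,
        phi_L=g.limb_phase,
        phi_L_raw=g.limb_phase_raw,
        track_phase=g.track_phase,
        duty_LH=g.duty_factors["LH"],
        duty_LF=g.duty_factors["LF"],
        grf_hind=g.grf_classes["LH"].label,
        grf_fore=g.grf_classes["LF"].label,
        gait=g.gait_label,
        status=s.status,
        n_converged=int(result.starts["converged"].sum()),
        max_defect=s.max_defect,
        max_complementarity=s.max_complementarity,
    )


def sweep(
    body: BodyModel,
    speeds: Sequence[float],
    c_prime: float = 3e-3,
    seed: int = 0,
    warm_chain: bool = True,
    phase_jump: float = 0.05,
    results_out: Optional[list] = None,
    **task_kwargs,
) -> tuple[pd.DataFrame, list[Transition]]:
    """Solve a speed grid and return the gait atlas plus detected transitions.

    Speeds are solved in ascending order; with ``warm_chain`` each task's
    multistart additionally seeds from the previous speed's best solution
    (rescaled), which stabilizes branch tracking along the sweep.
    """
    from .optimize import GaitTask, solve_multistart

    rows = []
    prev = None
    for k, U_H in enumerate(sorted(speeds)):
        task = GaitTask(body=body, U_H=U_H, c_prime=c_prime, seed=seed + k,
                        **task_kwargs)
        warm = []
        if warm_chain and prev is not None:
            warm.append(_rescale_warm_start(prev, task))
        result = solve_multistart(task, warm_starts=warm)
        if results_out is not None:
            results_out.append(result)
        rows.append(atlas_row(result))
        prev = result
    atlas = pd.DataFrame(rows)
    return atlas, detect_transitions(atlas, phase_jump=phase_jump)


def _rescale_warm_start(prev_result, task) -> np.ndarray:
    """Map the previous speed's solution onto the new task's scales."""
    from .optimize import build_problem

    prev_task = prev_result.task
    problem = build_problem(task)
    X = prev_result.solution.X_nd.copy()
    Q, U, p = problem.split(X)
    sx = task.D_H / prev_task.D_H
    sv = task.U_H / prev_task.U_H
    Q = Q.copy()
    Q[:, 0] *= sx
    Q[:, 3] *= sv
    return problem.pack(Q, U, p * sx)


def trackway_phase_trend(table: Optional[pd.DataFrame] = None):
    """Piecewise-linear track-phase-versus-speed trend of the trackways.

    Returns a callable ``phi_T(U_H)`` interpolating the published trackway
    (speed, track phase) points, used as the default target function for
    track-phase-constrained optimizations.
    """
    df = table if table is not None else trackway_table()
    df = df.dropna(subset=["track_phase", "est_speed"]).sort_values("est_speed")
    U = df["est_speed"].to_numpy(dtype=float)
    P = df["track_phase"].to_numpy(dtype=float)

    def target(U_H: float) -> float:
        return float(np.interp(U_H, U, P))

    return target
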