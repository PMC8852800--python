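"""Gait prediction by trajectory optimization: task setup, multistart solve.

The user-facing object is :class:`PlanarGaitModel`, a model built from a
body and a locomotor task (dimensionless speed, stride length, force-rate
penalty); its :meth:`~PlanarGaitModel.fit` runs a seeded multistart over
random and gait-structured initial guesses, solves each transcribed NLP
(sequential quadratic programming by default), keeps the best feasible
local optimum, and returns a :class:`GaitFitResult` carrying the
trajectory, the derived gait descriptors, and per-start diagnostics.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import Bounds, minimize

from .bodies import G, BodyModel, hip_height
from .collocation import NQ, NU, HalfCycleProblem, TranscriptionOptions
from .dynamics import IS_HIND, LIMB_NAMES, attachment_offset
from .trackways import SPEED_COEF, SPEED_EXP

#: reference dimensionless speed at which force-rate penalties are quoted
C_PRIME_REFERENCE_SPEED = 0.4


def stride_from_speed(U_H: float) -> float:
    """Invert the dynamic-similarity relation: ``D' = (U'/0.25)^(1/1.67)``."""
    return (U_H / SPEED_COEF) ** (1.0 / SPEED_EXP)


@dataclass(frozen=True)
class SolverOptions:
    """Stopping and feasibility tolerances for the NLP solver.

    ``method`` selects between the sequential-quadratic solver ("slsqp",
    default: fast active-set iterations with dense exact Jacobians) and the
    interior-point solver ("trust-constr", slower but sometimes more robust
    on badly scaled starts).
    """

    method: str = "slsqp"
    maxiter: int = 500
    ftol: float = 1e-9
    gtol: float = 1e-5
    xtol: float = 1e-10
    feasibility_tol: float = 1e-6
    #: stationarity residual below which a feasible trust-constr iterate
    #: that ran out of iterations still counts as a local optimum (the
    #: interior-point method reduces its barrier parameter very slowly
    #: near the solution)
    stationarity_tol: float = 1e-3


@dataclass(frozen=True)
class GaitTask:
    """One gait-prediction problem.

    ``c_prime`` is the dimensionless force-rate penalty quoted at the
    reference speed ``U_H' = 0.4``; the underlying dimensional coefficient
    is held fixed across speeds.  When ``D_H`` is omitted it is paired with
    the speed through the dynamic-similarity stride relation.
    """

    body: BodyModel
    U_H: float
    D_H: Optional[float] = None
    c_prime: float = 3e-3
    mesh_intervals: int = 24
    multistarts: int = 12
    seed: int = 0
    track_phase_target: Optional[float] = None
    relaxation_eps: float = 1e-3
    power_smoothing: float = 1e-3
    modulation_window: tuple[float, float] = (0.0, 1.0)
    solver: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self) -> None:
        if not self.U_H > 0:
            raise ValueError("U_H must be > 0")
        if self.D_H is None:
            object.__setattr__(self, "D_H", stride_from_speed(self.U_H))
        if not self.D_H > 0:
            raise ValueError("D_H must be > 0")
        if self.mesh_intervals < 10:
            raise ValueError("mesh_intervals must be >= 10")
        if self.multistarts < 1:
            raise ValueError("multistarts must be >= 1")
        if self.track_phase_target is not None and not 0 <= self.track_phase_target < 1:
            raise ValueError("track_phase_target must lie in [0, 1)")


def dimensionalize(task: GaitTask) -> tuple[float, float, float, float]:
    """Dimensional speed ``U`` (m/s), stride ``D`` (m), period ``T`` (s),
    and force-rate penalty coefficient ``c`` (m s / N).

    ``c`` is recovered from the quoted ``c' = c M g / (L_B T)`` at the
    reference-speed period, then reused unchanged at the task speed.
    """
    H = hip_height(task.body)
    U = task.U_H * math.sqrt(G * H)
    D = task.D_H * H
    T = D / U
    D_ref = stride_from_speed(C_PRIME_REFERENCE_SPEED) * H
    T_ref = D_ref / (C_PRIME_REFERENCE_SPEED * math.sqrt(G * H))
    c = task.c_prime * task.body.LB * T_ref / (task.body.M * G)
    return U, D, T, c


def nondimensional_penalty(task: GaitTask) -> float:
    """The force-rate penalty in solver units (lengths H, mass M, g = 1)."""
    H = hip_height(task.body)
    return task.c_prime * (task.body.LB / H) * (
        stride_from_speed(C_PRIME_REFERENCE_SPEED) / C_PRIME_REFERENCE_SPEED)


def nondimensional_body(body: BodyModel) -> BodyModel:
    """Rescale a body so hip height and mass are 1 (pitch MOI in M H^2)."""
    H = hip_height(body)
    return BodyModel(
        name=body.name + " (nondimensional)",
        LH=body.LH / H,
        LB=body.LB / H,
        LF=body.LF / H,
        LP=body.LP / H,
        LM=body.LM / H,
        MF_prime=body.MF_prime,
        M=1.0,
        I=body.I / (body.M * H * H),
    )


def build_problem(task: GaitTask) -> HalfCycleProblem:
    opts = TranscriptionOptions(
        mesh_intervals=task.mesh_intervals,
        relaxation_eps=task.relaxation_eps,
        power_smoothing=task.power_smoothing,
    )
    return HalfCycleProblem(
        nondimensional_body(task.body),
        U=task.U_H,
        D=task.D_H,
        c=nondimensional_penalty(task),
        options=opts,
        track_phase_target=task.track_phase_target,
    )


# ---------------------------------------------------------------------------
# initial guesses


def _standing_pose(body_nd: BodyModel) -> tuple[float, float]:
    """(COM height, trunk pitch) of a slightly crouched standing pose."""
    z_hip = 0.95 * body_nd.LH
    z_gl = 0.95 * body_nd.LF
    sin_th = np.clip((z_gl - z_hip) / body_nd.LB, -0.99, 0.99)
    th = math.asin(sin_th)
    z = z_hip + body_nd.MF_prime * (z_gl - z_hip)
    return z, th


def _bump(phase: np.ndarray) -> np.ndarray:
    """sin^2 bump on [0, 1], zero outside."""
    out = np.zeros_like(phase)
    inside = (phase >= 0) & (phase <= 1)
    out[inside] = np.sin(np.pi * phase[inside]) ** 2
    return out


def initial_guess(
    problem: HalfCycleProblem,
    rng: np.random.Generator,
    phi_L: Optional[float] = None,
    duty: Optional[float] = None,
) -> np.ndarray:
    """Build one seeded initial guess for the half-cycle NLP.

    With ``phi_L`` given, contact timing follows a symmetric gait with that
    limb phase and footfalls are placed under the girdles at mid-stance;
    otherwise onsets, duties, bump shapes and footfalls are random (footfall
    positions uniform over [-D/2, D]).  Force amplitudes are scaled so the
    limbs statically support body weight in the stated fore/hind shares.
    """
    body, K, T = problem.body, problem.K, problem.T
    Th = T / 2.0
    t = np.linspace(0.0, Th, K)
    z0, th0 = _standing_pose(body)

    Q = np.zeros((K, NQ))
    Q[:, 0] = problem.U * t
    Q[:, 1] = z0
    Q[:, 2] = th0
    Q[:, 3] = problem.U

    share = np.where(IS_HIND, (1.0 - body.MF_prime) / 2.0, body.MF_prime / 2.0)
    structured = phi_L is not None
    if structured:
        df = duty if duty is not None else float(
            np.clip(0.75 - 0.35 * problem.U, 0.3, 0.7))
        onsets = np.array([0.0, 0.5, phi_L, (0.5 + phi_L) % 1.0])
        onsets = (onsets + rng.uniform(0, 0.05)) % 1.0
        F = np.zeros((K, 4))
        for i in range(4):
            ph = ((t / T - onsets[i]) % 1.0) / df
            F[:, i] = (share[i] / (0.5 * df)) * _bump(ph)
    else:
        F = np.zeros((K, 4))
        for i in range(4):
            for _ in range(rng.integers(1, 3)):
                center = rng.uniform(0.0, Th)
                width = rng.uniform(0.15, 0.5) * Th
                ph = (t - (center - width / 2.0)) / width
                F[:, i] += rng.uniform(0.5, 1.5) * share[i] * _bump(ph)
        mean_total = max(F.sum(axis=1).mean(), 1e-6)
        F *= 1.0 / mean_total
    Q[:, 6:10] = F

    U = np.gradient(F, t, axis=0)  # force-rate controls consistent with F

    p = np.empty(4)
    b = np.array([attachment_offset(body, "hip" if h else "glenoid")
                  for h in IS_HIND])
    if structured:
        for i in range(4):
            w = F[:, i]
            t_mid = float((w * t).sum() / w.sum()) if w.sum() > 1e-9 else Th / 2.0
            p[i] = problem.U * t_mid + b[i] * math.cos(th0)
    else:
        p = rng.uniform(-problem.D / 2.0, problem.D, size=4)

    # make the guess consistent with its symmetric-footfall branch: snap the
    # right-limb footfalls and zero the boundary forces the branch forbids
    for i, s in zip((0, 2), HalfCycleProblem.guess_branches(Q)):
        m = 1 if i == 0 else 3
        p[m] = p[i] - s * problem.D / 2.0
        if s == 1:
            Q[0, 6 + i] = 0.0
            Q[-1, 6 + m] = 0.0
        else:
            Q[-1, 6 + i] = 0.0
            Q[0, 6 + m] = 0.0

    if problem.track_phase_target is not None:
        # place the fore footfall on an admissible wrap branch of the target
        target = problem.track_phase_target
        branch = round((p[2] - p[0]) / problem.D - target)
        branch = int(np.clip(branch, -1, 1))
        p[2] = p[0] + (target + branch) * problem.D
        p[3] = p[1] + (target + branch) * problem.D

    X = problem.pack(Q, U, p)
    lb, ub = problem.bounds()
    return np.clip(X, lb, ub)


GUESS_PHASES = (0.5, 0.25, 0.75)  # trot, lateral-sequence, diagonal-sequence


def interpolate_decision(
    X: np.ndarray, problem_old: HalfCycleProblem, problem_new: HalfCycleProblem
) -> np.ndarray:
    """Resample a decision vector onto a different mesh (same task scales)."""
    Qo, Uo, p = problem_old.split(X)
    to = np.linspace(0.0, 1.0, problem_old.K)
    tn = np.linspace(0.0, 1.0, problem_new.K)
    Qn = np.stack([np.interp(tn, to, Qo[:, j]) for j in range(NQ)], axis=1)
    Un = np.stack([np.interp(tn, to, Uo[:, j]) for j in range(NU)], axis=1)
    return problem_new.pack(Qn, Un, p.copy())


# ---------------------------------------------------------------------------
# solutions


@dataclass
class GaitSolution:
    """Optimizer output time series, in SI units over the half cycle."""

    task: GaitTask
    t: np.ndarray                # s, K nodes over [0, T/2]
    x: np.ndarray
    z: np.ndarray
    theta: np.ndarray
    vx: np.ndarray
    vz: np.ndarray
    omega: np.ndarray
    F: np.ndarray                # N, shape (K, 4), canonical limb order
    Fdot: np.ndarray             # N/s
    impulse: np.ndarray          # N s, cumulative per limb
    footfalls: np.ndarray        # m, shape (4,)
    U: float                     # m/s
    D: float                     # m
    T: float                     # s, full stride period
    J: float                     # J, work term + penalty term
    work: float                  # J, positive + |negative| axial limb work
    penalty: float               # J, force-rate penalty contribution
    status: int
    constr_violation: float
    max_defect: float
    max_complementarity: float
    X_nd: np.ndarray             # raw nondimensional decision vector
    objective_nd: float

    @property
    def limb_names(self) -> tuple[str, ...]:
        return LIMB_NAMES


def _post_solution(task: GaitTask, problem: HalfCycleProblem, res,
                   violation: float) -> GaitSolution:
    body = task.body
    H = hip_height(body)
    t_unit = math.sqrt(H / G)
    f_unit = body.M * G
    X = res.x
    Q, Uc, p = problem.split(X)
    Th_nd = problem.T / 2.0
    t = np.linspace(0.0, Th_nd, problem.K) * t_unit

    kin = problem._kinetics(Q, p)
    power_nd = kin.power  # (K, 4)
    work_rate = np.abs(power_nd).sum(axis=1)
    pen_rate = problem.c * (Uc**2).sum(axis=1)
    e_unit = f_unit * H
    work = np.trapezoid(work_rate, dx=problem.h) * e_unit
    penalty = np.trapezoid(pen_rate, dx=problem.h) * e_unit

    F = Q[:, 6:10] * f_unit
    defects = problem.defects(X)
    comp = (Q[:, 6:10] * (kin.L - problem.max_length)).max()
    return GaitSolution(
        task=task,
        t=t,
        x=Q[:, 0] * H,
        z=Q[:, 1] * H,
        theta=Q[:, 2].copy(),
        vx=Q[:, 3] * H / t_unit,
        vz=Q[:, 4] * H / t_unit,
        omega=Q[:, 5] / t_unit,
        F=F,
        Fdot=Uc * f_unit / t_unit,
        impulse=np.vstack([np.zeros(4), cumulative_trapezoid(F, t, axis=0)]),
        footfalls=p * H,
        U=task.U_H * math.sqrt(G * H),
        D=task.D_H * H,
        T=(problem.T) * t_unit,
        J=work + penalty,
        work=work,
        penalty=penalty,
        status=res.status,
        constr_violation=float(violation),
        max_defect=float(np.abs(defects).max()),
        max_complementarity=float(comp),
        X_nd=X.copy(),
        objective_nd=float(res.fun),
    )


_OK_STATUSES = {"slsqp": (0,), "trust-constr": (1, 2)}


def _feasibility_violation(problem, X, linear) -> float:
    """Worst constraint violation of an iterate (solver-independent)."""
    viol = float(np.abs(problem.defects(X)).max())
    path = problem.path(X)
    plb, pub = problem.path_bounds()
    viol = max(viol, float(np.maximum(path - pub, 0.0).max()),
               float(np.maximum(plb - path, 0.0).max()))
    for lc in linear:
        r = np.asarray(lc.A) @ X
        viol = max(viol, float(np.abs(r - lc.lb).max()))
    lb, ub = problem.bounds()
    viol = max(viol, float(np.maximum(X - ub, 0.0).max()),
               float(np.maximum(lb - X, 0.0).max()))
    return viol


def _solve_start(problem, X0, nonlinear, linear, lb, ub, sopts):
    """Run one local solve; returns (result, feasibility violation, niter)."""
    if sopts.method == "trust-constr":
        res = minimize(
            problem.objective, X0, jac=problem.gradient, method="trust-constr",
            bounds=Bounds(lb, ub), constraints=nonlinear + linear,
            options=dict(maxiter=sopts.maxiter, gtol=sopts.gtol,
                         xtol=sopts.xtol, sparse_jacobian=True, verbose=0),
        )
        return res, float(res.constr_violation), res.niter
    if sopts.method != "slsqp":
        raise ValueError(f"unknown solver method {sopts.method!r}")
    K4 = problem.K * 4
    plb, pub = problem.path_bounds()
    cons = [
        dict(type="eq", fun=problem.defects,
             jac=lambda X: problem.defects_jac(X).toarray()),
        # complementarity upper bound and joint-height lower bound
        dict(type="ineq",
             fun=lambda X: pub[:K4] - problem.path(X)[:K4],
             jac=lambda X: -problem.path_jac(X).toarray()[:K4]),
        dict(type="ineq",
             fun=lambda X: problem.path(X)[K4:],
             jac=lambda X: problem.path_jac(X).toarray()[K4:]),
    ]
    for lc in linear:
        A = np.asarray(lc.A)
        b = np.asarray(lc.lb)
        cons.append(dict(type="eq", fun=lambda X, A=A, b=b: A @ X - b,
                         jac=lambda X, A=A: A))
    res = minimize(
        problem.objective, X0, jac=problem.gradient, method="SLSQP",
        bounds=Bounds(lb, ub), constraints=cons,
        options=dict(maxiter=sopts.maxiter, ftol=sopts.ftol),
    )
    return res, _feasibility_violation(problem, res.x, linear), res.nit


class MultistartFailure(RuntimeError):
    """No start converged to a feasible local optimum."""

    def __init__(self, log: pd.DataFrame):
        self.log = log
        super().__init__(
            "no feasible local optimum found; per-start log:\n" + log.to_string()
        )


class PlanarGaitModel:
    """Work-plus-force-rate-optimal gait prediction for a planar quadruped.

    Parameters mirror :class:`GaitTask`; :meth:`fit` performs the seeded
    multistart optimization and returns a :class:`GaitFitResult`.
    """

    def __init__(self, body: BodyModel, U_H: float, **task_kwargs) -> None:
        self.task = GaitTask(body=body, U_H=U_H, **task_kwargs)

    @classmethod
    def from_task(cls, task: GaitTask) -> "PlanarGaitModel":
        obj = cls.__new__(cls)
        obj.task = task
        return obj

    def fit(
        self,
        multistarts: Optional[int] = None,
        seed: Optional[int] = None,
        warm_starts: Sequence[np.ndarray] = (),
    ) -> "GaitFitResult":
        from .postprocess import extract_gait  # deferred: avoids import cycle

        task = self.task
        n_starts = multistarts if multistarts is not None else task.multistarts
        seed = seed if seed is not None else task.seed
        problem = build_problem(task)
        sopts = task.solver
        nonlinear = problem.nonlinear_constraints()
        lb, ub = problem.bounds()

        streams = np.random.SeedSequence(seed).spawn(n_starts)
        records = []
        best = None
        guesses: list[tuple[str, np.ndarray]] = []
        for w, X0 in enumerate(warm_starts):
            if X0.shape == (problem.n_vars,):
                guesses.append((f"warm-{w}", np.clip(X0, lb, ub)))
        for i in range(n_starts):
            rng = np.random.default_rng(streams[i])
            if i < len(GUESS_PHASES):
                kind = f"structured-{GUESS_PHASES[i]}"
                X0 = initial_guess(problem, rng, phi_L=GUESS_PHASES[i])
            else:
                kind = "random"
                X0 = initial_guess(problem, rng)
            guesses.append((kind, X0))

        for kind, X0 in guesses:
            Q0, _, p0 = problem.split(X0)
            linear = [problem.linear_constraints(problem.guess_branches(Q0))]
            if task.track_phase_target is not None:
                branch = int(round((p0[2] - p0[0]) / problem.D
                                   - task.track_phase_target))
                linear.append(problem.track_phase_constraint(branch))
            try:
                res, violation, niter = _solve_start(
                    problem, X0, nonlinear, linear, lb, ub, sopts)
            except Exception as exc:  # solver blow-up counts as a failed start
                records.append(dict(start=kind, status=-99, J=np.nan,
                                    violation=np.nan, niter=0,
                                    converged=False, error=str(exc)))
                continue
            feasible = violation < sopts.feasibility_tol
            converged = feasible and res.status in _OK_STATUSES[sopts.method]
            if sopts.method == "trust-constr" and feasible and not converged:
                converged = res.optimality < sopts.stationarity_tol
            records.append(dict(start=kind, status=res.status, J=float(res.fun),
                                violation=float(violation),
                                niter=niter, converged=converged, error=""))
            if converged and (best is None or res.fun < best[0].fun):
                best = (res, violation)

        log = pd.DataFrame(records)
        if best is None:
            raise MultistartFailure(log)
        solution = _post_solution(task, problem, *best)
        gait = extract_gait(solution, task.modulation_window)
        return GaitFitResult(model=self, solution=solution, gait=gait, starts=log)


@dataclass
class GaitFitResult:
    """Best local optimum of a gait task plus derived gait descriptors."""

    model: PlanarGaitModel
    solution: GaitSolution
    gait: "object"              # GaitSummary (postprocess)
    starts: pd.DataFrame

    @property
    def task(self) -> GaitTask:
        return self.model.task

    def summary(self) -> str:
        s, g, t = self.solution, self.gait, self.task
        lines = [
            f"Planar gait optimization: {t.body.name}",
            f"  U_H' = {t.U_H:.3f}   D_H' = {t.D_H:.3f}   c' = {t.c_prime:.1e}"
            f"   mesh = {t.mesh_intervals}",
            f"  converged starts: {int(self.starts['converged'].sum())}"
            f"/{len(self.starts)}",
            f"  J = {s.J:.3f} J  (work {s.work:.3f}, penalty {s.penalty:.3f})",
            f"  cost of transport = {g.cot:.4f} (work-only {g.cot_work_only:.4f})",
            f"  limb phase = {g.limb_phase:.3f}   track phase = {g.track_phase:.3f}",
            f"  duty factors: " + "  ".join(
                f"{nm}={g.duty_factors[nm]:.2f}" for nm in LIMB_NAMES),
            f"  GRF classes: " + "  ".join(
                f"{nm}={g.grf_classes[nm].label}" for nm in LIMB_NAMES),
            f"  gait: {g.gait_label}",
            f"  max defect = {s.max_defect:.2e}   max complementarity = "
            f"{s.max_complementarity:.2e}",
        ]
        return "\n".join(lines)


def solve_multistart(task: GaitTask, **fit_kwargs) -> GaitFitResult:
    """Convenience wrapper: build the model for ``task`` and fit it."""
    return PlanarGaitModel.from_task(task).fit(**fit_kwargs)


def constrain_track_phase(task: GaitTask, target: float) -> GaitTask:
    """Return a copy of the task with the track phase constrained to
    ``target`` (the optimizer's footfall separation is fixed accordingly)."""
    return dataclasses.replace(task, track_phase_target=float(target % 1.0))
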