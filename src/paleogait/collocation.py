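"""Direct-collocation transcription of the half-cycle gait problem.

One symmetric half-stride of the planar quadruped is transcribed on a fixed
mesh with compressed Hermite-Simpson collocation.  States per node are the
six trunk kinematic states plus the four axial limb forces (forces are
states; force *rates* are the controls), and the four footfall positions
are global decision parameters.  The objective integrates, per limb, the
magnitude of axial limb power (smoothed near zero so the problem stays
twice differentiable) plus a force-rate-squared penalty.

Contact is handled by relaxed complementarity: force is admissible only
while the leg is no longer than its anatomical length,
``F * (L - L_max) <= eps``, with ``F >= 0`` (legs push only).  Hip and
glenoid must stay above ground, the trunk pitch within [-pi/2, pi/2], the
COM must advance from 0 to D/2 over the half cycle, trunk kinematics are
periodic, and left-limb forces at t=0 equal right-limb forces at t=T/2.

Everything here is nondimensional: lengths in hip heights H, time in
sqrt(H/g), force in units of body weight Mg.  The caller scales back.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.optimize import LinearConstraint, NonlinearConstraint

from .bodies import BodyModel
from .dynamics import IS_HIND, MIRROR, limb_kinetics, attachment_offset

NQ = 10  # states per node: x, z, th, vx, vz, om, F0..F3
NU = 4   # controls per node: Fdot0..Fdot3
NP = 4   # global parameters: footfall positions


@dataclass
class TranscriptionOptions:
    """Numerical parameters of the transcription (nondimensional units)."""

    mesh_intervals: int = 24
    relaxation_eps: float = 1e-3   # complementarity relaxation, units Mg*H
    power_smoothing: float = 1e-3  # |power| smoothing scale, units Mg*sqrt(gH)*H
    force_cap: float = 20.0        # max limb force, units Mg
    min_com_height: float = 0.02   # lower bound on COM height, units H

    def __post_init__(self) -> None:
        if self.mesh_intervals < 10:
            raise ValueError("mesh_intervals must be >= 10")


class HalfCycleProblem:
    """Nondimensional NLP for one half stride at fixed speed and stride length.

    Parameters
    ----------
    body_nd : BodyModel
        Body model rescaled so the hip height is 1 and the mass is 1.
    U, D : float
        Dimensionless mean speed and stride length; the half-cycle duration
        is ``D / U / 2``.
    c : float
        Nondimensional force-rate penalty coefficient.
    track_phase_target : float, optional
        When set, the fore/hind footfall separation is constrained so the
        track phase ``mod((p_fore - p_hind)/D, 1)`` equals the target.
    """

    def __init__(
        self,
        body_nd: BodyModel,
        U: float,
        D: float,
        c: float,
        options: TranscriptionOptions | None = None,
        track_phase_target: Optional[float] = None,
    ) -> None:
        self.body = body_nd
        self.U, self.D, self.c = float(U), float(D), float(c)
        self.T = self.D / self.U              # full stride period
        self.opts = options or TranscriptionOptions()
        self.track_phase_target = track_phase_target
        self.N = self.opts.mesh_intervals
        self.K = self.N + 1
        self.h = (self.T / 2.0) / self.N
        self.n_vars = self.K * (NQ + NU) + NP
        self.max_length = np.where(IS_HIND, body_nd.LH, body_nd.LF)
        self._cache_x: np.ndarray | None = None
        self._cache: dict = {}
        self._build_sparsity()

    # -- variable layout ---------------------------------------------------

    def split(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        K = self.K
        Q = X[: K * NQ].reshape(K, NQ)
        U = X[K * NQ: K * (NQ + NU)].reshape(K, NU)
        p = X[K * (NQ + NU):]
        return Q, U, p

    def pack(self, Q: np.ndarray, U: np.ndarray, p: np.ndarray) -> np.ndarray:
        return np.concatenate([Q.ravel(), U.ravel(), p])

    def _qcols(self, k):  # column indices of node-k states
        return np.arange(k * NQ, (k + 1) * NQ)

    # -- shared evaluation -------------------------------------------------

    def _eval(self, X: np.ndarray) -> dict:
        if self._cache_x is not None and np.array_equal(X, self._cache_x):
            return self._cache
        Q, U, p = self.split(X)
        kin = self._kinetics(Q, p)
        f = self._f(Q, U, kin)
        A, C = self._fjac(kin)
        h = self.h
        Qc = 0.5 * (Q[:-1] + Q[1:]) + (h / 8.0) * (f[:-1] - f[1:])
        Uc = 0.5 * (U[:-1] + U[1:])
        kin_c = self._kinetics(Qc, p)
        fc = self._f(Qc, Uc, kin_c)
        Ac, Cc = self._fjac(kin_c)
        self._cache = dict(Q=Q, U=U, p=p, kin=kin, f=f, A=A, C=C,
                           Qc=Qc, Uc=Uc, kin_c=kin_c, fc=fc, Ac=Ac, Cc=Cc)
        self._cache_x = X.copy()
        return self._cache

    def _kinetics(self, Q: np.ndarray, p: np.ndarray):
        return limb_kinetics(
            Q[:, 0], Q[:, 1], Q[:, 2], Q[:, 3], Q[:, 4], Q[:, 5],
            Q[:, 6:10], p, self.body, g=1.0,
        )

    @staticmethod
    def _f(Q: np.ndarray, U: np.ndarray, kin) -> np.ndarray:
        f = np.empty_like(Q)
        f[:, 0:3] = Q[:, 3:6]
        f[:, 3] = kin.ax
        f[:, 4] = kin.az
        f[:, 5] = kin.alpha
        f[:, 6:10] = U
        return f

    @staticmethod
    def _fjac(kin) -> tuple[np.ndarray, np.ndarray]:
        """Per-node Jacobians A = df/dq (K,10,10) and C = df/dp (K,10,4)."""
        K = kin.ax.shape[0]
        A = np.zeros((K, NQ, NQ))
        A[:, 0, 3] = A[:, 1, 4] = A[:, 2, 5] = 1.0
        for row, nm in ((3, "ax"), (4, "az"), (5, "alpha")):
            A[:, row, 0] = getattr(kin, f"d{nm}_dx")
            A[:, row, 1] = getattr(kin, f"d{nm}_dz")
            A[:, row, 2] = getattr(kin, f"d{nm}_dth")
            A[:, row, 6:10] = getattr(kin, f"d{nm}_dF")
        C = np.zeros((K, NQ, NP))
        C[:, 3, :] = kin.dax_dp
        C[:, 4, :] = kin.daz_dp
        C[:, 5, :] = kin.dalpha_dp
        return A, C

    # B = df/du is constant: rows 6..9 are the identity on the controls.

    # -- objective ---------------------------------------------------------

    def _cost_partials(self, kin, Q: np.ndarray, U: np.ndarray):
        """dg/dq (K,10), dg/du (K,4), dg/dp (K,4)."""
        delta = self.opts.power_smoothing
        P = kin.power
        wp = P / np.sqrt(P * P + delta * delta)
        F = Q[:, 6:10]
        dq = np.zeros((Q.shape[0], NQ))
        dq[:, 0] = (wp * F * kin.dLdot_dx).sum(axis=1)
        dq[:, 1] = (wp * F * kin.dLdot_dz).sum(axis=1)
        dq[:, 2] = (wp * F * kin.dLdot_dth).sum(axis=1)
        dq[:, 3] = (wp * F * kin.dLdot_dvx).sum(axis=1)
        dq[:, 4] = (wp * F * kin.dLdot_dvz).sum(axis=1)
        dq[:, 5] = (wp * F * kin.dLdot_dom).sum(axis=1)
        dq[:, 6:10] = wp * kin.Ldot
        du = 2.0 * self.c * U
        dp = wp * F * kin.dLdot_dp
        return dq, du, dp

    def objective(self, X: np.ndarray) -> float:
        ev = self._eval(X)
        delta = self.opts.power_smoothing

        def g_of(kin, U):
            P = kin.power
            return (np.sqrt(P * P + delta * delta) - delta).sum(axis=1) \
                + self.c * (U * U).sum(axis=1)

        g = g_of(ev["kin"], ev["U"])
        gc = g_of(ev["kin_c"], ev["Uc"])
        return float(self.h / 6.0 * (g[:-1].sum() + 4.0 * gc.sum() + g[1:].sum()))

    def gradient(self, X: np.ndarray) -> np.ndarray:
        ev = self._eval(X)
        h, K, N = self.h, self.K, self.N
        dq, du, dp = self._cost_partials(ev["kin"], ev["Q"], ev["U"])
        dqc, duc, dpc = self._cost_partials(ev["kin_c"], ev["Qc"], ev["Uc"])
        A, C, Ac, Cc = ev["A"], ev["C"], ev["Ac"], ev["Cc"]

        w_node = np.full(K, 2.0 * h / 6.0)
        w_node[0] = w_node[-1] = h / 6.0
        gQ = w_node[:, None] * dq
        gU = w_node[:, None] * du
        gp = (w_node[:, None] * dp).sum(axis=0)

        wm = 4.0 * h / 6.0
        # chain through the interpolated midpoint states
        # v @ (I/2 + h/8 A_k) etc.
        vA_k = 0.5 * dqc + (h / 8.0) * np.einsum("kj,kji->ki", dqc, A[:-1])
        vA_k1 = 0.5 * dqc - (h / 8.0) * np.einsum("kj,kji->ki", dqc, A[1:])
        np.add.at(gQ, np.arange(N), wm * vA_k)
        np.add.at(gQ, np.arange(1, K), wm * vA_k1)
        # v @ (h/8 B) picks force-rate rows 6..9 of v
        vB = (h / 8.0) * dqc[:, 6:10]
        np.add.at(gU, np.arange(N), wm * (vB + 0.5 * duc))
        np.add.at(gU, np.arange(1, K), wm * (-vB + 0.5 * duc))
        vCdiff = np.einsum("kj,kji->ki", dqc, C[:-1] - C[1:])
        gp += wm * (dpc + (h / 8.0) * vCdiff).sum(axis=0)

        return self.pack(gQ, gU, gp)

    # -- defect constraints ------------------------------------------------

    def defects(self, X: np.ndarray) -> np.ndarray:
        ev = self._eval(X)
        Q, f, fc = ev["Q"], ev["f"], ev["fc"]
        d = Q[1:] - Q[:-1] - (self.h / 6.0) * (f[:-1] + 4.0 * fc + f[1:])
        return d.ravel()

    def _build_sparsity(self) -> None:
        """Precompute COO indices for the defect Jacobian blocks."""
        N, K = self.N, self.K
        rows_q, cols_qk, cols_qk1 = [], [], []
        for k in range(N):
            r = np.repeat(np.arange(k * NQ, (k + 1) * NQ), NQ)
            rows_q.append(r)
            cols_qk.append(np.tile(np.arange(k * NQ, (k + 1) * NQ), NQ))
            cols_qk1.append(np.tile(np.arange((k + 1) * NQ, (k + 2) * NQ), NQ))
        self._def_rows_q = np.concatenate(rows_q)
        self._def_cols_qk = np.concatenate(cols_qk)
        self._def_cols_qk1 = np.concatenate(cols_qk1)
        u0 = K * NQ
        rows_u, cols_uk, cols_uk1 = [], [], []
        for k in range(N):
            r = np.repeat(np.arange(k * NQ, (k + 1) * NQ), NU)
            rows_u.append(r)
            cols_uk.append(np.tile(np.arange(u0 + k * NU, u0 + (k + 1) * NU), NQ))
            cols_uk1.append(np.tile(np.arange(u0 + (k + 1) * NU, u0 + (k + 2) * NU), NQ))
        self._def_rows_u = np.concatenate(rows_u)
        self._def_cols_uk = np.concatenate(cols_uk)
        self._def_cols_uk1 = np.concatenate(cols_uk1)
        p0 = K * (NQ + NU)
        self._def_rows_p = np.repeat(np.arange(N * NQ), NP)
        self._def_cols_p = np.tile(np.arange(p0, p0 + NP), N * NQ)

    def defects_jac(self, X: np.ndarray) -> sp.csr_matrix:
        ev = self._eval(X)
        A, C, Ac, Cc = ev["A"], ev["C"], ev["Ac"], ev["Cc"]
        h, N = self.h, self.N
        I10 = np.eye(NQ)

        Ak, Ak1 = A[:-1], A[1:]
        # dq_c/dq_k = I/2 + h/8 A_k ; dq_c/dq_{k+1} = I/2 - h/8 A_{k+1}
        Jq_k = -I10 - (h / 6.0) * (Ak + 4.0 * np.einsum(
            "kij,kjl->kil", Ac, 0.5 * I10 + (h / 8.0) * Ak))
        Jq_k1 = I10 - (h / 6.0) * (Ak1 + 4.0 * np.einsum(
            "kij,kjl->kil", Ac, 0.5 * I10 - (h / 8.0) * Ak1))
        # B is constant: df/du has identity in rows 6..9
        B = np.zeros((NQ, NU))
        B[6:10, :] = np.eye(NU)
        AcB = np.einsum("kij,jl->kil", Ac, B)
        Ju_k = -(h / 6.0) * (3.0 * B[None] + (h / 2.0) * AcB)
        Ju_k1 = -(h / 6.0) * (3.0 * B[None] - (h / 2.0) * AcB)
        Jp = -(h / 6.0) * (C[:-1] + C[1:] + 4.0 * (
            Cc + (h / 8.0) * np.einsum("kij,kjl->kil", Ac, C[:-1] - C[1:])))

        rows = np.concatenate([self._def_rows_q, self._def_rows_q,
                               self._def_rows_u, self._def_rows_u,
                               self._def_rows_p])
        cols = np.concatenate([self._def_cols_qk, self._def_cols_qk1,
                               self._def_cols_uk, self._def_cols_uk1,
                               self._def_cols_p])
        vals = np.concatenate([Jq_k.ravel(), Jq_k1.ravel(),
                               Ju_k.ravel(), Ju_k1.ravel(), Jp.ravel()])
        return sp.coo_matrix((vals, (rows, cols)),
                             shape=(N * NQ, self.n_vars)).tocsr()

    # -- path constraints (complementarity + joint heights) ---------------

    def path(self, X: np.ndarray) -> np.ndarray:
        ev = self._eval(X)
        kin, Q, p = ev["kin"], ev["Q"], ev["p"]
        F = Q[:, 6:10]
        comp = (F * (kin.L - self.max_length)).ravel()
        b_hip = attachment_offset(self.body, "hip")
        b_gl = attachment_offset(self.body, "glenoid")
        sth = np.sin(Q[:, 2])
        heights = np.stack([Q[:, 1] + b_hip * sth, Q[:, 1] + b_gl * sth], axis=1)
        return np.concatenate([comp, heights.ravel()])

    def path_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        K = self.K
        eps = self.opts.relaxation_eps
        lb = np.concatenate([np.full(K * 4, -np.inf), np.zeros(K * 2)])
        ub = np.concatenate([np.full(K * 4, eps), np.full(K * 2, np.inf)])
        return lb, ub

    def path_jac(self, X: np.ndarray) -> sp.csr_matrix:
        ev = self._eval(X)
        kin, Q, p = ev["kin"], ev["Q"], ev["p"]
        K = self.K
        F = Q[:, 6:10]
        rows, cols, vals = [], [], []

        def add(r, c, v):
            rows.append(np.asarray(r).ravel())
            cols.append(np.asarray(c).ravel())
            vals.append(np.asarray(v).ravel())

        # complementarity rows: 4 per node
        ridx = (np.arange(K)[:, None] * 4 + np.arange(4)[None, :])
        qbase = np.arange(K)[:, None] * NQ
        add(ridx, qbase + 6 + np.arange(4)[None, :], kin.L - self.max_length)
        add(ridx, np.broadcast_to(qbase + 0, ridx.shape), F * kin.dL_dx)
        add(ridx, np.broadcast_to(qbase + 1, ridx.shape), F * kin.dL_dz)
        add(ridx, np.broadcast_to(qbase + 2, ridx.shape), F * kin.dL_dth)
        p0 = K * (NQ + NU)
        add(ridx, np.broadcast_to(p0 + np.arange(4)[None, :], ridx.shape),
            F * kin.dL_dp)
        # joint-height rows: 2 per node
        b = np.array([attachment_offset(self.body, "hip"),
                      attachment_offset(self.body, "glenoid")])
        hidx = K * 4 + np.arange(K)[:, None] * 2 + np.arange(2)[None, :]
        add(hidx, np.broadcast_to(qbase + 1, hidx.shape), np.ones((K, 2)))
        add(hidx, np.broadcast_to(qbase + 2, hidx.shape),
            b[None, :] * np.cos(Q[:, 2])[:, None])
        return sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(K * 6, self.n_vars)).tocsr()

    # -- linear boundary / periodicity constraints ------------------------

    def linear_constraints(self, branches: tuple[int, int] = (1, 1)) -> LinearConstraint:
        """Boundary, periodicity, and symmetric-footfall constraints.

        ``branches`` gives, per left limb (hind, fore), the sign ``s`` of
        the symmetric-gait footfall relation ``p_left - p_right = s D/2``.
        A limb's contact can only span the half-cycle boundary whose
        footfall relocation that sign makes consistent, so the force at the
        opposite boundary is pinned to zero; this excludes unphysical
        solutions in which one leg presses at two ground points (one
        cranial, one caudal) within a single stride.
        """
        K, n = self.K, self.n_vars
        rows = []
        rhs = []

        def row(pairs, value):
            r = np.zeros(n)
            for col, coef in pairs:
                r[col] += coef
            rows.append(r)
            rhs.append(value)

        q0 = 0
        qE = (K - 1) * NQ
        u0 = K * NQ
        uE = K * NQ + (K - 1) * NU
        p0 = K * (NQ + NU)
        row([(q0 + 0, 1.0)], 0.0)                      # x(0) = 0
        row([(qE + 0, 1.0)], self.D / 2.0)             # x(T/2) = D/2
        for j in range(1, 6):                          # z, th, vx, vz, om periodic
            row([(qE + j, 1.0), (q0 + j, -1.0)], 0.0)
        for i in range(4):                             # force symmetry (and rate)
            row([(qE + 6 + i, 1.0), (q0 + 6 + MIRROR[i], -1.0)], 0.0)
            row([(uE + i, 1.0), (u0 + MIRROR[i], -1.0)], 0.0)
        for (i, s) in zip((0, 2), branches):           # symmetric footfalls
            if s not in (-1, 1):
                raise ValueError("branch signs must be +/-1")
            m = MIRROR[i]
            row([(p0 + i, 1.0), (p0 + m, -1.0)], s * self.D / 2.0)
            # pin the force at the boundary the branch makes inconsistent
            col = (q0 + 6 + i) if s == 1 else (qE + 6 + i)
            row([(col, 1.0)], 0.0)
        A = np.array(rows)
        rhs = np.array(rhs)
        return LinearConstraint(A, rhs, rhs)

    @staticmethod
    def guess_branches(Q: np.ndarray) -> tuple[int, int]:
        """Pick footfall branch signs from a guess's boundary forces: a limb
        more loaded at the end of the half cycle spans that boundary."""
        return tuple(1 if Q[-1, 6 + i] >= Q[0, 6 + i] else -1 for i in (0, 2))

    def track_phase_constraint(self, branch: int) -> LinearConstraint:
        """Linear equality fixing the fore-hind footfall separation to
        ``(target + branch) * D`` for a given wrap branch."""
        if self.track_phase_target is None:
            raise ValueError("no track-phase target set on this problem")
        n = self.n_vars
        p0 = self.K * (NQ + NU)
        r = np.zeros(n)
        r[p0 + 2] = 1.0   # left fore footfall
        r[p0 + 0] = -1.0  # left hind footfall
        rhs = (self.track_phase_target + branch) * self.D
        return LinearConstraint(r[None, :], [rhs], [rhs])

    # -- bounds ------------------------------------------------------------

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        K, D = self.K, self.D
        qlo = np.array([-D, self.opts.min_com_height, -np.pi / 2,
                        -10.0, -10.0, -20.0, 0.0, 0.0, 0.0, 0.0])
        qhi = np.array([1.5 * D, 3.0, np.pi / 2, 10.0, 10.0, 20.0]
                       + [self.opts.force_cap] * 4)
        ulo = np.full(NU, -2000.0)
        uhi = np.full(NU, 2000.0)
        plo = np.full(NP, -1.5 * D)
        phi = np.full(NP, 2.0 * D)
        lb = np.concatenate([np.tile(qlo, K), np.tile(ulo, K), plo])
        ub = np.concatenate([np.tile(qhi, K), np.tile(uhi, K), phi])
        return lb, ub

    def nonlinear_constraints(self) -> list[NonlinearConstraint]:
        ncon_d = self.N * NQ
        lb, ub = self.path_bounds()
        return [
            NonlinearConstraint(self.defects, np.zeros(ncon_d), np.zeros(ncon_d),
                                jac=self.defects_jac),
            NonlinearConstraint(self.path, lb, ub, jac=self.path_jac),
        ]
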