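"""Planar rigid-trunk, massless-axial-leg locomotor dynamics.

The trunk is a rigid body (mass ``M``, pitch MOI ``I``) whose COM lies on
the glenoacetabular axis.  Each of the four legs is a massless, axial
actuator connecting a fixed ground point (the footfall) to its girdle joint
(acetabulum for hindlimbs, glenoid for forelimbs); leg force acts along
this axis and is reflected instantaneously in the ground reaction force
(point feet, infinite friction).  Legs can only push (F >= 0).

Sign conventions: x cranial (travel direction), z up, trunk pitch ``theta``
positive nose-up, measured from horizontal.

The module exposes both a scalar API mirroring the model's operations and
vectorized kinetics with analytic partial derivatives, which the direct
collocation transcription consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import SimpleNamespace
from typing import Literal, Sequence

import numpy as np

from .bodies import G, BodyModel

Attachment = Literal["hip", "glenoid"]

#: canonical limb ordering used throughout: left hind, right hind,
#: left fore, right fore
LIMB_NAMES = ("LH", "RH", "LF", "RF")
#: index of the contralateral limb (left/right mirror) for each limb
MIRROR = (1, 0, 3, 2)
#: True for hindlimbs in canonical order
IS_HIND = (True, True, False, False)


@dataclass
class TrunkState:
    """Planar trunk kinematic state."""

    x: float
    z: float
    theta: float
    xdot: float = 0.0
    zdot: float = 0.0
    thetadot: float = 0.0

    def __post_init__(self) -> None:
        if not -np.pi / 2 <= self.theta <= np.pi / 2:
            raise ValueError("trunk pitch must lie in [-pi/2, pi/2]")


@dataclass
class Limb:
    """One massless axial leg: its girdle attachment, maximum (anatomical)
    length, and the ground point it pushes from."""

    attachment: Attachment
    max_length: float
    foot_x: float = 0.0

    def __post_init__(self) -> None:
        if not self.max_length > 0:
            raise ValueError("max_length must be > 0")


@dataclass
class LimbForceState:
    """Axial force state of one limb: force (a state, integrated from the
    force-rate control) and accumulated impulse."""

    F: float
    Fdot: float = 0.0
    impulse: float = 0.0

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError("legs push only: F must be >= 0")


def attachment_offset(body: BodyModel, attachment: Attachment) -> float:
    """Signed distance from COM to a girdle joint along the trunk axis.

    Negative toward the hip: the COM sits ``MF' * LB`` cranial of the hip.
    """
    if attachment == "hip":
        return -body.MF_prime * body.LB
    if attachment == "glenoid":
        return (1.0 - body.MF_prime) * body.LB
    raise ValueError(f"unknown attachment {attachment!r}")


def joint_position(s: TrunkState, body: BodyModel, attachment: Attachment) -> np.ndarray:
    """Planar position of the hip or glenoid for a given trunk state."""
    b = attachment_offset(body, attachment)
    u = np.array([np.cos(s.theta), np.sin(s.theta)])
    return np.array([s.x, s.z]) + b * u


def leg_geometry(
    s: TrunkState, body: BodyModel, limb: Limb
) -> tuple[float, np.ndarray, float]:
    """Leg length, unit vector (foot to joint), and length rate.

    The length rate follows from the chain rule on the trunk states: the
    joint velocity is ``(xdot - b sin(theta) thetadot, zdot + b cos(theta)
    thetadot)`` and its projection on the leg axis is the lengthening rate.
    """
    b = attachment_offset(body, limb.attachment)
    joint = joint_position(s, body, limb.attachment)
    e = joint - np.array([limb.foot_x, 0.0])
    L = float(np.linalg.norm(e))
    if L == 0.0:
        raise ValueError("leg length is zero: axial direction undefined")
    u = e / L
    jdot = np.array(
        [s.xdot - b * np.sin(s.theta) * s.thetadot,
         s.zdot + b * np.cos(s.theta) * s.thetadot]
    )
    return L, u, float(u @ jdot)


def accelerations(
    s: TrunkState,
    body: BodyModel,
    limbs: Sequence[Limb],
    forces: Sequence[float],
    g: float = G,
) -> tuple[float, float, float]:
    """Newton-Euler trunk accelerations under axial leg forces and gravity.

    Returns ``(xddot, zddot, thetaddot)``.
    """
    ax = az = alpha = 0.0
    for limb, F in zip(limbs, forces):
        b = attachment_offset(body, limb.attachment)
        L, u, _ = leg_geometry(s, body, limb)
        ax += F * u[0] / body.M
        az += F * u[1] / body.M
        # torque of the axial force about the COM; moment arm b along trunk
        alpha += F * b * (np.cos(s.theta) * u[1] - np.sin(s.theta) * u[0]) / body.I
    return ax, az - g, alpha


def limb_power_split(F: float, length_rate: float) -> tuple[float, float]:
    """Split the axial limb power into non-negative positive / negative parts.

    ``P_plus - P_minus = F * length_rate`` and the two are never jointly
    nonzero; the objective charges both with equal weight so negative work
    cannot subsidize positive work.
    """
    P = F * length_rate
    return (P, 0.0) if P >= 0 else (0.0, -P)


# ---------------------------------------------------------------------------
# vectorized kinetics with analytic partials (used by the transcription)


def limb_kinetics(
    x: np.ndarray,
    z: np.ndarray,
    th: np.ndarray,
    vx: np.ndarray,
    vz: np.ndarray,
    om: np.ndarray,
    F: np.ndarray,
    p: np.ndarray,
    body: BodyModel,
    g: float = G,
    derivs: bool = True,
) -> SimpleNamespace:
    """Evaluate per-limb geometry, trunk accelerations, and limb power over
    a batch of ``K`` time nodes, with analytic partial derivatives.

    Parameters are arrays: trunk states of shape ``(K,)``, limb forces
    ``(K, 4)`` and footfall positions ``(4,)`` in the canonical limb order.
    Returns a namespace of value arrays, and (when ``derivs``) the partials
    of accelerations and length rates with respect to states, forces and
    footfalls, named ``d<quantity>_d<variable>``.
    """
    M, I = body.M, body.I
    b = np.array([attachment_offset(body, "hip" if h else "glenoid") for h in IS_HIND])
    c = np.cos(th)[:, None]
    s = np.sin(th)[:, None]
    ex = x[:, None] + b * c - p[None, :]
    ez = z[:, None] + b * s
    L = np.hypot(ex, ez)
    if np.any(L <= 0):
        raise ValueError("leg length is zero: axial direction undefined")
    ux, uz = ex / L, ez / L
    tau = b * (c * uz - s * ux)  # torque moment arm per unit force

    wx = vx[:, None] - b * s * om[:, None]
    wz = vz[:, None] + b * c * om[:, None]
    Ldot = ux * wx + uz * wz

    out = SimpleNamespace(
        L=L, ux=ux, uz=uz, tau=tau, Ldot=Ldot,
        ax=(F * ux).sum(axis=1) / M,
        az=(F * uz).sum(axis=1) / M - g,
        alpha=(F * tau).sum(axis=1) / I,
        power=F * Ldot,
    )
    if not derivs:
        return out

    # unit-vector partials: du = (de - u dL)/L with dL = u . de
    def u_partials(dex, dez):
        dL = ux * dex + uz * dez
        return (dex - ux * dL) / L, (dez - uz * dL) / L

    dux_dx, duz_dx = u_partials(1.0, 0.0)
    dux_dz, duz_dz = u_partials(0.0, 1.0)
    dux_dth, duz_dth = u_partials(-b * s, b * c)
    dux_dp, duz_dp = u_partials(-1.0, 0.0)

    dtau = {
        "x": b * (c * duz_dx - s * dux_dx),
        "z": b * (c * duz_dz - s * dux_dz),
        "th": b * (-s * uz + c * duz_dth - c * ux - s * dux_dth),
        "p": b * (c * duz_dp - s * dux_dp),
    }
    dU = {"x": (dux_dx, duz_dx), "z": (dux_dz, duz_dz),
          "th": (dux_dth, duz_dth), "p": (dux_dp, duz_dp)}

    for name, (dux, duz) in dU.items():
        setattr(out, f"dax_d{name}", (F * dux).sum(axis=1) / M if name != "p" else F * dux / M)
        setattr(out, f"daz_d{name}", (F * duz).sum(axis=1) / M if name != "p" else F * duz / M)
        setattr(out, f"dalpha_d{name}",
                (F * dtau[name]).sum(axis=1) / I if name != "p" else F * dtau[name] / I)
        dLdot = dux * wx + duz * wz
        if name == "th":
            dLdot = dLdot + ux * (-b * c * om[:, None]) + uz * (-b * s * om[:, None])
        setattr(out, f"dLdot_d{name}", dLdot)

    # direct force partials (per limb)
    out.dax_dF = ux / M
    out.daz_dF = uz / M
    out.dalpha_dF = tau / I
    # Ldot velocity partials
    out.dLdot_dvx = ux
    out.dLdot_dvz = uz
    out.dLdot_dom = tau
    # length partials (for complementarity constraints)
    out.dL_dx = ux
    out.dL_dz = uz
    out.dL_dth = ux * (-b * s) + uz * (b * c)
    out.dL_dp = -ux
    return out


def joint_heights(z: np.ndarray, th: np.ndarray, body: BodyModel) -> np.ndarray:
    """Hip and glenoid heights, shape ``(K, 2)`` (hip first)."""
    b_hip = attachment_offset(body, "hip")
    b_gl = attachment_offset(body, "glenoid")
    s = np.sin(th)
    return np.stack([z + b_hip * s, z + b_gl * s], axis=1)
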