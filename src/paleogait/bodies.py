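"""Quadrupedal body models and derived morphometric scalars.

A :class:`BodyModel` is the planar abstraction of a standing quadruped:
a rigid trunk spanning the glenoacetabular axis, with a massless hindlimb
hanging from the acetabulum and a massless forelimb from the glenoid.
All quantities are SI (metres, kilograms, seconds).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace, asdict
from pathlib import Path

#: standard gravitational acceleration, m/s^2
G = 9.81


class BodyModelError(ValueError):
    """Raised when body parameters violate the model's geometric invariants."""


@dataclass(frozen=True)
class BodyModel:
    """Planar body model of a standing quadruped.

    Parameters
    ----------
    name : str
        Identifier for the model (e.g. taxon name).
    LH : float
        Pes-to-acetabulum (hindlimb) length in standing, m.
    LB : float
        Glenoacetabular distance (glenoid to acetabulum along the trunk), m.
    LF : float
        Manus-to-glenoid (forelimb) length in standing, m.
    LP : float
        Pes (hind footprint) length, m.  May be ``nan`` when no autopodial
        data exist (e.g. the dog model).
    LM : float
        Manus (fore footprint) length, m.  May be ``nan``.
    MF_prime : float
        COM forelimb bias: distance from the hip to the COM along the
        glenoacetabular axis divided by ``LB``.  0 puts the COM over the
        hips, 1 over the shoulders.
    M : float
        Body mass, kg.
    I : float
        Pitch moment of inertia about the COM, kg m^2.
    """

    name: str
    LH: float
    LB: float
    LF: float
    LP: float
    LM: float
    MF_prime: float
    M: float
    I: float

    def __post_init__(self) -> None:
        for field in ("LH", "LB", "LF"):
            if not getattr(self, field) > 0:
                raise BodyModelError(f"{self.name}: {field} must be > 0")
        for field in ("LP", "LM"):
            v = getattr(self, field)
            if not (math.isnan(v) or v > 0):
                raise BodyModelError(f"{self.name}: {field} must be > 0 or NaN")
        if not self.M > 0:
            raise BodyModelError(f"{self.name}: mass must be > 0")
        if not self.I > 0:
            raise BodyModelError(f"{self.name}: pitch MOI must be > 0")
        if not 0.0 <= self.MF_prime <= 1.0:
            raise BodyModelError(f"{self.name}: MF_prime must lie in [0, 1]")
        if not abs(self.LH - self.LF) < self.LB:
            raise BodyModelError(
                f"{self.name}: |LH - LF| = {abs(self.LH - self.LF):.3g} must be "
                f"< LB = {self.LB:.3g} for the horizontal GAD to be real"
            )

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["units"] = {"lengths": "m", "M": "kg", "I": "kg m^2"}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BodyModel":
        d = {k: v for k, v in d.items() if k != "units"}
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "BodyModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def horizontal_gad(body: BodyModel) -> float:
    """Horizontal component of the glenoacetabular distance in standing.

    With the pes under the acetabulum and the manus under the glenoid, the
    trunk pitches by ``asin((LH - LF)/LB)``, so the horizontal girdle
    separation is ``LBx = sqrt(LB^2 - (LH - LF)^2)``.
    """
    return math.sqrt(body.LB**2 - (body.LH - body.LF) ** 2)


def murphy_number(body: BodyModel) -> float:
    """Normalized pitch moment of inertia, ``I / (M * (LB/2)^2)``.

    This dimensionless number measures how costly pitching the trunk is
    relative to raising and lowering it; above ~1, four-beat running gaits
    become work-optimal over trotting.
    """
    return body.I / (body.M * (body.LB / 2.0) ** 2)


def hip_height(body: BodyModel) -> float:
    """Standing hip height ``H``, taken as the pes-acetabulum length LH."""
    return body.LH


def trackmaker_hip_height(mean_pes_length: float, reference: BodyModel) -> float:
    """Estimate a trackmaker's hip height from its mean pes print length.

    Scales the reference model's hip-height-to-pes-length ratio:
    ``H = pes_len * (LH / LP)``.
    """
    if not mean_pes_length > 0:
        raise ValueError("mean_pes_length must be > 0")
    if math.isnan(reference.LP):
        raise ValueError(f"reference model {reference.name!r} has no pes length")
    return mean_pes_length * (reference.LH / reference.LP)


def scale_forelimb(body: BodyModel, factor: float) -> BodyModel:
    """Return a copy of ``body`` with the forelimb length scaled by ``factor``.

    Used for sensitivity analyses on forelimb length; all other fields are
    unchanged.  Raises :class:`BodyModelError` if the scaled model violates
    the geometric invariants.
    """
    if not factor > 0:
        raise ValueError("scale factor must be > 0")
    return replace(body, LF=body.LF * factor)
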