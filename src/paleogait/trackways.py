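"""Geometry of digitized quadrupedal trackways.

A trackway is an ordered sequence of footprints, each digitized as two
landmarks: the tip of the reference digit and the caudal-most point of the
print.  From these the module derives stride vectors (displacement between
midpoints of successive same-side pes prints), manus-pes midpoint distances
projected on the mean travel direction, the track phase ``Phi_T = d/D``, a
dynamic-similarity speed estimate, and glenoacetabular-distance estimates,
together with the analytic relation linking track phase to limb phase:

    Phi_T = mod(phi_L + LBx/D, 1)

All coordinates are planar and in metres; the frame is arbitrary (every
derived quantity is invariant under rigid motions of the landmark cloud).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .bodies import BodyModel, hip_height, trackmaker_hip_height

Limb = Literal["pes", "manus"]
Side = Literal["left", "right"]

#: Alexander-style dynamic similarity relation U' = ALPHA * D'^BETA
SPEED_COEF = 0.25
SPEED_EXP = 1.67


@dataclass
class Footprint:
    """A single digitized print: reference-digit tip and caudal-most point."""

    print_id: int
    limb: Limb
    side: Side
    tip: np.ndarray
    caudal: np.ndarray
    preserved: bool = True
    notes: str = ""

    def __post_init__(self) -> None:
        self.tip = np.asarray(self.tip, dtype=float)
        self.caudal = np.asarray(self.caudal, dtype=float)
        if self.tip.shape != (2,) or self.caudal.shape != (2,):
            raise ValueError(f"print {self.print_id}: landmarks must be 2-D points")
        if np.allclose(self.tip, self.caudal):
            raise ValueError(f"print {self.print_id}: tip and caudal coincide")


def print_length(fp: Footprint) -> float:
    """Print length: Euclidean distance from caudal landmark to digit tip."""
    return float(np.linalg.norm(fp.tip - fp.caudal))


def midpoint(fp: Footprint) -> np.ndarray:
    """Midpoint of the two landmarks; proxy for the centre of pressure."""
    return 0.5 * (fp.tip + fp.caudal)


@dataclass
class Trackway:
    """Ordered footprints in one planar frame, with optional exclusions.

    ``exclusion_ranges`` are inclusive ``(first_id, last_id)`` print-id
    ranges excluded from stride/phase statistics (e.g. a turning segment at
    the start of a trackway) but still used for print-size statistics.
    """

    name: str
    prints: list[Footprint]
    exclusion_ranges: list[tuple[int, int]] = field(default_factory=list)

    def excluded(self, print_id: int) -> bool:
        return any(lo <= print_id <= hi for lo, hi in self.exclusion_ranges)

    def select(self, limb: Limb | None = None, side: Side | None = None,
               respect_exclusions: bool = False) -> list[Footprint]:
        out = []
        for fp in self.prints:
            if limb is not None and fp.limb != limb:
                continue
            if side is not None and fp.side != side:
                continue
            if respect_exclusions and self.excluded(fp.print_id):
                continue
            out.append(fp)
        return sorted(out, key=lambda fp: fp.print_id)


def stride_vectors(tw: Trackway, limb: Limb = "pes") -> np.ndarray:
    """Displacements between midpoints of successive same-side prints.

    One vector per consecutive same-side pair of ``limb`` prints, both
    outside the exclusion ranges and adjacent in the same-side sequence.
    Returns an ``(n, 2)`` array; empty (with a warning) when no valid pair
    exists.
    """
    vecs: list[np.ndarray] = []
    for side in ("left", "right"):
        seq = tw.select(limb=limb, side=side)
        for a, b in zip(seq, seq[1:]):
            if tw.excluded(a.print_id) or tw.excluded(b.print_id):
                continue
            vecs.append(midpoint(b) - midpoint(a))
    if not vecs:
        warnings.warn(f"{tw.name}: no same-side {limb} pair for stride measurement")
        return np.empty((0, 2))
    return np.array(vecs)


def mean_stride_vector(tw: Trackway, limb: Limb = "pes") -> np.ndarray:
    """Average stride vector; defines the trackway's travel direction."""
    vecs = stride_vectors(tw, limb=limb)
    if len(vecs) == 0:
        raise ValueError(f"{tw.name}: no stride vectors available")
    return vecs.mean(axis=0)


def manus_pes_pairs(tw: Trackway) -> tuple[list[tuple[Footprint, Footprint]], list[str]]:
    """Pair each manus with the nearest caudal same-side pes within one stride.

    Returns ``(pairs, notes)`` where each pair is ``(pes, manus)``.  Manus
    prints with no resolvable pes partner are reported in ``notes`` rather
    than silently dropped.
    """
    Dav = mean_stride_vector(tw)
    D = float(np.linalg.norm(Dav))
    u = Dav / D
    pairs: list[tuple[Footprint, Footprint]] = []
    notes: list[str] = []
    for side in ("left", "right"):
        pes_prints = tw.select(limb="pes", side=side)
        if not pes_prints:
            continue
        pes_proj = [float(midpoint(p) @ u) for p in pes_prints]
        for manus in tw.select(limb="manus", side=side):
            mproj = float(midpoint(manus) @ u)
            # nearest pes caudal to the manus (small caudal overshoot of the
            # manus is tolerated: noise can place it slightly behind its pes)
            best = None
            for p, pp in zip(pes_prints, pes_proj):
                if pp <= mproj + 0.25 * D and (best is None or pp > best[1]):
                    best = (p, pp)
            if best is None or mproj - best[1] >= D:
                notes.append(
                    f"manus {manus.print_id}: no same-side pes within one stride"
                )
                continue
            pairs.append((best[0], manus))
    return pairs, notes


def manus_pes_distances(
    tw: Trackway, mode: Literal["projected", "absolute"] = "projected"
) -> np.ndarray:
    """Manus-pes midpoint distances ``d`` for every resolvable pair.

    ``projected`` (default) projects the pes-to-manus midpoint vector onto
    the trackway's mean stride direction (signed; positive = manus cranial
    to its pes).  ``absolute`` returns the unprojected norm, for trackways
    with no orthogonal view.  Excluded prints do not contribute.
    """
    Dav = mean_stride_vector(tw)
    u = Dav / np.linalg.norm(Dav)
    pairs, _ = manus_pes_pairs(tw)
    out = []
    for pes, manus in pairs:
        if tw.excluded(pes.print_id) or tw.excluded(manus.print_id):
            continue
        dvec = midpoint(manus) - midpoint(pes)
        out.append(float(dvec @ u) if mode == "projected" else float(np.linalg.norm(dvec)))
    return np.array(out)


def trailing_manus_distance(
    tw: Trackway, manus_id: int, next_pes_id: int, stride_length: float
) -> float:
    """Manus-pes distance for a trailing manus whose own pes is missing.

    Measures the midpoint distance from the manus to the *next* same-side
    pes and subtracts it from the stride length, recovering the distance to
    the (unpreserved) pes of the manus's own set.
    """
    by_id = {fp.print_id: fp for fp in tw.prints}
    manus, pes = by_id[manus_id], by_id[next_pes_id]
    dist = float(np.linalg.norm(midpoint(manus) - midpoint(pes)))
    if dist > stride_length:
        raise ValueError(
            f"manus {manus_id} is {dist:.3f} m from pes {next_pes_id}, "
            f"farther than the stride length {stride_length:.3f} m"
        )
    return stride_length - dist


def ipd_to_midpoint_distance(ipd: float, pes_len: float, manus_len: float) -> float:
    """Convert an inter-print distance (caudal pes edge to cranial manus edge
    gap) to a midpoint-to-midpoint distance: ``(pes + manus)/2 + IPD``."""
    return 0.5 * (pes_len + manus_len) + ipd


def track_phase(d: float, D: float) -> float:
    """Track phase ``Phi_T = d/D``, wrapped into [0, 1)."""
    if not D > 0:
        raise ValueError("stride length D must be > 0")
    return (d / D) % 1.0


def estimate_speed(D: float, H: float) -> float:
    """Dimensionless speed ``U' = 0.25 (D/H)^1.67`` from dynamic similarity.

    ``D`` is the stride length and ``H`` the (estimated) hip height; the
    result is speed normalized by ``sqrt(g H)``.
    """
    if not H > 0:
        raise ValueError("hip height H must be > 0")
    if D < 0:
        raise ValueError("stride length D must be >= 0")
    return SPEED_COEF * (D / H) ** SPEED_EXP


def analytic_track_phase(phi_L: float, LBx: float, D: float) -> float:
    """Track phase implied by limb phase for a steady symmetric gait:
    ``Phi_T = mod(phi_L + LBx/D, 1)``."""
    if not D > 0:
        raise ValueError("stride length D must be > 0")
    return (phi_L + LBx / D) % 1.0


def limb_phase_candidates(phi_T: float, LBx: float, D: float) -> float:
    """Invert the analytic track-phase relation: ``mod(Phi_T - LBx/D, 1)``."""
    if not D > 0:
        raise ValueError("stride length D must be > 0")
    return (phi_T - LBx / D) % 1.0


def gad_from_trot(d: float, D: float) -> float:
    """Horizontal glenoacetabular distance assuming a trot with quadruple
    stance: ``LBx = d + D/2``.  Only meaningful for slow trackways
    (estimated dimensionless speed below ~0.4)."""
    if not D > 0:
        raise ValueError("stride length D must be > 0")
    return d + D / 2.0


# ---------------------------------------------------------------------------
# summaries


@dataclass
class Stat:
    """Mean / SD / count triple for one measured quantity."""

    mean: float
    sd: Optional[float]
    n: int

    @classmethod
    def of(cls, values: Sequence[float]) -> Optional["Stat"]:
        vals = np.asarray(values, dtype=float)
        if vals.size == 0:
            return None
        sd = float(vals.std(ddof=1)) if vals.size > 1 else None
        return cls(mean=float(vals.mean()), sd=sd, n=int(vals.size))


@dataclass
class TrackwaySummary:
    """Per-trackway aggregate measurements and derived gait parameters."""

    name: str
    pes_length: Optional[Stat]
    manus_length: Optional[Stat]
    mp_distance: Optional[Stat]
    stride: Optional[Stat]
    track_phase: Optional[float]
    hip_height: Optional[float]
    nondim_stride: Optional[float]
    speed: Optional[float]
    stride_source: Literal["pes", "manus", "given"] = "pes"
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.track_phase is not None and not 0 <= self.track_phase < 1:
            raise ValueError("track phase must lie in [0, 1)")


def summary_from_means(
    name: str,
    pes_length: float,
    manus_length: Optional[float],
    mp_distance: Optional[float],
    stride: float,
    reference: BodyModel,
) -> TrackwaySummary:
    """Build a summary from published per-trackway mean values.

    The track phase is mean d over mean D; the hip height scales the
    reference model to the mean pes print; the speed follows the dynamic
    similarity relation.
    """
    H = trackmaker_hip_height(pes_length, reference)
    phase = track_phase(mp_distance, stride) if mp_distance is not None else None
    return TrackwaySummary(
        name=name,
        pes_length=Stat(pes_length, None, 1),
        manus_length=Stat(manus_length, None, 1) if manus_length is not None else None,
        mp_distance=Stat(mp_distance, None, 1) if mp_distance is not None else None,
        stride=Stat(stride, None, 1),
        track_phase=phase,
        hip_height=H,
        nondim_stride=stride / H,
        speed=estimate_speed(stride, H),
        stride_source="given",
    )


def _align_wrap_branches(d: np.ndarray, D: float) -> np.ndarray:
    """Re-express manus-pes distances on a common wrap branch.

    Distances differing by a whole stride describe the same print geometry
    (a manus almost overstepping the next pes may pair to either pes under
    noise), but mixing branches corrupts the arithmetic mean.  Each value
    is shifted by the multiple of ``D`` that brings it nearest the circular
    mean of the distances modulo ``D``.
    """
    d = np.asarray(d, dtype=float)
    ang = (d % D) * (2.0 * np.pi / D)
    centre = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) * D / (2.0 * np.pi)
    delta = ((d - centre + D / 2.0) % D) - D / 2.0
    return centre + delta


def summarize(tw: Trackway, reference: BodyModel) -> TrackwaySummary:
    """Aggregate a digitized trackway into gait parameters.

    Print-size statistics use *all* preserved prints (including those inside
    exclusion ranges); stride and phase statistics respect the exclusions.
    When no same-side pes pair exists, same-side manus displacements provide
    the stride (flagged via ``stride_source``).  Missing manus data yield a
    summary with absent ``d``/track-phase fields rather than an error.
    """
    notes: list[str] = []
    pes_stat = Stat.of([print_length(fp) for fp in tw.select(limb="pes")
                        if fp.preserved])
    manus_stat = Stat.of([print_length(fp) for fp in tw.select(limb="manus")
                          if fp.preserved])

    stride_source: Literal["pes", "manus"] = "pes"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        svecs = stride_vectors(tw, limb="pes")
    if len(svecs) == 0:
        svecs = stride_vectors(tw, limb="manus")
        stride_source = "manus"
        notes.append("stride measured from same-side manus prints")
    stride_stat = Stat.of(np.linalg.norm(svecs, axis=1)) if len(svecs) else None

    d_stat = None
    if any(fp.limb == "manus" for fp in tw.prints) and stride_stat is not None:
        try:
            dvals = manus_pes_distances(tw)
        except ValueError:
            dvals = np.array([])
        _, pair_notes = manus_pes_pairs(tw) if len(dvals) else ([], [])
        notes.extend(pair_notes)
        if len(dvals) > 1 and stride_stat is not None:
            dvals = _align_wrap_branches(dvals, stride_stat.mean)
        d_stat = Stat.of(dvals)

    phase = H = DH = UH = None
    if stride_stat is not None:
        if d_stat is not None:
            phase = track_phase(d_stat.mean, stride_stat.mean)
        if pes_stat is not None:
            H = trackmaker_hip_height(pes_stat.mean, reference)
            DH = stride_stat.mean / H
            UH = estimate_speed(stride_stat.mean, H)

    return TrackwaySummary(
        name=tw.name,
        pes_length=pes_stat,
        manus_length=manus_stat,
        mp_distance=d_stat,
        stride=stride_stat,
        track_phase=phase,
        hip_height=H,
        nondim_stride=DH,
        speed=UH,
        stride_source=stride_source,
        notes=notes,
    )


def extend_caudal_point(fp: Footprint, target_length: float) -> Footprint:
    """Return a copy of a cropped print with the caudal landmark extended
    along the print axis so the print reaches ``target_length``.

    An explicit, provenance-recorded edit for prints whose caudal portion
    was cropped in the source image; never applied automatically.
    """
    axis = fp.tip - fp.caudal
    axis = axis / np.linalg.norm(axis)
    new_caudal = fp.tip - target_length * axis
    return Footprint(
        print_id=fp.print_id,
        limb=fp.limb,
        side=fp.side,
        tip=fp.tip.copy(),
        caudal=new_caudal,
        preserved=fp.preserved,
        notes=(fp.notes + "; " if fp.notes else "")
        + f"caudal point extended to length {target_length:.3f} m",
    )
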