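"""Readers, writers and report assembly.

File formats: landmark CSV (two rows per print: tip and caudal), body-model
JSON, trackway-summary CSV, gait-atlas CSV, and a long-format comparison
table of track phase against speed from simulation, trackways and the
analytic trot relation.  All file numerics are SI; display rounding happens
only in report files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .bodies import BodyModel, horizontal_gad, hip_height
from .trackways import (
    Footprint,
    Trackway,
    TrackwaySummary,
    analytic_track_phase,
    summary_from_means,
)

LANDMARK_COLUMNS = [
    "trackway", "print_id", "limb", "side", "landmark", "x_m", "y_m",
    "preserved", "notes",
]


class LandmarkSchemaError(ValueError):
    """Landmark CSV fails schema validation."""


def write_landmarks(trackways: Sequence[Trackway], path: str | Path) -> None:
    rows = []
    for tw in trackways:
        for fp in tw.prints:
            for lm_name, pt in (("tip", fp.tip), ("caudal", fp.caudal)):
                rows.append([tw.name, fp.print_id, fp.limb, fp.side, lm_name,
                             pt[0], pt[1], int(fp.preserved), fp.notes])
    pd.DataFrame(rows, columns=LANDMARK_COLUMNS).to_csv(path, index=False)


def read_landmarks(path: str | Path) -> list[Trackway]:
    """Parse and validate a landmark CSV into trackways.

    Each print must contribute exactly one ``tip`` and one ``caudal`` row;
    violations are reported with the offending trackway and print id.
    """
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    missing = set(LANDMARK_COLUMNS) - set(df.columns)
    if missing:
        raise LandmarkSchemaError(f"missing columns: {sorted(missing)}")
    bad_limb = set(df["limb"]) - {"pes", "manus"}
    if bad_limb:
        raise LandmarkSchemaError(f"invalid limb values: {sorted(bad_limb)}")
    bad_side = set(df["side"]) - {"left", "right"}
    if bad_side:
        raise LandmarkSchemaError(f"invalid side values: {sorted(bad_side)}")
    bad_lm = set(df["landmark"]) - {"tip", "caudal"}
    if bad_lm:
        raise LandmarkSchemaError(f"invalid landmark values: {sorted(bad_lm)}")

    trackways = []
    for name, group in df.groupby("trackway", sort=False):
        prints = []
        for pid, rows in group.groupby("print_id", sort=True):
            counts = rows["landmark"].value_counts().to_dict()
            if counts.get("tip", 0) != 1 or counts.get("caudal", 0) != 1:
                raise LandmarkSchemaError(
                    f"trackway {name!r} print {pid}: needs exactly one tip and "
                    f"one caudal landmark, got {counts}"
                )
            limbs = rows["limb"].unique()
            sides = rows["side"].unique()
            if len(limbs) != 1 or len(sides) != 1:
                raise LandmarkSchemaError(
                    f"trackway {name!r} print {pid}: inconsistent limb/side labels"
                )
            tip = rows.loc[rows["landmark"] == "tip", ["x_m", "y_m"]].to_numpy()[0]
            caudal = rows.loc[rows["landmark"] == "caudal", ["x_m", "y_m"]].to_numpy()[0]
            prints.append(Footprint(
                print_id=int(pid), limb=limbs[0], side=sides[0],
                tip=tip.astype(float), caudal=caudal.astype(float),
                preserved=bool(rows["preserved"].iloc[0]),
                notes=str(rows["notes"].iloc[0]),
            ))
        trackways.append(Trackway(name=str(name), prints=prints))
    return trackways


def read_body(path: str | Path) -> BodyModel:
    """Load a body model from JSON, enforcing the geometric invariants."""
    return BodyModel.from_json(path)


def write_body(body: BodyModel, path: str | Path) -> None:
    body.to_json(path)


# ---------------------------------------------------------------------------
# reports


def _round2(x: Optional[float]) -> Optional[float]:
    return None if x is None else round(float(x), 2)


def summary_to_row(s: TrackwaySummary) -> dict:
    def stat(st):
        if st is None:
            return (None, None, 0)
        return (_round2(st.mean), _round2(st.sd), st.n)

    pes, pes_sd, pes_n = stat(s.pes_length)
    man, man_sd, man_n = stat(s.manus_length)
    d, d_sd, d_n = stat(s.mp_distance)
    D, D_sd, D_n = stat(s.stride)
    return dict(
        trackway=s.name,
        pes_length=pes, pes_length_sd=pes_sd, pes_length_n=pes_n,
        manus_length=man, manus_length_sd=man_sd, manus_length_n=man_n,
        mp_distance=d, mp_distance_sd=d_sd, mp_distance_n=d_n,
        stride=D, stride_sd=D_sd, stride_n=D_n,
        track_phase=_round2(s.track_phase),
        est_speed=_round2(s.speed),
        stride_source=s.stride_source,
    )


def report_table2(
    summaries: Sequence[TrackwaySummary], path: Optional[str | Path] = None
) -> pd.DataFrame:
    """Trackway summary report: per-trackway sizes, stride, track phase and
    recomputed speed, rounded to two decimals as in the published table."""
    cols = list(summary_to_row(TrackwaySummary(
        name="", pes_length=None, manus_length=None, mp_distance=None,
        stride=None, track_phase=None, hip_height=None, nondim_stride=None,
        speed=None)).keys())
    df = pd.DataFrame([summary_to_row(s) for s in summaries], columns=cols)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def summaries_from_table(table: pd.DataFrame, reference: BodyModel) -> list[TrackwaySummary]:
    """Recompute summaries (phase, hip height, speed) from published
    per-trackway mean measurements."""
    out = []
    for row in table.itertuples():
        out.append(summary_from_means(
            name=str(row.track_id),
            pes_length=float(row.pes_length_mean),
            manus_length=(None if pd.isna(row.manus_length_mean)
                          else float(row.manus_length_mean)),
            mp_distance=(None if pd.isna(row.mp_distance_mean)
                         else float(row.mp_distance_mean)),
            stride=float(row.stride_mean),
            reference=reference,
        ))
    return out


def report_comparison(
    atlas: pd.DataFrame,
    summaries: Sequence[TrackwaySummary],
    body: BodyModel,
    path: Optional[str | Path] = None,
    trot_speed_grid: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Long-format (speed, track phase, source) table.

    Sources: ``simulation`` (gait-atlas rows), ``trackway`` (published or
    digitized trackway summaries) and ``analytic-trot`` (the track phase a
    trot implies at each speed through the stride-speed relation).
    """
    from .optimize import stride_from_speed  # local import avoids cycle

    rows = []
    for r in atlas.itertuples():
        rows.append(dict(U_H=float(r.U_H), track_phase=float(r.track_phase),
                         source="simulation"))
    for s in summaries:
        if s.speed is not None and s.track_phase is not None:
            rows.append(dict(U_H=s.speed, track_phase=s.track_phase,
                             source="trackway"))
    H = hip_height(body)
    LBx = horizontal_gad(body)
    grid = (trot_speed_grid if trot_speed_grid is not None
            else np.linspace(0.05, 2.0, 79))
    for U_H in grid:
        D = stride_from_speed(float(U_H)) * H
        rows.append(dict(U_H=float(U_H),
                         track_phase=analytic_track_phase(0.5, LBx, D),
                         source="analytic-trot"))
    df = pd.DataFrame(rows, columns=["U_H", "track_phase", "source"])
    if path is not None:
        df.to_csv(path, index=False)
    return df


# ---------------------------------------------------------------------------
# provenance


@dataclass
class RunManifest:
    """Provenance record written alongside every CLI output."""

    command: str
    config: dict
    seeds: list[int]
    version: str = __version__
    input_digests: dict[str, str] = field(default_factory=dict)
    timestamp: str = field(default_factory=lambda: time.strftime(
        "%Y-%m-%dT%H:%M:%S", time.gmtime()))

    @staticmethod
    def digest(path: str | Path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]

    @classmethod
    def create(cls, command: Optional[str] = None, config: Optional[dict] = None,
               seeds: Sequence[int] = (), inputs: Sequence[str | Path] = ()) -> "RunManifest":
        return cls(
            command=command if command is not None else " ".join(sys.argv),
            config=config or {},
            seeds=list(int(s) for s in seeds),
            input_digests={str(p): cls.digest(p) for p in inputs},
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, default=str) + "\n")


def manifest_path(output: str | Path) -> Path:
    out = Path(output)
    return out.with_name(out.name + ".manifest.json")
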