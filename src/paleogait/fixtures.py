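"""Built-in reference data: body models and published chirotheriid trackway summaries.

Two complete planar body models are shipped: *Batrachotomus kupferzellensis*
(a long-limbed Middle Triassic pseudosuchian, parameters from a volumetric
reconstruction) and a Belgian Malinois dog (a living cursorial quadruped used
to validate the gait predictions).  The trackway table collects published
summary statistics for Triassic *Isochirotherium* and *Brachychirotherium*
trackways: per-trackway mean pes/manus print lengths, manus-pes midpoint
distance ``d``, stride length ``D``, and the derived track phase and
dimensionless speed.
"""

from __future__ import annotations

import math

import pandas as pd

from .bodies import BodyModel

__all__ = ["BATRACHOTOMUS", "DOG", "body_models", "trackway_table"]

BATRACHOTOMUS = BodyModel(
    name="Batrachotomus",
    LH=0.76,
    LB=0.80,
    LF=0.46,
    LP=0.26,
    LM=0.15,
    MF_prime=0.31,
    M=142.0,
    I=69.0,
)

DOG = BodyModel(
    name="Belgian Malinois dog",
    LH=0.48,
    LB=0.48,
    LF=0.44,
    LP=math.nan,
    LM=math.nan,
    MF_prime=0.63,
    M=28.0,
    I=1.35,
)


def body_models() -> dict[str, BodyModel]:
    """Return the shipped body models keyed by short name."""
    return {"batrachotomus": BATRACHOTOMUS, "dog": DOG}


# Published per-trackway summary statistics.  Columns *_mean in metres,
# *_sd in metres (NaN when the source reports a single value), *_n counts.
# track_phase and est_speed are the values printed in the source compilation,
# re-derivable as d/D and the dynamic-similarity speed estimate.
_TRACKWAY_ROWS = [
    # ichnogenus, track_id, age, pes(mean, sd, n), manus(mean, sd, n),
    # d(mean, sd, n), stride(mean, sd, n), track_phase, est_speed, provenance
    ("Isochirotherium", "12", "MT,A", 0.34, None, 1, 0.12, None, 1,
     0.24, None, 1, 1.68, None, 1, 0.14, 0.60, "table"),
    ("Isochirotherium", "1", "MT,A", 0.22, None, 1, 0.10, None, 1,
     0.17, None, 1, 1.28, None, 1, 0.13, 0.79, "table"),
    ("Isochirotherium", "-", "MT,A", 0.24, None, 1, 0.08, None, 1,
     0.19, None, 1, 1.30, None, 1, 0.15, 0.70, "table"),
    ("Isochirotherium", "per-set table", "MT,A", 0.34, 0.02, 34, 0.12, 0.01, 34,
     0.23, 0.03, 34, 1.68, 0.03, 11, 0.14, 0.60, "table"),
    ("Isochirotherium", "SLID_1", "ET/MT,S/A", 0.29, 0.03, 14, 0.10, None, 1,
     0.28, None, 1, 1.20, 0.07, 11, 0.23, 0.45, "figure"),
    ("Isochirotherium", "BWF_5", "ET/MT,S/A", 0.28, 0.02, 5, 0.08, None, 1,
     0.51, None, 1, 1.08, 0.07, 4, 0.47, 0.40, "figure"),
    ("Brachychirotherium", "BsZ-A", "LT,C", 0.32, 0.02, 10, 0.09, 0.01, 8,
     0.24, 0.03, 8, 1.49, 0.04, 8, 0.16, 0.54, "table"),
    ("Brachychirotherium", "BsZ-D", "LT,C", 0.24, 0.00, 3, 0.12, 0.01, 3,
     0.22, 0.01, 3, 1.41, None, 1, 0.16, 0.80, "table"),
    ("Brachychirotherium", "R1", "LT", 0.39, 0.03, 3, 0.20, None, 2,
     0.56, None, 2, 1.29, None, 1, 0.43, 0.31, "figure"),
    ("Brachychirotherium", "R2-t1", "LT", 0.30, 0.03, 7, 0.11, 0.02, 6,
     0.26, 0.04, 4, 1.23, 0.08, 3, 0.21, 0.44, "figure"),
    ("Brachychirotherium", "R2-t5", "LT", 0.24, 0.03, 11, 0.08, 0.02, 9,
     0.25, 0.03, 9, 0.91, 0.04, 8, 0.27, 0.39, "figure"),
    ("Brachychirotherium", "R2-t9", "LT", 0.33, 0.07, 5, 0.12, None, 2,
     0.33, None, 2, 1.29, 0.04, 4, 0.26, 0.41, "figure"),
    ("Brachychirotherium", "NMMNH P-48756", "LT,N", 0.15, 0.01, 3, 0.04, 0.01, 3,
     0.09, 0.01, 3, 0.98, None, 1, 0.09, 0.96, "figure"),
    ("Brachychirotherium", "CDUE 802-808", "LT,C", 0.12, 0.01, 4, 0.05, 0.01, 5,
     0.13, 0.01, 4, 1.19, 0.04, 4, 0.11, 1.92, "figure"),
]

_COLUMNS = [
    "ichnogenus", "track_id", "age",
    "pes_length_mean", "pes_length_sd", "pes_length_n",
    "manus_length_mean", "manus_length_sd", "manus_length_n",
    "mp_distance_mean", "mp_distance_sd", "mp_distance_n",
    "stride_mean", "stride_sd", "stride_n",
    "track_phase", "est_speed", "provenance",
]


def trackway_table() -> pd.DataFrame:
    """Published chirotheriid trackway summary statistics as a DataFrame."""
    df = pd.DataFrame(_TRACKWAY_ROWS, columns=_COLUMNS)
    for c in df.columns:
        if c.endswith("_sd"):
            df[c] = df[c].astype(float)
    return df
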