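"""Scalar cochlear measures derived from A/B segment measurements.

Each cochlea is measured along the A-axis (largest basal-turn diameter
through the round window and modiolar axis) and the perpendicular B-axis
as seven consecutive segments per axis.  From these the lateral-wall and
modiolar-wall diameters and the round-window distance follow by
summation:

    A_lat = sum(A1..A7)          B_lat = sum(B1..B7)
    A_mod = A_lat - A1 - A7      B_mod = B_lat - B1 - B7
    r0    = sum(A1..A4)

Population dispersion is summarized by the coefficient of variation
cv = sd / mean, and values are compared across cochleae after
normalization to the population mean, x_norm = (x - mean) / mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SegmentMeasurements",
    "DerivedMeasures",
    "PopulationSummary",
    "MissingSegmentError",
    "derive_measures",
    "normalize_to_mean",
    "summarize",
    "read_measurements_csv",
    "write_measurements_csv",
    "derive_measures_table",
    "write_derived_csv",
]

METHODS = ("corrosion", "clinical_ct", "micro_ct")
SIDES = ("left", "right")

SEGMENT_COLUMNS = [f"A{i}" for i in range(1, 8)] + [f"B{i}" for i in range(1, 8)]
MEASUREMENT_COLUMNS = ["id", "side", "method"] + SEGMENT_COLUMNS
DERIVED_COLUMNS = ["id", "side", "method", "A_lat", "B_lat", "A_mod", "B_mod", "r0"]


class MissingSegmentError(ValueError):
    """A required A/B segment is absent."""


@dataclass(frozen=True)
class SegmentMeasurements:
    """Raw per-cochlea segment measurements (mm); NaN marks a missing slot."""

    cochlea_id: str
    side: str
    method: str
    A_segments: tuple
    B_segments: tuple

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        for name, segs in (("A", self.A_segments), ("B", self.B_segments)):
            segs = tuple(float(s) for s in segs)
            object.__setattr__(self, f"{name}_segments", segs)
            if len(segs) != 7:
                raise ValueError(f"{name}_segments must have exactly 7 slots")
            if any((not math.isnan(s)) and s <= 0 for s in segs):
                raise ValueError(f"all present {name} segments must be positive")

    def missing_slots(self) -> list[str]:
        out = [f"A{i+1}" for i, s in enumerate(self.A_segments) if math.isnan(s)]
        out += [f"B{i+1}" for i, s in enumerate(self.B_segments) if math.isnan(s)]
        return out


@dataclass(frozen=True)
class DerivedMeasures:
    """Lateral/modiolar diameters and round-window distance (mm)."""

    A_lat: float
    B_lat: float
    A_mod: float
    B_mod: float
    r0: float

    def __post_init__(self) -> None:
        if not (self.A_lat > self.A_mod > 0):
            raise ValueError("requires A_lat > A_mod > 0")
        if not (self.B_lat > self.B_mod > 0):
            raise ValueError("requires B_lat > B_mod > 0")
        if not (self.r0 < self.A_lat):
            raise ValueError("requires r0 < A_lat")


@dataclass(frozen=True)
class PopulationSummary:
    """n, mean, sample SD and coefficient of variation of one measure."""

    n: int
    mean: float
    sd: float
    cv: float


def derive_measures(segments: SegmentMeasurements) -> DerivedMeasures:
    """Summation formulas mapping the 14 segments to the 5 derived measures."""
    missing = segments.missing_slots()
    if missing:
        raise MissingSegmentError(f"missing segment(s): {', '.join(missing)}")
    A = segments.A_segments
    B = segments.B_segments
    a_lat = float(sum(A))
    b_lat = float(sum(B))
    return DerivedMeasures(
        A_lat=a_lat,
        B_lat=b_lat,
        A_mod=a_lat - A[0] - A[6],
        B_mod=b_lat - B[0] - B[6],
        r0=float(sum(A[:4])),
    )


def normalize_to_mean(x, mean: float):
    """Relative deviation from the population mean, (x - mean) / mean."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    return (np.asarray(x, float) - mean) / mean if np.ndim(x) else (float(x) - mean) / mean


def summarize(values: Sequence[float]) -> PopulationSummary:
    """Mean, sample SD and CV of a population of positive lengths.

    Missing entries (NaN) are skipped; at least two present values are
    required.
    """
    v = np.asarray(list(values), float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("need at least 2 non-missing values to summarize")
    if np.any(v <= 0):
        raise ValueError("all values must be positive")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    return PopulationSummary(n=int(v.size), mean=mean, sd=sd, cv=sd / mean)


# ---------------------------------------------------------------------------
# delimited-text interfaces
# ---------------------------------------------------------------------------

def read_measurements_csv(path: str | Path) -> pd.DataFrame:
    """Read a measurement table: id, side, method, A1..A7, B1..B7 (mm).

    Empty cells are missing values (NaN).
    """
    df = pd.read_csv(path, dtype={"id": str})
    missing_cols = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"measurement CSV lacks columns: {missing_cols}")
    df = df[MEASUREMENT_COLUMNS]
    bad_side = ~df["side"].isin(SIDES)
    bad_method = ~df["method"].isin(METHODS)
    if bad_side.any() or bad_method.any():
        raise ValueError("invalid side/method labels in measurement CSV")
    return df


def write_measurements_csv(df: pd.DataFrame, path: str | Path) -> None:
    df[MEASUREMENT_COLUMNS].to_csv(path, index=False)


def rows_to_records(df: pd.DataFrame) -> Iterable[SegmentMeasurements]:
    for _, row in df.iterrows():
        yield SegmentMeasurements(
            cochlea_id=str(row["id"]),
            side=row["side"],
            method=row["method"],
            A_segments=tuple(row[f"A{i}"] for i in range(1, 8)),
            B_segments=tuple(row[f"B{i}"] for i in range(1, 8)),
        )


def derive_measures_table(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized derive_measures over a measurement table.

    Rows with missing segments get NaN derived values (no imputation);
    the count of such rows is available as ``result.attrs['n_incomplete']``.
    """
    a_cols = [f"A{i}" for i in range(1, 8)]
    b_cols = [f"B{i}" for i in range(1, 8)]
    out = df[["id", "side", "method"]].copy()
    A = df[a_cols].to_numpy(float)
    B = df[b_cols].to_numpy(float)
    complete = ~(np.isnan(A).any(axis=1) | np.isnan(B).any(axis=1))
    out["A_lat"] = A.sum(axis=1)
    out["B_lat"] = B.sum(axis=1)
    out["A_mod"] = out["A_lat"] - A[:, 0] - A[:, 6]
    out["B_mod"] = out["B_lat"] - B[:, 0] - B[:, 6]
    out["r0"] = A[:, :4].sum(axis=1)
    out.loc[~complete, ["A_lat", "B_lat", "A_mod", "B_mod", "r0"]] = np.nan
    out.attrs["n_incomplete"] = int((~complete).sum())
    return out


def write_derived_csv(df: pd.DataFrame, path: str | Path) -> None:
    df[DERIVED_COLUMNS].to_csv(path, index=False)
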