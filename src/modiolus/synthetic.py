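"""Synthetic cochlear cohorts with the study's statistical structure.

No individual-level measurement data accompany the published summary
statistics, so every pipeline stage is exercised on synthetic cohorts:
correlated (A_lat, B_lat, A_mod, B_mod) vectors drawn from a truncated
multivariate normal calibrated to the printed means, SDs and
correlations of the three measurement methods, decomposed into plausible
A1..A7 / B1..B7 segment tables, with an optional measurement-noise /
soft-tissue-offset model emulating the clinical-CT contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .measures import MEASUREMENT_COLUMNS, DerivedMeasures, SegmentMeasurements

__all__ = [
    "SyntheticPopulationConfig",
    "MethodNoiseProfile",
    "PROFILES",
    "CLINICAL_NOISE",
    "population_config",
    "generate_population",
    "generate_segments",
    "segment_table",
    "generate_cohort",
    "add_measurement_noise",
]

MEASURE_COLUMNS = ["A_lat", "B_lat", "A_mod", "B_mod"]

#: default cross-axis correlation corr(A_lat, B_lat); the A and B lateral
#: dimensions co-vary strongly (shared overall cochlear size)
AXIS_CROSS_CORR = 0.8


def build_correlation(lat_mod_corr: float, axis_cross: float = AXIS_CROSS_CORR) -> np.ndarray:
    """4x4 correlation of (A_lat, B_lat, A_mod, B_mod).

    Off-diagonals not pinned by the two inputs follow a shared-size
    factor structure (products of the pinned entries); the result is
    projected to the nearest positive-definite correlation matrix if
    sampling noise in the inputs makes it indefinite.
    """
    c = np.eye(4)
    c[0, 1] = axis_cross
    c[0, 2] = lat_mod_corr
    c[1, 3] = lat_mod_corr
    c[0, 3] = c[1, 2] = axis_cross * lat_mod_corr
    c[2, 3] = axis_cross
    c = np.maximum(c, c.T)
    return _nearest_pd_correlation(c)


def _nearest_pd_correlation(c: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    vals, vecs = np.linalg.eigh(c)
    if vals.min() > eps:
        return c
    vals = np.clip(vals, eps, None)
    c = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(c))
    return c / np.outer(d, d)


@dataclass(frozen=True)
class MethodNoiseProfile:
    """Systematic soft-tissue offset plus additive measurement noise.

    Corrosion casts mould the soft tissue around the modiolus into the
    cast, whereas CT sees only bone: clinical modiolar measures are
    systematically smaller.  ``offset_A_mod``/``offset_B_mod`` are
    subtracted from the modiolar columns; ``noise_sd`` is the SD of
    zero-mean Gaussian noise added to every measure.
    """

    offset_A_mod: float = 0.0
    offset_B_mod: float = 0.0
    noise_sd: float = 0.0


#: calibration emulating the corrosion-cast -> clinical-CT contrast
CLINICAL_NOISE = MethodNoiseProfile(offset_A_mod=0.8, offset_B_mod=0.35, noise_sd=0.1)


@dataclass(frozen=True)
class SyntheticPopulationConfig:
    """Calibration of one synthetic cohort."""

    n: int
    mean: tuple  # (A_lat, B_lat, A_mod, B_mod) in mm
    sd: tuple
    correlation: np.ndarray
    method: str = "corrosion"
    noise: MethodNoiseProfile = field(default_factory=MethodNoiseProfile)
    seed: int = 0
    truncation_sd: float = 4.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("cohort size n must be >= 2")
        mean = tuple(float(m) for m in self.mean)
        sd = tuple(float(s) for s in self.sd)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", sd)
        if len(mean) != 4 or len(sd) != 4:
            raise ValueError("mean and sd must have 4 entries (A_lat, B_lat, A_mod, B_mod)")
        if any(s <= 0 for s in sd):
            raise ValueError("all sds must be positive")
        c = np.asarray(self.correlation, float)
        object.__setattr__(self, "correlation", c)
        if c.shape != (4, 4) or not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1):
            raise ValueError("correlation must be symmetric 4x4 with unit diagonal")
        if np.linalg.eigvalsh(c).min() <= 0:
            raise ValueError("correlation matrix must be positive definite")


#: printed calibration of the three datasets: means/SDs of
#: (A_lat, B_lat, A_mod, B_mod) in mm and the lateral-modiolar correlation
PROFILES: dict[str, dict] = {
    "corrosion": {
        "mean": (9.24, 6.80, 5.46, 3.17),
        "sd": (0.42, 0.36, 0.32, 0.32),
        "lat_mod_corr": 0.7,
        "method": "corrosion",
    },
    "clinical": {
        "mean": (9.18, 6.99, 4.66, 2.82),
        "sd": (0.40, 0.31, 0.34, 0.26),
        "lat_mod_corr": 0.37,
        "method": "clinical_ct",
    },
    "microct": {
        "mean": (9.60, 7.14, 5.04, 2.91),
        "sd": (0.31, 0.34, 0.31, 0.32),
        "lat_mod_corr": 0.7,
        "method": "micro_ct",
    },
}


def population_config(profile: str, n: int = 108, seed: int = 0) -> SyntheticPopulationConfig:
    """Packaged calibration profile ('corrosion', 'clinical' or 'microct')."""
    try:
        p = PROFILES[profile]
    except KeyError:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    return SyntheticPopulationConfig(
        n=n,
        mean=p["mean"],
        sd=p["sd"],
        correlation=build_correlation(p["lat_mod_corr"]),
        method=p["method"],
        seed=seed,
    )


def generate_population(config: SyntheticPopulationConfig) -> pd.DataFrame:
    """Draw n (A_lat, B_lat, A_mod, B_mod) vectors for one cohort.

    Truncated multivariate normal: draws beyond ``truncation_sd`` SDs on
    any coordinate, non-positive, or violating the physical ordering
    A_lat > A_mod / B_lat > B_mod are rejected and redrawn.
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    mean = np.asarray(config.mean)
    sd = np.asarray(config.sd)
    cov = config.correlation * np.outer(sd, sd)
    rows = []
    need = config.n
    while need > 0:
        draw = rng.multivariate_normal(mean, cov, size=max(2 * need, 16),
                                       method="cholesky")
        z_ok = np.all(np.abs(draw - mean) <= config.truncation_sd * sd, axis=1)
        order_ok = (draw[:, 0] > draw[:, 2]) & (draw[:, 1] > draw[:, 3])
        pos_ok = np.all(draw > 0, axis=1)
        good = draw[z_ok & order_ok & pos_ok]
        rows.append(good[:need])
        need -= len(good[:need])
    vals = np.vstack(rows)
    df = pd.DataFrame(vals, columns=MEASURE_COLUMNS)
    df.insert(0, "method", config.method)
    df.insert(0, "side", np.where(rng.random(config.n) < 0.5, "left", "right"))
    df.insert(0, "id", [f"{config.method}-{i:04d}" for i in range(config.n)])
    return df


def generate_segments(
    measures: DerivedMeasures,
    seed: int | np.random.Generator = 0,
    cochlea_id: str = "synthetic",
    side: str = "left",
    method: str = "corrosion",
) -> SegmentMeasurements:
    """Random segment decomposition consistent with the derived measures.

    A1 and A7 are positive random fractions summing exactly to
    A_lat - A_mod; A2..A6 split A_mod by a symmetric Dirichlet
    composition (likewise for B), so deriving measures from the output
    reproduces the input.
    """
    if measures.A_mod >= measures.A_lat or measures.B_mod >= measures.B_lat:
        raise ValueError("modiolar measures must be smaller than lateral ones")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def split(outer: float, inner: float) -> tuple:
        first = float(outer * rng.beta(4.0, 4.0))
        last = outer - first
        w = rng.dirichlet(np.full(5, 4.0))
        mid = inner * w
        mid[-1] = inner - mid[:-1].sum()  # exact sum
        return (first, *mid, last)

    return SegmentMeasurements(
        cochlea_id=cochlea_id,
        side=side,
        method=method,
        A_segments=split(measures.A_lat - measures.A_mod, measures.A_mod),
        B_segments=split(measures.B_lat - measures.B_mod, measures.B_mod),
    )


def segment_table(population: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Decompose a derived-measure population into a segment table."""
    rng = np.random.default_rng(seed)
    records = []
    for _, row in population.iterrows():
        dm = DerivedMeasures(
            A_lat=row["A_lat"], B_lat=row["B_lat"],
            A_mod=row["A_mod"], B_mod=row["B_mod"],
            r0=0.5 * row["A_lat"],  # placeholder; true r0 follows from segments
        )
        seg = generate_segments(dm, rng, cochlea_id=row["id"],
                                side=row["side"], method=row["method"])
        records.append(
            {"id": seg.cochlea_id, "side": seg.side, "method": seg.method}
            | {f"A{i+1}": s for i, s in enumerate(seg.A_segments)}
            | {f"B{i+1}": s for i, s in enumerate(seg.B_segments)}
        )
    return pd.DataFrame.from_records(records, columns=MEASUREMENT_COLUMNS)


def generate_cohort(profile: str, n: int = 108, seed: int = 0) -> pd.DataFrame:
    """Full synthetic cohort as a raw segment table (the pipeline's input)."""
    config = population_config(profile, n=n, seed=seed)
    pop = generate_population(config)
    if config.method == "clinical_ct":
        pop = add_measurement_noise(pop, CLINICAL_NOISE, seed=seed + 1)
    return segment_table(pop, seed=seed + 2)


def add_measurement_noise(
    table: pd.DataFrame, profile: MethodNoiseProfile, seed: int = 0
) -> pd.DataFrame:
    """Apply a method's soft-tissue offset and additive noise to measures.

    Modiolar columns are shifted by -offset; all four measure columns are
    perturbed by zero-mean Gaussian noise of SD ``noise_sd``.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    out["A_mod"] = out["A_mod"] - profile.offset_A_mod
    out["B_mod"] = out["B_mod"] - profile.offset_B_mod
    if profile.noise_sd > 0:
        for col in MEASURE_COLUMNS:
            out[col] = out[col] + rng.normal(0.0, profile.noise_sd, size=len(out))
    return out
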