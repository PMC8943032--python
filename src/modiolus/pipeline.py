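"""End-to-end analysis orchestration and run configuration.

Ties the stages together in the analysis order: derived measures from a
(real or synthetic) cohort, cross-method and lateral-modiolar
comparisons, insertion-trajectory transition quantities for the three
perimodiolar offsets, the EID-IA-d_off surface, and the curvature / tip
fold-over profiles — all emitted as CSV tables plus a JSON run manifest
that fully determines the outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anatomy import individualize, mean_anatomy
from .curvature import DEFAULT_D_LW, curvature_profile
from .insertion import eid_ia_surface, offset_trajectory
from .measures import derive_measures_table, normalize_to_mean, read_measurements_csv
from .stats import compare_distributions, correlate
from .synthetic import generate_cohort

__all__ = ["RunConfig", "run_full_analysis", "transitions_table", "comparisons_report"]

log = logging.getLogger("modiolus")


@dataclass
class RunConfig:
    """Parameters of one full analysis run (mm and degrees throughout)."""

    out_dir: str = "modiolus-out"
    input_csv: str | None = None  # when None, a synthetic cohort is generated
    profile: str = "corrosion"
    n: int = 20
    seed: int = 0
    d_off_values: tuple = (0.3, 0.8, 1.0)
    d_lw: float = DEFAULT_D_LW
    surface_d_off_grid: tuple = (0.0, 0.3, 0.6, 0.9, 1.2, 1.5)
    surface_ia_grid: tuple = tuple(float(a) for a in range(90, 721, 45))
    cohort_curvature: bool = False  # per-cochlea r_fold profiles (slower)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not all(0.0 <= d <= 1.5 for d in self.d_off_values):
            raise ValueError("d_off values must lie within [0, 1.5] mm")
        if self.d_lw < 0:
            raise ValueError("d_LW must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("d_off_values", "surface_d_off_grid", "surface_ia_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def comparisons_report(derived: pd.DataFrame) -> pd.DataFrame:
    """Lateral-vs-modiolar comparisons per method, on normalized values.

    For each method and axis: Pearson correlation between lateral and
    modiolar measures, and rank-sum + KS comparisons of the normalized
    (mean-relative) lateral vs modiolar distributions.
    """
    rows = []
    for method, grp in derived.groupby("method", sort=True):
        for axis in ("A", "B"):
            lat = grp[f"{axis}_lat"].dropna()
            mod_ = grp[f"{axis}_mod"].dropna()
            if min(len(lat), len(mod_)) < 3:
                continue
            both = grp[[f"{axis}_lat", f"{axis}_mod"]].dropna()
            corr = correlate(both[f"{axis}_lat"], both[f"{axis}_mod"])
            rows.append(
                dict(test="pearson", variable=axis, group1=f"{axis}_lat",
                     group2=f"{axis}_mod", method=method, statistic=corr.statistic,
                     p=corr.p_value, n1=corr.n1, n2=corr.n2,
                     r2_percent=corr.effect["r2_percent"])
            )
            lat_n = normalize_to_mean(lat.to_numpy(), float(lat.mean()))
            mod_n = normalize_to_mean(mod_.to_numpy(), float(mod_.mean()))
            for test in ("rank_sum", "ks"):
                res = compare_distributions(lat_n, mod_n, test=test)
                rows.append(
                    dict(test=test, variable=f"{axis}_norm", group1=f"{axis}_lat",
                         group2=f"{axis}_mod", method=method, statistic=res.statistic,
                         p=res.p_value, n1=res.n1, n2=res.n2, r2_percent=np.nan)
                )
    return pd.DataFrame(rows)


def transitions_table(derived: pd.DataFrame, d_off_values) -> pd.DataFrame:
    """l_str / IA_str / l_crit per cochlea and per modiolar offset."""
    rows = []
    skipped = 0
    for _, rec in derived.iterrows():
        if any(np.isnan(rec[c]) for c in ("A_lat", "B_lat", "A_mod", "B_mod")):
            skipped += 1
            continue
        modiolar, lateral = individualize(
            rec["A_lat"], rec["B_lat"], rec["A_mod"], rec["B_mod"]
        )
        for d in d_off_values:
            traj = offset_trajectory(modiolar, lateral, d, theta_max=450.0, truncate=True)
            tr = traj.transition
            rows.append(
                dict(id=rec["id"], d_off_mm=float(d), l_str_mm=tr.l_str,
                     IA_str_deg=tr.IA_str, l_crit_mm=tr.l_crit)
            )
    out = pd.DataFrame(rows, columns=["id", "d_off_mm", "l_str_mm", "IA_str_deg", "l_crit_mm"])
    out.attrs["n_skipped"] = skipped
    return out


def run_full_analysis(config: RunConfig) -> dict:
    """Run the whole pipeline; returns the manifest (also written as JSON)."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_csv is not None:
        cohort = read_measurements_csv(config.input_csv)
    else:
        cohort = generate_cohort(config.profile, n=config.n, seed=config.seed)
    if len(cohort) == 0:
        raise ValueError("empty cohort: nothing to analyze")
    cohort.to_csv(out / "cohort.csv", index=False)

    derived = derive_measures_table(cohort)
    derived.to_csv(out / "derived_measures.csv", index=False)
    log.info("derived measures for %d cochleae (%d incomplete)",
             len(derived), derived.attrs["n_incomplete"])

    report = comparisons_report(derived)
    report.to_csv(out / "comparisons.csv", index=False)

    trans = transitions_table(derived, config.d_off_values)
    trans.to_csv(out / "transitions.csv", index=False)

    complete = derived.dropna(subset=["A_lat", "B_lat", "A_mod", "B_mod"])
    anatomies = [
        individualize(r["A_lat"], r["B_lat"], r["A_mod"], r["B_mod"])
        for _, r in complete.iterrows()
    ]
    surface, counts = eid_ia_surface(
        anatomies, config.surface_d_off_grid, config.surface_ia_grid
    )
    surface.to_csv(out / "eid_ia_surface.csv")
    counts.to_csv(out / "eid_ia_surface_counts.csv")

    risk_rows = []
    curv_targets = (
        [("cohort", a) for a in anatomies] if config.cohort_curvature
        else [("mean", mean_anatomy())]
    )
    frames = {}
    for label, (modiolar, lateral) in curv_targets:
        for d in config.d_off_values:
            prof = curvature_profile(modiolar, lateral, d, config.d_lw)
            frames.setdefault(d, []).append(prof)
    for d, profs in frames.items():
        tab = pd.DataFrame({
            "IA_deg": profs[0].ia_deg,
            "r_pre_mm": np.mean([p.r_pre for p in profs], axis=0),
            "r_pre_sd_mm": np.std([p.r_pre for p in profs], axis=0),
            "r_fold_mm": np.nanmean([p.r_fold for p in profs], axis=0),
            "r_fold_sd_mm": np.nanstd([p.r_fold for p in profs], axis=0),
        })
        tab.to_csv(out / f"curvature_doff_{d:.1f}.csv", index=False)
        for p in profs:
            risk_rows.append(
                dict(d_off_mm=d, d_LW_mm=p.d_LW, basal_max_r_fold_mm=p.basal_max_r_fold,
                     risk_angle_deg=p.risk_angle, crossover_angle_deg=p.crossover_angle)
            )
    pd.DataFrame(risk_rows).to_csv(out / "fold_risk.csv", index=False)

    manifest = {
        "package": "modiolus",
        "version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "n_cochleae": int(len(cohort)),
        "n_incomplete": int(derived.attrs["n_incomplete"]),
        "n_skipped": int(trans.attrs["n_skipped"]),
        "n_tests": int(len(report)),
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
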