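"""Orchestrate the full meta-research analysis into one reproducible run.

Stage order mirrors the analysis narrative: publication trends → sampling
inequality (Gini/Dagum/Theil with permutation inference) → methodological
contrasts on precision-weighted accuracy → case–control skewness →
quality rating → optional covariate (GDP) associations.  Every stochastic
stage draws its seed from a registry spawned off the run seed, and the report
records seed and replicate counts next to each result so any single number
can be recomputed in isolation.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .evidence import (
    EvidenceTable,
    GroupedSample,
    aggregate_sample_by_unit,
    read_evidence_table,
    read_units_csv,
)
from .inequality import dagum_decomposition, gini, gini_permutation_test, lorenz_curve, theil_index
from .meta_performance import (
    DEFAULT_SKEW_THRESHOLD,
    case_control_skewness,
    compare_groups,
    precision_weighted_mean,
    skewness_prevalence,
)
from .quality import default_rubric, score_table
from .stats_core import exp_growth_fit, mann_kendall, spearman_bootstrap, spline_gam_fit

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis", "write_report"]


@dataclass(frozen=True)
class RunConfig:
    seed: int = 7
    permutations: int = 10_000
    bootstrap: int = 1000
    skew_threshold: float = DEFAULT_SKEW_THRESHOLD
    low_quality_stars: float = 3.0
    strict: bool = False

    def to_dict(self) -> dict:
        return dict(vars(self))


def _stage_seeds(seed: int, names: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, frozenset):
        return sorted(obj)
    return obj


def run_full_analysis(
    evidence: EvidenceTable | str,
    units: Optional[GroupedSample | str] = None,
    covariates: Optional[pd.DataFrame | str] = None,
    config: Optional[RunConfig] = None,
) -> dict:
    """Execute every stage and return the machine-readable run report.

    ``units`` defaults to the country aggregation of the evidence table
    itself.  ``covariates``, when given, is a table with a ``unit`` column and
    optional ``gdp`` / ``gini`` columns: GDP is correlated against unit
    totals, and when per-unit inequality values are supplied the
    GDP → inequality spline regression runs as well.  Stage failures are
    recorded and skipped unless ``config.strict``.
    """
    cfg = config or RunConfig()
    if isinstance(evidence, (str, Path)):
        evidence = read_evidence_table(evidence)
    if isinstance(units, (str, Path)):
        units = read_units_csv(units)
    if units is None:
        units = aggregate_sample_by_unit(
            evidence,
            module_map={r.sample_country: (r.economic_bloc or "all") for r in evidence.records},
        )
    if isinstance(covariates, (str, Path)):
        covariates = pd.read_csv(covariates)

    seeds = _stage_seeds(cfg.seed, ["inequality", "perf", "skew", "quality", "covariates"])
    report: dict = {
        "schema_version": "1.0",
        "config": cfg.to_dict(),
        "versions": {"metasample": __version__, "numpy": np.__version__,
                     "python": platform.python_version()},
        "seed_registry": seeds,
        "warnings": [],
        "stages": {},
    }

    def run_stage(name, fn):
        try:
            report["stages"][name] = fn()
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            if cfg.strict:
                raise
            logger.exception("stage %s failed", name)
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            report["warnings"].append(f"stage {name} failed: {exc}")

    # --- trends ------------------------------------------------------------
    def stage_trends():
        years = pd.Series([r.year for r in evidence.records])
        counts = years.value_counts().sort_index()
        yr = counts.index.to_numpy(dtype=float)
        k = counts.to_numpy(dtype=float)
        mk = mann_kendall(k)
        growth = exp_growth_fit(yr, k)
        return {"yearly_counts": {int(y): int(c) for y, c in counts.items()},
                "mann_kendall": mk.to_dict(), "exp_growth": growth.to_dict()}

    # --- sampling inequality ------------------------------------------------
    def stage_inequality():
        vals = units.values
        out = {
            "n_units": int(vals.size),
            "gini": gini(vals),
            "theil": theil_index(vals),
            "lorenz": lorenz_curve(vals).points.tolist(),
        }
        perm = gini_permutation_test(units, B=cfg.permutations, seed=seeds["inequality"])
        out["permutation"] = perm.to_dict()
        groups = units.by_module()
        if len(groups) > 1:
            out["dagum"] = dagum_decomposition(units).to_dict()
            out["per_module_gini"] = {m: (gini(v) if v.size > 1 and v.sum() > 0 else None)
                                      for m, v in groups.items()}
        return out

    # --- methodological contrasts -------------------------------------------
    def stage_perf():
        recs = evidence.records
        overall = precision_weighted_mean(recs, n_boot=cfg.bootstrap, seed=seeds["perf"])

        def contrast(name, pred_a, pred_b):
            a = [r for r in recs if pred_a(r)]
            b = [r for r in recs if pred_b(r)]
            if not a or not b:
                return {"status": "skipped", "reason": "empty stratum"}
            return compare_groups(a, b, seed=seeds["perf"]).to_dict()

        return {
            "overall": overall.to_dict(),
            "loocv_vs_kfold": contrast(
                "loocv_vs_kfold",
                lambda r: r.cv_scheme == "LOOCV",
                lambda r: r.cv_scheme in ("kfold", "nested_kfold")),
            "independent_vs_internal": contrast(
                "independent_vs_internal",
                lambda r: r.external_validation != "none",
                lambda r: r.external_validation == "none"),
            "cross_vs_within_country": contrast(
                "cross_vs_within_country",
                lambda r: r.external_validation == "cross_country",
                lambda r: r.external_validation == "within_country"),
        }

    # --- case–control skewness ----------------------------------------------
    def stage_skew():
        share, count, n = skewness_prevalence(evidence.records, cfg.skew_threshold)
        ratios, accs = [], []
        for r in evidence.records:
            if r.n_patients > 0 and r.n_controls > 0:
                ratios.append(case_control_skewness(r.n_patients, r.n_controls))
                accs.append(r.accuracy)
        corr = spearman_bootstrap(ratios, accs, n_boot=cfg.bootstrap, seed=seeds["skew"])
        return {"threshold": cfg.skew_threshold, "prevalence": share,
                "n_skewed": count, "n": n, "skew_accuracy_corr": corr.to_dict()}

    # --- quality rating -------------------------------------------------------
    def stage_quality():
        scores, summary = score_table(evidence, default_rubric(), cfg.low_quality_stars)
        by_year = summary["mean_total_by_year"]
        out = {"summary": summary}
        if len(by_year) >= 4:
            yrs = sorted(by_year)
            corr = spearman_bootstrap(yrs, [by_year[y] for y in yrs],
                                      n_boot=cfg.bootstrap, seed=seeds["quality"])
            out["quality_year_corr"] = corr.to_dict()
        totals = [s.total for s in scores]
        accs = [r.accuracy for r in evidence.records]
        if len(set(totals)) > 1:
            out["quality_accuracy_corr"] = spearman_bootstrap(
                totals, accs, n_boot=cfg.bootstrap, seed=seeds["quality"]).to_dict()
        return out

    # --- covariates (GDP) ------------------------------------------------------
    def stage_covariates():
        if covariates is None:
            return {"status": "skipped", "reason": "no covariates supplied"}
        cov = covariates.copy()
        cov.columns = [c.lower() for c in cov.columns]
        if "unit" not in cov.columns:
            raise ValueError("covariates table needs a 'unit' column")
        cov = cov.set_index(cov["unit"].astype(str))
        out = {}
        unit_vals = dict(zip(units.unit_ids, units.values))
        if "gdp" in cov.columns:
            common = [u for u in unit_vals if u in cov.index]
            if len(common) >= 4:
                x = np.log(cov.loc[common, "gdp"].astype(float).to_numpy())
                y = np.asarray([unit_vals[u] for u in common])
                out["gdp_sample_corr"] = spearman_bootstrap(
                    x, y, n_boot=cfg.bootstrap, seed=seeds["covariates"],
                    compute_bf=True).to_dict()
        if {"gdp", "gini"} <= set(cov.columns):
            sub = cov.dropna(subset=["gdp", "gini"])
            if len(sub) >= 8:
                n_knots = max(2, min(10, len(sub) - 7))  # basis must fit the unit count
                fit = spline_gam_fit(np.log(sub["gdp"].astype(float).to_numpy()),
                                     sub["gini"].astype(float).to_numpy(),
                                     {"n_knots": n_knots})
                out["gdp_gini_gam"] = fit.to_dict()
        return out or {"status": "skipped", "reason": "no usable covariate columns"}

    run_stage("trends", stage_trends)
    run_stage("inequality", stage_inequality)
    run_stage("performance", stage_perf)
    run_stage("skewness", stage_skew)
    run_stage("quality", stage_quality)
    run_stage("covariates", stage_covariates)
    return _jsonable(report)


def write_report(report: dict, out_dir) -> Path:
    """Write the JSON report (and per-stage CSVs where tabular) under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "report.json"
    path.write_text(json.dumps(report, indent=2))
    stages = report.get("stages", {})
    trends = stages.get("trends", {})
    if "yearly_counts" in trends:
        pd.Series(trends["yearly_counts"]).rename("count").rename_axis("year") \
            .to_csv(out / "yearly_counts.csv")
    quality = stages.get("quality", {})
    if "summary" in quality:
        pd.Series(quality["summary"]["mean_total_by_year"]).rename("mean_total") \
            .rename_axis("year").to_csv(out / "quality_by_year.csv")
    return path
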