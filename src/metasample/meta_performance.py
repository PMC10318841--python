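"""Precision-weighted synthesis of reported classifier performance, the
case–control skewness metric, and contrasts between methodological strata.

Reported accuracies from studies with very different test-set sizes are not
equally informative: a proportion estimated on n subjects has sampling
variance p(1-p)/n, so accuracies are pooled by inverse-variance ("precision")
weights rather than averaged raw.  Group contrasts (e.g. LOOCV vs k-fold
cross-validation, within- vs cross-country external validation) use the
non-parametric rank-sum W test with Cohen's d on the raw metric and the
precision-weighted means of both strata reported alongside.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .evidence import StudyRecord
from .stats_core import jzs_bayes_factor

logger = logging.getLogger(__name__)

__all__ = [
    "PrecisionWeightedSummary",
    "GroupComparison",
    "case_control_skewness",
    "precision_weighted_mean",
    "compare_groups",
    "skewness_prevalence",
]

#: default imbalance threshold: a study "exhibits case–control skewness"
#: when max(n_patients, n_controls)/min(...) exceeds this ratio
DEFAULT_SKEW_THRESHOLD = 1.5


def case_control_skewness(n_patients: int, n_controls: int) -> float:
    """Ratio of the larger to the smaller of the two group sizes (≥ 1)."""
    if n_patients <= 0 or n_controls <= 0:
        raise ValueError("both group counts must be positive")
    a, b = float(n_patients), float(n_controls)
    return max(a, b) / min(a, b)


def skewness_prevalence(records: Sequence[StudyRecord],
                        threshold: float = DEFAULT_SKEW_THRESHOLD) -> tuple[float, int, int]:
    """(share, count, n) of records whose skewness ratio exceeds ``threshold``."""
    usable = [r for r in records if r.n_patients > 0 and r.n_controls > 0]
    if not usable:
        raise ValueError("no records with positive case and control counts")
    flags = [case_control_skewness(r.n_patients, r.n_controls) > threshold for r in usable]
    return sum(flags) / len(usable), sum(flags), len(usable)


@dataclass(frozen=True)
class PrecisionWeightedSummary:
    n_studies: int
    weighted_mean: float
    unweighted_mean: float
    weights_sum: float
    ci95: tuple[float, float]
    n_basis: tuple[str, ...] = ()  # per record: which n backed the weight

    def to_dict(self) -> dict:
        d = dict(vars(self))
        d["n_basis"] = list(self.n_basis)
        return d


def _metric_and_n(records: Sequence[StudyRecord], metric: str):
    vals, ns, basis = [], [], []
    skipped = 0
    for r in records:
        v = getattr(r, metric, None)
        if v is None or not np.isfinite(v):
            skipped += 1
            continue
        n = r.n_test if r.n_test else r.n_total
        if not n or n <= 0:
            skipped += 1
            continue
        vals.append(float(v))
        ns.append(float(n))
        basis.append("n_test" if r.n_test else "n_total")
    if skipped:
        logger.info("excluded %d record(s) without usable %s or n", skipped, metric)
    return np.asarray(vals), np.asarray(ns), tuple(basis), skipped


def _pw_mean(p: np.ndarray, n: np.ndarray) -> tuple[float, np.ndarray]:
    # clip the variance plug-in away from {0,1}: a reported 100% accuracy on
    # n subjects still carries at least a half-count of uncertainty
    p_tilde = np.clip(p, 0.5 / n, 1.0 - 0.5 / n)
    w = n / (p_tilde * (1.0 - p_tilde))  # 1/SE^2
    return float(np.dot(w, p) / w.sum()), w


def precision_weighted_mean(
    records: Sequence[StudyRecord],
    metric: str = "accuracy",
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> PrecisionWeightedSummary:
    """Inverse-variance weighted mean of a reported proportion metric.

    Study i gets weight 1/SE_i² with SE_i² = p̃_i(1-p̃_i)/n_i, n_i being the
    held-out test size when coded and the total sample otherwise.  The 95% CI
    is a seeded percentile bootstrap over studies.
    """
    p, n, basis, _ = _metric_and_n(records, metric)
    if p.size == 0:
        raise ValueError(f"no records with usable {metric!r}")
    wm, w = _pw_mean(p, n)
    if p.size == 1:
        ci = (float(p[0]), float(p[0]))
    else:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, p.size, size=(n_boot, p.size))
        boots = np.array([_pw_mean(p[row], n[row])[0] for row in idx])
        lo, hi = np.percentile(boots, [2.5, 97.5])
        ci = (float(min(lo, wm)), float(max(hi, wm)))
    return PrecisionWeightedSummary(
        n_studies=int(p.size),
        weighted_mean=wm,
        unweighted_mean=float(p.mean()),
        weights_sum=float(w.sum()),
        ci95=ci,
        n_basis=basis,
    )


@dataclass(frozen=True)
class GroupComparison:
    stat_W: float
    p_value: float
    cohens_d: float
    means: tuple[float, float]  # precision-weighted means (A, B)
    unweighted_means: tuple[float, float]
    n: tuple[int, int]
    bf10: Optional[float] = None

    def to_dict(self) -> dict:
        return dict(vars(self))


def compare_groups(
    group_a: Sequence[StudyRecord],
    group_b: Sequence[StudyRecord],
    metric: str = "accuracy",
    seed: Optional[int] = None,
    compute_bf: bool = True,
    prior_scale: float = 0.34,
) -> GroupComparison:
    """Contrast a proportion metric between two study strata.

    W is the rank sum of group A (Wilcoxon rank-sum form of Mann–Whitney U),
    with tie-corrected normal approximation for the two-sided p.  Cohen's d is
    computed on the raw metric values (pooled SD); the precision-weighted
    means of both strata are reported for the substantive comparison.  The
    unweighted means are reported too: because the binomial-variance weights
    depend on the observed proportion itself, the weighted means carry a
    small upward pull near the [0,1] boundary, so the unweighted difference
    is the unbiased estimate of an additive accuracy shift.
    """
    pa, na, _, _ = _metric_and_n(group_a, metric)
    pb, nb, _, _ = _metric_and_n(group_b, metric)
    if pa.size == 0 or pb.size == 0:
        raise ValueError("both groups need at least one record with a usable metric")

    # exact null enumeration for small untied samples, tie-corrected normal
    # approximation otherwise (scipy picks per its documented auto rule)
    res = stats.mannwhitneyu(pa, pb, alternative="two-sided", method="auto")
    W = float(res.statistic + pa.size * (pa.size + 1) / 2.0)  # rank sum of A
    p_value = float(res.pvalue)

    n1, n2 = pa.size, pb.size
    if n1 > 1 or n2 > 1:
        var_p = (((n1 - 1) * pa.var(ddof=1) if n1 > 1 else 0.0)
                 + ((n2 - 1) * pb.var(ddof=1) if n2 > 1 else 0.0)) / max(n1 + n2 - 2, 1)
        sd_p = math.sqrt(var_p)
    else:
        sd_p = 0.0
    d = (pa.mean() - pb.mean()) / sd_p if sd_p > 0 else 0.0

    wm_a, _ = _pw_mean(pa, na)
    wm_b, _ = _pw_mean(pb, nb)

    bf10 = None
    if compute_bf and n1 >= 2 and n2 >= 2 and sd_p > 0:
        bf10 = jzs_bayes_factor("two_sample", (pa, pb), prior_scale)

    return GroupComparison(stat_W=W, p_value=p_value, cohens_d=float(d),
                           means=(wm_a, wm_b),
                           unweighted_means=(float(pa.mean()), float(pb.mean())),
                           n=(n1, n2), bf10=bf10)
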