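"""Sampling-inequality machinery: Gini, Lorenz curves, the Dagum three-part
decomposition, the Theil entropy index, and permutation inference.

The "sampling inequality" of a research literature is measured by treating the
total sampled population per geographic unit (a country worldwide, or a
first-level administrative region within a country) as the quantity whose
concentration is assessed.  The Gini coefficient

    G = sum_i sum_j |y_i - y_j| / (2 n^2 ybar)

is 0 under perfect equality and approaches 1 when one unit holds all samples
(exactly (n-1)/n for a one-hot allocation).  When units carry a module label
(e.g. the MEDC / LEDC economic blocs), Dagum's decomposition splits G into a
within-module part, a net between-module part, and a transvariation part
measuring how much of the between-module difference is due to overlapping
module distributions.  The Theil index provides an entropy-based robustness
check on the same values.

Statistical significance of an observed G is assessed against a null in which
the grand total is allocated to units with no systematic inequality
(equal-probability multinomial by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .evidence import GroupedSample

__all__ = [
    "LorenzCurve",
    "GiniDecomposition",
    "PermutationResult",
    "gini",
    "lorenz_curve",
    "theil_index",
    "dagum_decomposition",
    "gini_permutation_test",
]


def _as_values(values: Sequence[float], min_n: int = 2) -> np.ndarray:
    y = np.asarray(values, dtype=float)
    if y.ndim != 1 or y.size < min_n:
        raise ValueError(f"need a 1-d array of at least {min_n} values")
    if not np.all(np.isfinite(y)):
        raise ValueError("values must be finite")
    if np.any(y < 0):
        raise ValueError("values must be nonnegative")
    return y


def gini(values: Sequence[float]) -> float:
    """Gini coefficient of nonnegative values (mean must be positive).

    Computed with the sorted-rank identity
    ``G = 2 * sum_i i*y_(i) / (n * sum y) - (n+1)/n``,
    algebraically equal to the mean-absolute-difference form.
    """
    y = _as_values(values)
    total = y.sum()
    if total <= 0:
        raise ValueError("mean of values must be positive (all-zero input)")
    n = y.size
    ys = np.sort(y)
    ranks = np.arange(1, n + 1, dtype=float)
    return float(2.0 * np.dot(ranks, ys) / (n * total) - (n + 1.0) / n)


def _gini_rows(mat: np.ndarray) -> np.ndarray:
    """Row-wise Gini for a (B, n) matrix of nonnegative allocations."""
    n = mat.shape[1]
    ys = np.sort(mat, axis=1)
    totals = ys.sum(axis=1)
    ranks = np.arange(1, n + 1, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = 2.0 * (ys @ ranks) / (n * totals) - (n + 1.0) / n
    g[totals <= 0] = np.nan
    return g


@dataclass(frozen=True)
class LorenzCurve:
    """Cumulative population share vs cumulative value share, values sorted
    ascending.  Starts at (0,0), ends at (1,1); lies on or below the diagonal."""

    points: np.ndarray  # (n+1, 2)

    @property
    def area(self) -> float:
        """Trapezoidal area under the curve; relates to Gini as G = 1 - 2A."""
        p, L = self.points[:, 0], self.points[:, 1]
        return float(np.trapezoid(L, p))

    def gini(self) -> float:
        return 1.0 - 2.0 * self.area


def lorenz_curve(values: Sequence[float]) -> LorenzCurve:
    y = _as_values(values, min_n=1)
    if y.sum() <= 0:
        raise ValueError("sum of values must be positive")
    ys = np.sort(y)
    n = ys.size
    p = np.arange(0, n + 1) / n
    L = np.concatenate([[0.0], np.cumsum(ys)]) / ys.sum()
    return LorenzCurve(points=np.column_stack([p, L]))


def theil_index(values: Sequence[float]) -> float:
    """Theil T entropy index: (1/n) sum (y/ybar) ln(y/ybar), with 0·ln0 = 0.

    Zero iff all values are equal; bounded above by ln n."""
    y = _as_values(values)
    mean = y.mean()
    if mean <= 0:
        raise ValueError("mean of values must be positive")
    r = y / mean
    pos = r > 0
    return float(np.sum(r[pos] * np.log(r[pos])) / y.size)


@dataclass(frozen=True)
class PairwiseTerm:
    """Between-module term for one (richer j, poorer h) module pair."""

    module_j: str
    module_h: str
    G_jh: float
    D_jh: float
    d_jh: float
    p_jh: float


@dataclass(frozen=True)
class GiniDecomposition:
    """Dagum split G_total = G_within + G_between_net + G_transvariation."""

    G_total: float
    G_within: float
    G_between_net: float
    G_transvariation: float
    pairwise: list[PairwiseTerm] = field(default_factory=list)
    shares: dict[str, tuple[float, float]] = field(default_factory=dict)  # module -> (p_j, s_j)

    def to_dict(self) -> dict:
        return {
            "G_total": self.G_total,
            "G_within": self.G_within,
            "G_between_net": self.G_between_net,
            "G_transvariation": self.G_transvariation,
            "pairwise": [vars(t) for t in self.pairwise],
            "shares": {m: {"p": p, "s": s} for m, (p, s) in self.shares.items()},
        }


def dagum_decomposition(grouped: GroupedSample) -> GiniDecomposition:
    """Decompose the pooled Gini over labelled modules (Dagum, 1997).

    With modules ordered by descending mean, for each pair (j richer, h
    poorer):

    * ``G_jh`` — between-module Gini: mean cross-pair |difference| over
      ``(ybar_j + ybar_h)``;
    * ``d_jh`` — mean positive excess of richer-module values over
      poorer-module values across all cross pairs;
    * ``p_jh`` — the symmetric moment for the poorer module (transvariation);
    * ``D_jh = (d_jh - p_jh) / (d_jh + p_jh)`` — relative economic affluence,
      in [0,1].

    Components:
    ``G_w = sum_j G_jj p_j s_j``,
    ``G_nb = sum_{j>h} G_jh (p_j s_h + p_h s_j) D_jh``,
    ``G_t = sum_{j>h} G_jh (p_j s_h + p_h s_j) (1 - D_jh)``,
    and the identity ``G = G_w + G_nb + G_t`` holds to float precision.
    """
    pooled = grouped.values
    if pooled.size < 2:
        raise ValueError("need at least 2 units overall")
    groups = grouped.by_module()
    total = pooled.sum()
    if total <= 0:
        raise ValueError("overall mean must be positive")
    n = pooled.size

    G_total = gini(pooled)

    # module shares and means, ordered by descending mean (Dagum's convention)
    stats = {m: (v.size, v.sum(), v.mean()) for m, v in groups.items()}
    order = sorted(groups, key=lambda m: stats[m][2], reverse=True)
    p = {m: stats[m][0] / n for m in order}
    s = {m: stats[m][1] / total for m in order}

    def _within(v: np.ndarray) -> float:
        if v.size < 2:
            return 0.0
        if v.sum() <= 0:
            return 0.0
        return gini(v)

    G_within = sum(_within(groups[m]) * p[m] * s[m] for m in order)

    pairwise: list[PairwiseTerm] = []
    G_nb = 0.0
    G_t = 0.0
    for a in range(len(order)):
        for b in range(a + 1, len(order)):
            j, h = order[a], order[b]  # j is the richer module
            yj, yh = groups[j], groups[h]
            diff = yj[:, None] - yh[None, :]
            nm = yj.size * yh.size
            d_jh = float(np.sum(diff[diff > 0])) / nm
            p_jh = float(-np.sum(diff[diff < 0])) / nm
            mean_sum = stats[j][2] + stats[h][2]
            G_jh = float(np.abs(diff).sum()) / (nm * mean_sum) if mean_sum > 0 else 0.0
            denom = d_jh + p_jh
            D_jh = (d_jh - p_jh) / denom if denom > 0 else 0.0
            weight = p[j] * s[h] + p[h] * s[j]
            G_nb += G_jh * weight * D_jh
            G_t += G_jh * weight * (1.0 - D_jh)
            pairwise.append(PairwiseTerm(j, h, G_jh, D_jh, d_jh, p_jh))

    return GiniDecomposition(
        G_total=G_total,
        G_within=float(G_within),
        G_between_net=float(G_nb),
        G_transvariation=float(G_t),
        pairwise=pairwise,
        shares={m: (p[m], s[m]) for m in order},
    )


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic vs a resampled null, with add-one-corrected p."""

    observed: float
    null_samples: int
    p_value: float
    alternative: str
    seed: Optional[int] = None
    null_model: Optional[str] = None

    def to_dict(self) -> dict:
        return dict(vars(self))


def _perm_pvalue(observed: float, null: np.ndarray, alternative: str) -> float:
    # Phipson–Smyth add-one correction: never report p = 0 at finite B
    B = null.size
    p_g = (1.0 + np.sum(null >= observed)) / (B + 1.0)
    p_l = (1.0 + np.sum(null <= observed)) / (B + 1.0)
    if alternative == "greater":
        return float(p_g)
    if alternative == "less":
        return float(p_l)
    if alternative == "two_sided":
        return float(min(1.0, 2.0 * min(p_g, p_l)))
    raise ValueError(f"unknown alternative {alternative!r}")


def gini_permutation_test(
    grouped: GroupedSample,
    B: int = 10_000,
    seed: Optional[int] = None,
    null_model: str = "multinomial",
    alternative: str = "greater",
) -> PermutationResult:
    """Test the observed allocation Gini against an equal-allocation null.

    ``null_model='multinomial'`` reallocates the (rounded) grand total across
    units with equal probabilities — the natural "no sampling inequality"
    hypothesis for count data; ``'dirichlet_uniform'`` draws continuous unit
    shares from a flat Dirichlet instead.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y = grouped.values
    observed = gini(y)
    k = y.size
    rng = np.random.default_rng(seed)
    if null_model == "multinomial":
        total = int(round(y.sum()))
        if total < 1:
            raise ValueError("grand total must be >= 1 for the multinomial null")
        null_mat = rng.multinomial(total, np.full(k, 1.0 / k), size=B).astype(float)
    elif null_model == "dirichlet_uniform":
        null_mat = rng.dirichlet(np.ones(k), size=B) * y.sum()
    else:
        raise ValueError(f"unknown null_model {null_model!r}")
    null = _gini_rows(null_mat)
    null = null[np.isfinite(null)]
    return PermutationResult(
        observed=observed,
        null_samples=int(null.size),
        p_value=_perm_pvalue(observed, null, alternative),
        alternative=alternative,
        seed=seed,
        null_model=null_model,
    )
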