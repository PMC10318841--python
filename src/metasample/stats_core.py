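"""Shared inferential machinery.

Covers the statistics the meta-analysis leans on: Spearman correlation with a
seeded percentile-bootstrap CI, permutation inference for correlations,
the Mann–Kendall trend test with tie correction, exponential growth-curve
fits for yearly study counts, Jeffreys–Zellner–Siow (JZS) Bayes factors by
numerical integration, and a semi-parametric penalized-spline regression that
reports a linear coefficient alongside a centered smooth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import integrate, interpolate, optimize, special, stats

from .inequality import PermutationResult, _perm_pvalue

__all__ = [
    "CorrelationResult",
    "MannKendallResult",
    "GrowthFit",
    "SplineFit",
    "spearman_bootstrap",
    "permutation_correlation",
    "mann_kendall",
    "exp_growth_fit",
    "jzs_bayes_factor",
    "spline_gam_fit",
    "partial_spearman_residuals",
]


# ---------------------------------------------------------------------------
# Correlation

@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    ci95: tuple[float, float]
    n: int
    n_boot: int
    seed: Optional[int] = None
    bf10: Optional[float] = None

    def to_dict(self) -> dict:
        return dict(vars(self))


def _check_xy(x, y, min_n: int = 4) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return x, y


def spearman_bootstrap(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 1000,
    seed: Optional[int] = None,
    compute_bf: bool = False,
    prior_scale: float = 0.34,
) -> CorrelationResult:
    """Spearman rho (mid-ranks for ties) with asymptotic two-sided p and a
    percentile bootstrap CI over paired resamples."""
    x, y = _check_xy(x, y)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    n = x.size
    rho, p = stats.spearmanr(x, y)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    rx = stats.rankdata(x[idx], axis=1)
    ry = stats.rankdata(y[idx], axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        boot = (rx * ry).sum(axis=1) / denom
    boot = boot[np.isfinite(boot)]
    if boot.size:
        lo, hi = np.percentile(boot, [2.5, 97.5])
    else:  # pathological resamples (all constant); fall back to the point estimate
        lo = hi = rho
    lo, hi = min(lo, rho), max(hi, rho)

    bf10 = jzs_bayes_factor("correlation", (float(rho), n), prior_scale) if compute_bf else None
    return CorrelationResult(rho=float(rho), p_value=float(p), ci95=(float(lo), float(hi)),
                             n=n, n_boot=n_boot, seed=seed, bf10=bf10)


def permutation_correlation(
    x: Sequence[float],
    y: Sequence[float],
    B: int = 10_000,
    seed: Optional[int] = None,
    alternative: str = "two_sided",
) -> PermutationResult:
    """Permutation test on Spearman rho, permuting y against x.

    The null distribution is built by re-ranking nothing: ranks are computed
    once and the y-ranks permuted, which is exactly the Spearman statistic of
    a permuted pairing.  p uses the add-one correction.
    """
    x, y = _check_xy(x, y)
    if B < 1:
        raise ValueError("B must be >= 1")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    scale = math.sqrt(float((rxc**2).sum() * (ryc**2).sum()))
    observed = float(np.dot(rxc, ryc) / scale)

    rng = np.random.default_rng(seed)
    n = x.size
    perm = np.empty(B)
    for b in range(B):
        perm[b] = np.dot(rxc, ryc[rng.permutation(n)])
    null = perm / scale
    return PermutationResult(
        observed=observed, null_samples=B,
        p_value=_perm_pvalue(observed, null, alternative),
        alternative=alternative, seed=seed, null_model="permute_y",
    )


def partial_spearman_residuals(
    x: Sequence[float], y: Sequence[float], covariates: np.ndarray,
    n_boot: int = 1000, seed: Optional[int] = None,
) -> CorrelationResult:
    """Spearman correlation of x and y after removing linear covariate effects.

    Both variables are residualized on the covariate matrix by OLS before
    correlating.  This is one concrete reading of a "conditions-adjusted"
    correlation; it makes no claim to match any particular published
    adjustment.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.column_stack([np.ones(x.size), np.asarray(covariates, dtype=float)])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    return spearman_bootstrap(rx, ry, n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# Mann–Kendall trend

@dataclass(frozen=True)
class MannKendallResult:
    S: int
    var_S: float
    Z: float
    p_value: float
    trend: str  # increasing / decreasing / none

    def to_dict(self) -> dict:
        return dict(vars(self))


def mann_kendall(series: Sequence[float], alpha: float = 0.05) -> MannKendallResult:
    """Mann–Kendall trend test with the standard tie-corrected variance and
    ±1 continuity correction on Z."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a series of at least 3 observations")
    n = x.size
    S = int(np.sign(x[None, :] - x[:, None])[np.triu_indices(n, k=1)].sum())
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_S = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var_S <= 0 or S == 0:
        Z = 0.0
    else:
        Z = (S - np.sign(S)) / math.sqrt(var_S)
    p = float(2.0 * stats.norm.sf(abs(Z))) if var_S > 0 else 1.0
    if p < alpha and S > 0:
        trend = "increasing"
    elif p < alpha and S < 0:
        trend = "decreasing"
    else:
        trend = "none"
    return MannKendallResult(S=S, var_S=float(var_S), Z=float(Z), p_value=p, trend=trend)


# ---------------------------------------------------------------------------
# Exponential growth fit

@dataclass(frozen=True)
class GrowthFit:
    b: float
    b_ci95: tuple[float, float]
    scale: float
    r2: float

    def to_dict(self) -> dict:
        return dict(vars(self))


def exp_growth_fit(t: Sequence[float], k: Sequence[float]) -> GrowthFit:
    """Fit yearly counts k = a·exp(b·(t - tbar)) by nonlinear least squares.

    Time is centered for conditioning; the start values come from a
    log-linear regression on the positive counts.  Counts are
    variance-weighted (sigma_i proportional to sqrt(k_i), the Poisson scaling)
    so large years do not dominate the fit, and the 95% CI on b is Wald.
    """
    t = np.asarray(t, dtype=float)
    k = np.asarray(k, dtype=float)
    if t.shape != k.shape or t.size < 3:
        raise ValueError("need at least 3 (t, k) points")
    if np.any(k < 0):
        raise ValueError("counts must be nonnegative")
    if np.all(k == 0):
        raise ValueError("all counts are zero; growth rate undefined")
    tc = t - t.mean()
    pos = k > 0
    if pos.sum() >= 2 and np.ptp(tc[pos]) > 0:
        b0, loga0 = np.polyfit(tc[pos], np.log(k[pos]), 1)
        a0 = math.exp(loga0)
    else:
        b0, a0 = 0.0, max(k.mean(), 1e-9)

    def model(tt, a, b):
        return a * np.exp(b * tt)

    # iteratively reweighted NLS: weights from the *fitted* curve (not the
    # observed counts, which would bias the multiplicative fit), Poisson
    # scaling sigma_i ~ sqrt(mu_i)
    popt, pcov = optimize.curve_fit(model, tc, k, p0=[a0, b0], maxfev=20_000)
    for _ in range(3):
        sigma = np.sqrt(np.maximum(model(tc, *popt), 0.5))
        popt, pcov = optimize.curve_fit(model, tc, k, p0=popt, sigma=sigma,
                                        absolute_sigma=False, maxfev=20_000)
    a, b = popt
    se_b = math.sqrt(max(pcov[1, 1], 0.0))
    resid = k - model(tc, a, b)
    ss_tot = float(((k - k.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    half = 1.959963984540054 * se_b
    return GrowthFit(b=float(b), b_ci95=(float(b - half), float(b + half)),
                     scale=float(a), r2=float(r2))


# ---------------------------------------------------------------------------
# JZS Bayes factors

class BayesFactorError(ArithmeticError):
    """Numerical integration of the JZS marginal likelihood failed."""


def _zs_prior_logpdf(g: np.ndarray, b: float) -> np.ndarray:
    # inverse-gamma(1/2, b/2) density for g: sqrt(b/2)/Gamma(1/2) g^{-3/2} e^{-b/(2g)}
    return 0.5 * np.log(b / 2.0) - special.gammaln(0.5) - 1.5 * np.log(g) - b / (2.0 * g)


def _integrate_log(f_log, lo: float = 0.0, hi: float = np.inf) -> float:
    """Integrate exp(f_log(g)) over g with a stabilising shift."""
    # locate the mode on a wide log grid to set the shift
    grid = np.logspace(-8, 8, 400)
    vals = f_log(grid)
    shift = float(np.max(vals))
    if not np.isfinite(shift):
        raise BayesFactorError("integrand is non-finite over the search grid")
    val, err = integrate.quad(lambda g: math.exp(min(f_log(np.array([g]))[0] - shift, 700.0)),
                              lo, hi, limit=300)
    if not np.isfinite(val) or (val > 0 and err / val > 1e-4):
        raise BayesFactorError(f"quadrature did not converge (value={val}, abserr={err})")
    return math.log(val) + shift


def jzs_bayes_factor(
    kind: str,
    data_or_stats,
    prior_scale: float = 0.34,
) -> float:
    """JZS (Cauchy-prior) Bayes factor BF10 for a correlation or a two-sample
    mean difference, by numerical integration over the g-prior mixture.

    ``kind='correlation'`` takes ``(r, n)``: the Zellner–Siow regression Bayes
    factor for a single standardized covariate with prior scale
    ``prior_scale`` on the standardized slope,

        BF10 = ∫ (1+g)^{(n-2)/2} (1 + (1-r²)g)^{-(n-1)/2} π(g) dg,
        g ~ InvGamma(1/2, n·s²/2).

    ``kind='two_sample'`` takes ``(t, n1, n2)`` or two raw samples: the JZS
    t-test Bayes factor with effective sample size N = n1·n2/(n1+n2),

        BF10 = ∫ (1+Ng)^{-1/2} (1 + t²/((1+Ng)ν))^{-(ν+1)/2} π(g) dg
               / (1 + t²/ν)^{-(ν+1)/2},
        g ~ InvGamma(1/2, s²/2), ν = n1+n2-2.

    BF01 is simply 1/BF10.  The factor is symmetric in the sign of the effect
    and grows without bound in n at any fixed nonzero effect.
    """
    if prior_scale <= 0:
        raise ValueError("prior_scale must be positive")
    s2 = prior_scale * prior_scale

    if kind == "correlation":
        r, n = data_or_stats
        r = float(r)
        n = int(n)
        if n < 4:
            raise ValueError("correlation BF needs n >= 4")
        if not -1.0 < r < 1.0:
            r = max(min(r, 1.0 - 1e-12), -1.0 + 1e-12)
        one_minus_r2 = 1.0 - r * r

        def f_log(g):
            return (0.5 * (n - 2) * np.log1p(g)
                    - 0.5 * (n - 1) * np.log1p(one_minus_r2 * g)
                    + _zs_prior_logpdf(g, n * s2))

        return math.exp(_integrate_log(f_log))

    if kind == "two_sample":
        if len(data_or_stats) == 3 and np.isscalar(data_or_stats[0]):
            t, n1, n2 = data_or_stats
        else:
            a, b = (np.asarray(v, dtype=float) for v in data_or_stats)
            n1, n2 = a.size, b.size
            t, _ = stats.ttest_ind(a, b, equal_var=True)
        t = float(t)
        n1, n2 = int(n1), int(n2)
        if min(n1, n2) < 2:
            raise ValueError("two_sample BF needs n1, n2 >= 2")
        N = n1 * n2 / (n1 + n2)
        nu = n1 + n2 - 2
        log_null = -0.5 * (nu + 1) * math.log1p(t * t / nu)

        def f_log(g):
            ng1 = 1.0 + N * g
            return (-0.5 * np.log(ng1)
                    - 0.5 * (nu + 1) * np.log1p(t * t / (ng1 * nu))
                    + _zs_prior_logpdf(g, s2))

        return math.exp(_integrate_log(f_log) - log_null)

    raise ValueError(f"unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# Penalized-spline semi-parametric regression

@dataclass(frozen=True)
class SplineFit:
    linear_beta: float
    linear_se: float
    t_value: float
    p_value: float
    r2: float
    r2_adj: float
    smooth_edf: float
    knots: int
    lam: float

    def to_dict(self) -> dict:
        return dict(vars(self))


def _bspline_basis(x: np.ndarray, n_knots: int, degree: int) -> np.ndarray:
    lo, hi = x.min(), x.max()
    inner = np.quantile(x, np.linspace(0, 1, n_knots + 2)[1:-1])
    t = np.concatenate([[lo] * (degree + 1), inner, [hi] * (degree + 1)])
    xc = np.clip(x, lo, hi)
    B = interpolate.BSpline.design_matrix(xc, t, degree).toarray()
    return B


def spline_gam_fit(
    x: Sequence[float],
    y: Sequence[float],
    config: Optional[dict] = None,
) -> SplineFit:
    """Semi-parametric fit y = α + β·x + f(x) + ε with a penalized cubic
    B-spline smooth f.

    The smooth's basis is residualized against [1, x] (a sum-to-zero-plus-
    no-linear-trend constraint) so the linear coefficient β stays estimable;
    the penalty is a second-order difference penalty on the spline
    coefficients with the smoothing parameter chosen by GCV on a log grid.
    ``smooth_edf`` is the trace of the smooth's hat block (floored at 1, the
    dimension of the penalty's surviving null space), so a purely linear
    signal shrinks to smooth_edf ≈ 1 at heavy smoothing.

    ``config`` keys: ``n_knots`` (interior knots, default 10), ``degree``
    (default 3), ``lambdas`` (grid, default logspace(-4, 8, 40)), ``mode``
    (``'linear_plus_smooth'`` default, or ``'pure_smooth'``).
    """
    cfg = {"n_knots": 10, "degree": 3, "lambdas": None, "mode": "linear_plus_smooth"}
    cfg.update(config or {})
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 8:
        raise ValueError("need at least 8 points")
    B = _bspline_basis(x, int(cfg["n_knots"]), int(cfg["degree"]))
    m = B.shape[1]
    if n <= m + 2:
        raise ValueError(f"n={n} too small for a basis of dimension {m}; reduce n_knots")

    if cfg["mode"] == "pure_smooth":
        X = np.ones((n, 1))
    else:
        X = np.column_stack([np.ones(n), x - x.mean()])
    # project the basis orthogonal to the parametric columns (identifiability)
    Q, _ = np.linalg.qr(X)
    Z = B - Q @ (Q.T @ B)

    D = np.diff(np.eye(m), n=2, axis=0)
    P = D.T @ D

    beta_hat = np.linalg.lstsq(X, y, rcond=None)[0]
    resid_param = y - X @ beta_hat
    ZtZ = Z.T @ Z
    Zty = Z.T @ resid_param  # Z ⟂ X, so fitting on residuals equals joint fit

    lambdas = cfg["lambdas"]
    if lambdas is None:
        lambdas = np.logspace(-4, 8, 40)
    best = None
    p_param = X.shape[1]
    for lam in np.asarray(lambdas, dtype=float):
        A = ZtZ + lam * P
        try:
            theta = np.linalg.solve(A, Zty)
            edf_s = float(np.trace(np.linalg.solve(A, ZtZ)))
        except np.linalg.LinAlgError:
            continue
        fitted = X @ beta_hat + Z @ theta
        rss = float(((y - fitted) ** 2).sum())
        edf_tot = p_param + edf_s
        gcv = n * rss / (n - edf_tot) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, lam, theta, edf_s, rss)
    if best is None:
        raise np.linalg.LinAlgError("penalized solve failed for every lambda")
    _, lam, theta, edf_s, rss = best

    edf_tot = p_param + edf_s
    sigma2 = rss / max(n - edf_tot, 1.0)
    XtX_inv = np.linalg.inv(X.T @ X)
    if cfg["mode"] == "pure_smooth":
        beta, se = float("nan"), float("nan")
        t_val, p_val = float("nan"), float("nan")
    else:
        beta = float(beta_hat[1])
        se = float(math.sqrt(sigma2 * XtX_inv[1, 1]))
        t_val = beta / se if se > 0 else float("inf")
        p_val = float(2.0 * stats.t.sf(abs(t_val), df=max(n - edf_tot, 1.0)))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else 1.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / max(n - edf_tot, 1.0)
    return SplineFit(
        linear_beta=beta, linear_se=se, t_value=t_val, p_value=p_val,
        r2=float(r2), r2_adj=float(r2_adj),
        smooth_edf=float(max(1.0, edf_s)), knots=int(cfg["n_knots"]), lam=float(lam),
    )
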