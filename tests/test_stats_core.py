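"""Correlation, trend, growth-fit, Bayes-factor and spline machinery."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from metasample import (
    exp_growth_fit,
    jzs_bayes_factor,
    mann_kendall,
    permutation_correlation,
    spearman_bootstrap,
    spline_gam_fit,
)
from metasample.stats_core import _zs_prior_logpdf


# --- Spearman ---------------------------------------------------------------

def test_spearman_monotone_transforms():
    x = np.array([0.3, 1.2, 2.0, 3.5, 5.1, 7.0])
    assert spearman_bootstrap(x, 2 * x + 1, n_boot=50, seed=0).rho == pytest.approx(1.0)
    assert spearman_bootstrap(x, -x**3, n_boot=50, seed=0).rho == pytest.approx(-1.0)
    # invariance under strictly monotone transforms of either variable
    y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
    base = spearman_bootstrap(x, y, n_boot=50, seed=0).rho
    assert spearman_bootstrap(np.exp(x), y, n_boot=50, seed=0).rho == pytest.approx(base)
    assert spearman_bootstrap(x, np.log(y), n_boot=50, seed=0).rho == pytest.approx(base)


def test_spearman_rank_difference_formula():
    res = spearman_bootstrap([1, 2, 3, 4], [1, 3, 2, 4], n_boot=100, seed=0)
    assert res.rho == pytest.approx(0.8)  # 1 - 6*2/(4*15)
    assert res.ci95[0] <= res.rho <= res.ci95[1]


def test_spearman_rejects_constant_vector():
    with pytest.raises(ValueError):
        spearman_bootstrap([1, 1, 1, 1], [1, 2, 3, 4], n_boot=10, seed=0)


def test_spearman_bootstrap_ci_coverage(rng):
    """Percentile-bootstrap CI covers the true rho about 95% of the time
    (bivariate normal, rho=0.5, n=100)."""
    rho_true_pearson = 0.5
    rho_true = 6 / math.pi * math.asin(rho_true_pearson / 2)  # Spearman of a binormal
    cov = [[1, rho_true_pearson], [rho_true_pearson, 1]]
    hits = 0
    n_rep = 500
    for i in range(n_rep):
        xy = rng.multivariate_normal([0, 0], cov, size=100)
        res = spearman_bootstrap(xy[:, 0], xy[:, 1], n_boot=400, seed=int(rng.integers(2**31)))
        if res.ci95[0] <= rho_true <= res.ci95[1]:
            hits += 1
    assert abs(hits / n_rep - 0.95) <= 0.03


# --- permutation correlation -------------------------------------------------

def test_permutation_correlation_perfect_association():
    x = np.arange(10.0)
    res = permutation_correlation(x, x, B=999, seed=4, alternative="greater")
    assert res.p_value == pytest.approx(1 / 1000)


def test_permutation_two_sided_doubles_one_tailed():
    rng = np.random.default_rng(0)
    x = rng.normal(size=30)
    y = 0.5 * x + rng.normal(size=30)
    one = permutation_correlation(x, y, B=2000, seed=9, alternative="greater").p_value
    two = permutation_correlation(x, y, B=2000, seed=9, alternative="two_sided").p_value
    assert two == pytest.approx(min(1.0, 2 * one))


def test_permutation_null_at_small_n_matches_enumeration():
    """At n=5 the add-one permutation p for the identity pairing matches full
    enumeration of the 5! pairings."""
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    y = x.copy()
    rx = x - x.mean()
    count_ge = sum(
        np.dot(rx, np.array(p) - x.mean()) >= np.dot(rx, rx) - 1e-9
        for p in itertools.permutations(x)
    )
    exact = count_ge / math.factorial(5)  # = 1/120
    res = permutation_correlation(x, y, B=4999, seed=2, alternative="greater")
    assert abs(res.p_value - exact) < 0.01


# --- Mann–Kendall ------------------------------------------------------------

def mk_S_bruteforce(series):
    s = 0
    for i in range(len(series)):
        for j in range(i + 1, len(series)):
            s += np.sign(series[j] - series[i])
    return int(s)


@pytest.mark.parametrize("series,S", [
    ([1, 2, 3, 4, 5], 10),
    ([5, 4, 3, 2, 1], -10),
    ([1, 2, 2, 3], 5),
])
def test_mann_kendall_known_S(series, S):
    assert mann_kendall(series).S == S


def test_mann_kendall_tie_variance():
    res = mann_kendall([1, 2, 2, 3])
    # n=4: [4*3*13 - 2*1*9]/18
    assert res.var_S == pytest.approx((156 - 18) / 18)


def test_mann_kendall_matches_enumeration_all_permutations():
    """S equals the exhaustive pair-count oracle for every permutation of
    n <= 7 distinct values."""
    for n in range(3, 8):
        for perm in itertools.permutations(range(n)):
            assert mann_kendall(list(perm)).S == mk_S_bruteforce(perm)


def test_mann_kendall_flat_series():
    res = mann_kendall([3.0, 3.0, 3.0, 3.0])
    assert res.S == 0
    assert res.trend == "none"
    assert res.p_value == 1.0


def test_mann_kendall_antisymmetry_of_Z(rng):
    x = rng.normal(size=20)
    up, down = mann_kendall(x), mann_kendall(-x)
    assert up.S == -down.S
    assert up.Z == pytest.approx(-down.Z)


# --- exponential growth -------------------------------------------------------

def test_exp_growth_exact_recovery():
    t = np.arange(1995, 2020, dtype=float)
    tc = t - t.mean()
    fit = exp_growth_fit(t, 2.0 * np.exp(0.3 * tc))
    assert fit.b == pytest.approx(0.3, abs=1e-8)
    assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    flat = exp_growth_fit(t, np.full_like(t, 7.0))
    assert flat.b == pytest.approx(0.0, abs=1e-8)


def test_exp_growth_ci_covers_truth_under_poisson_noise(rng):
    t = np.arange(25, dtype=float)
    tc = t - t.mean()
    mu = 3.0 * np.exp(0.25 * tc)
    covered = 0
    for _ in range(100):
        k = rng.poisson(mu).astype(float)
        fit = exp_growth_fit(t, k)
        if fit.b_ci95[0] <= 0.25 <= fit.b_ci95[1]:
            covered += 1
    assert covered >= 90


def test_exp_growth_rejects_all_zero():
    with pytest.raises(ValueError):
        exp_growth_fit([1, 2, 3], [0, 0, 0])


# --- JZS Bayes factors --------------------------------------------------------

def bf_grid_oracle(kind, args, prior_scale=0.34):
    """Fine-grid trapezoid quadrature of the same marginal likelihood ratio,
    independent of the adaptive quadrature used by the implementation."""
    g = np.exp(np.linspace(math.log(1e-10), math.log(1e10), 200_001))
    if kind == "correlation":
        r, n = args
        log_f = (0.5 * (n - 2) * np.log1p(g)
                 - 0.5 * (n - 1) * np.log1p((1 - r * r) * g)
                 + _zs_prior_logpdf(g, n * prior_scale**2))
        shift = log_f.max()
        return math.exp(shift) * np.trapezoid(np.exp(log_f - shift), g)
    t, n1, n2 = args
    N = n1 * n2 / (n1 + n2)
    nu = n1 + n2 - 2
    log_f = (-0.5 * np.log1p(N * g)
             - 0.5 * (nu + 1) * np.log1p(t * t / ((1 + N * g) * nu))
             + _zs_prior_logpdf(g, prior_scale**2))
    shift = log_f.max()
    num = math.exp(shift) * np.trapezoid(np.exp(log_f - shift), g)
    return num / (1 + t * t / nu) ** (-0.5 * (nu + 1))


def test_bf_null_data_favor_h0():
    assert jzs_bayes_factor("correlation", (0.0, 50)) < 1
    assert jzs_bayes_factor("two_sample", (0.0, 20, 20)) < 1


def test_bf_matches_grid_oracle_to_3_significant_digits():
    for r, n in [(0.5, 40), (0.2, 100), (-0.7, 25)]:
        ours = jzs_bayes_factor("correlation", (r, n))
        oracle = bf_grid_oracle("correlation", (r, n))
        assert ours == pytest.approx(oracle, rel=5e-4)
    for t, n1, n2 in [(2.5, 30, 30), (0.8, 15, 20), (4.0, 50, 40)]:
        ours = jzs_bayes_factor("two_sample", (t, n1, n2))
        oracle = bf_grid_oracle("two_sample", (t, n1, n2))
        assert ours == pytest.approx(oracle, rel=5e-4)


def test_bf_sign_symmetry_and_monotonicity():
    assert jzs_bayes_factor("correlation", (0.4, 30)) == pytest.approx(
        jzs_bayes_factor("correlation", (-0.4, 30)), rel=1e-9)
    grid = [jzs_bayes_factor("correlation", (r, 30)) for r in (0.1, 0.3, 0.5, 0.7)]
    assert all(a < b for a, b in zip(grid, grid[1:]))
    # grows without bound in n at fixed nonzero effect
    by_n = [jzs_bayes_factor("correlation", (0.4, n)) for n in (20, 60, 180)]
    assert all(a < b for a, b in zip(by_n, by_n[1:]))


def test_bf_two_sample_matches_pingouin_default_prior():
    pingouin = pytest.importorskip("pingouin")
    t, n1, n2 = 2.3, 25, 30
    ours = jzs_bayes_factor("two_sample", (t, n1, n2), prior_scale=0.707)
    theirs = float(pingouin.bayesfactor_ttest(t, n1, n2, paired=False, r=0.707))
    assert ours == pytest.approx(theirs, rel=1e-3)


def test_bf_raw_two_sample_data(rng):
    a = rng.normal(0.5, 1.0, size=40)
    b = rng.normal(0.0, 1.0, size=40)
    t, _ = stats.ttest_ind(a, b)
    assert jzs_bayes_factor("two_sample", (a, b)) == pytest.approx(
        jzs_bayes_factor("two_sample", (float(t), 40, 40)), rel=1e-6)


# --- penalized-spline regression ---------------------------------------------

def test_spline_linear_limit():
    x = np.linspace(0, 1, 120)
    y = 2.0 - 2.75 * x
    fit = spline_gam_fit(x, y)
    assert fit.linear_beta == pytest.approx(-2.75, abs=1e-6)
    assert fit.smooth_edf == pytest.approx(1.0, abs=0.1)
    assert fit.r2_adj == pytest.approx(1.0, abs=1e-6)


def test_spline_captures_nonlinearity(rng):
    x = np.linspace(0, np.pi, 200)
    y = np.sin(4 * x) + rng.normal(0, 0.2, size=200)
    fit = spline_gam_fit(x, y)
    assert fit.r2_adj > 0.8
    assert fit.smooth_edf > 3


def test_spline_beta_recovery_with_smooth_confounder(rng):
    """beta estimated within +/-2 SE in >=90% of replicates when the signal is
    a known slope plus a linear-free smooth."""
    n = 120
    x = np.linspace(0, 1, n)
    f = np.sin(3 * np.pi * x)
    X = np.column_stack([np.ones(n), x])
    f = f - X @ np.linalg.lstsq(X, f, rcond=None)[0]  # strip any linear leak
    hits = 0
    n_rep = 200
    for _ in range(n_rep):
        y = 1.0 - 2.75 * x + f + rng.normal(0, 0.3, size=n)
        fit = spline_gam_fit(x, y)
        if abs(fit.linear_beta - (-2.75)) <= 2 * fit.linear_se:
            hits += 1
    assert hits >= 0.9 * n_rep


def test_spline_input_validation():
    with pytest.raises(ValueError):
        spline_gam_fit([1, 2, 3], [1, 2, 3])
    with pytest.raises(ValueError, match="n_knots"):
        spline_gam_fit(np.linspace(0, 1, 10), np.zeros(10), {"n_knots": 20})
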