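"""Gini/Lorenz/Theil/Dagum machinery and permutation inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metasample import (
    GroupedSample,
    dagum_decomposition,
    gini,
    gini_permutation_test,
    lorenz_curve,
    theil_index,
)


def gini_bruteforce(values):
    """O(n^2) double-sum oracle: sum |y_i - y_j| / (2 n^2 ybar)."""
    y = np.asarray(values, dtype=float)
    n = y.size
    return float(np.abs(y[:, None] - y[None, :]).sum() / (2 * n * n * y.mean()))


@pytest.mark.parametrize("values,expected", [
    ([2, 2, 2, 2], 0.0),
    ([0, 0, 0, 1], 0.75),
    ([1, 3], 0.25),
])
def test_gini_known_values(values, expected):
    assert gini(values) == pytest.approx(expected, abs=1e-12)


def test_gini_matches_bruteforce_oracle(rng):
    for _ in range(50):
        y = rng.gamma(0.7, 10.0, size=rng.integers(2, 40))
        assert gini(y) == pytest.approx(gini_bruteforce(y), abs=1e-12)


def test_gini_rejects_degenerate_input():
    with pytest.raises(ValueError):
        gini([0.0, 0.0])
    with pytest.raises(ValueError):
        gini([5.0])
    with pytest.raises(ValueError):
        gini([1.0, -1.0])


@given(st.lists(st.one_of(st.just(0.0), st.floats(1e-6, 1e6)),
                min_size=2, max_size=30).filter(lambda v: sum(v) > 1e-6),
       st.floats(1e-3, 1e3))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_gini_and_theil_scale_invariance(values, c):
    assert gini(np.array(values) * c) == pytest.approx(gini(values), abs=1e-9)
    assert theil_index(np.array(values) * c) == pytest.approx(theil_index(values), abs=1e-9)


def test_pigou_dalton_transfer_never_increases_inequality(rng):
    """A mean-preserving transfer from a richer to a poorer unit cannot
    increase G or T."""
    for _ in range(200):
        y = rng.gamma(1.0, 5.0, size=10) + 0.01
        i, j = int(np.argmax(y)), int(np.argmin(y))
        eps = (y[i] - y[j]) * rng.uniform(0, 0.5)
        z = y.copy()
        z[i] -= eps
        z[j] += eps
        assert gini(z) <= gini(y) + 1e-12
        assert theil_index(z) <= theil_index(y) + 1e-12


@pytest.mark.parametrize("values,expected", [
    ([5, 5, 5], 0.0),
    ([1, 3], 0.13081203594113697),
    ([0, 1], np.log(2)),
])
def test_theil_known_values(values, expected):
    assert theil_index(values) == pytest.approx(expected, abs=1e-9)


def test_theil_bounded_by_log_n(rng):
    y = np.concatenate([np.zeros(9), [1.0]])
    assert theil_index(y) <= np.log(10) + 1e-12


def test_lorenz_curve_shapes():
    eq = lorenz_curve([1, 1, 1, 1]).points
    assert np.allclose(eq[:, 0], eq[:, 1])

    onehot = lorenz_curve([0, 0, 0, 1]).points
    assert onehot[3].tolist() == [0.75, 0.0]
    assert onehot[4].tolist() == [1.0, 1.0]

    two = lorenz_curve([1, 3]).points
    assert two[1].tolist() == [0.5, 0.25]


def test_lorenz_invariants_and_gini_consistency(rng):
    y = rng.gamma(0.8, 4.0, size=200)
    lc = lorenz_curve(y)
    p, L = lc.points[:, 0], lc.points[:, 1]
    assert (p[0], L[0]) == (0.0, 0.0)
    assert (p[-1], L[-1]) == (1.0, 1.0)
    assert np.all(np.diff(L) >= -1e-15)
    assert np.all(L <= p + 1e-12)
    # trapezoidal area relates to the coefficient: G = 1 - 2A (up to 1/n term)
    assert lc.gini() == pytest.approx(gini(y), abs=1e-2)
    with pytest.raises(ValueError):
        lorenz_curve([1.0, -0.5])


def test_dagum_separated_modules():
    gs = GroupedSample([("a", 1, "A"), ("b", 1, "A"), ("c", 3, "B"), ("d", 3, "B")])
    d = dagum_decomposition(gs)
    assert d.G_total == pytest.approx(0.25, abs=1e-12)
    assert d.G_within == pytest.approx(0.0, abs=1e-12)
    assert d.G_between_net == pytest.approx(0.25, abs=1e-12)
    assert d.G_transvariation == pytest.approx(0.0, abs=1e-12)
    assert d.pairwise[0].D_jh == pytest.approx(1.0)


def test_dagum_overlapping_modules():
    gs = GroupedSample([("a", 1, "A"), ("b", 3, "A"), ("c", 2, "B"), ("d", 4, "B")])
    d = dagum_decomposition(gs)
    assert d.G_total == pytest.approx(0.25, abs=1e-12)
    assert d.G_within == pytest.approx(0.10, abs=1e-12)
    assert d.G_between_net == pytest.approx(0.10, abs=1e-12)
    assert d.G_transvariation == pytest.approx(0.05, abs=1e-12)
    term = d.pairwise[0]
    assert (term.module_j, term.module_h) == ("B", "A")
    assert term.d_jh == pytest.approx(1.25)
    assert term.p_jh == pytest.approx(0.25)
    assert term.D_jh == pytest.approx(2 / 3)


def test_dagum_single_module_collapses_to_within():
    gs = GroupedSample([("a", 1, "X"), ("b", 2, "X"), ("c", 5, "X")])
    d = dagum_decomposition(gs)
    assert d.G_within == pytest.approx(d.G_total, abs=1e-12)
    assert d.G_between_net == 0.0
    assert d.G_transvariation == 0.0


def test_dagum_shares_sum_to_one(rng):
    gs = _random_grouped(rng)
    d = dagum_decomposition(gs)
    ps = sum(p for p, _ in d.shares.values())
    ss = sum(s for _, s in d.shares.values())
    assert ps == pytest.approx(1.0, abs=1e-12)
    assert ss == pytest.approx(1.0, abs=1e-12)
    for t in d.pairwise:
        assert -1e-12 <= t.D_jh <= 1 + 1e-12


def _random_grouped(rng, max_modules=4):
    k = int(rng.integers(2, max_modules + 1))
    units = []
    for m in range(k):
        size = int(rng.integers(1, 8))
        vals = rng.gamma(rng.uniform(0.3, 3.0), rng.uniform(1, 20), size=size)
        units += [(f"m{m}u{i}", float(v), f"M{m}") for i, v in enumerate(vals)]
    if sum(v for _, v, _ in units) <= 0 or len(units) < 2:
        units = [("a", 1.0, "M0"), ("b", 2.0, "M1")]
    return GroupedSample(units)


def test_dagum_identity_on_random_samples(rng):
    """G_total = G_w + G_nb + G_t to 1e-10 across random grouped samples."""
    for _ in range(300):
        gs = _random_grouped(rng)
        d = dagum_decomposition(gs)
        assert d.G_within + d.G_between_net + d.G_transvariation == pytest.approx(
            d.G_total, abs=1e-10)


def test_permutation_equal_allocation_is_null_typical():
    gs = GroupedSample([(f"u{i}", 100.0, "all") for i in range(10)])
    res = gini_permutation_test(gs, B=999, seed=1)
    assert res.p_value > 0.9


def test_permutation_one_hot_is_extreme():
    units = [(f"u{i}", 0.0, "all") for i in range(19)] + [("u19", 10_000.0, "all")]
    res = gini_permutation_test(GroupedSample(units), B=999, seed=1)
    assert res.p_value == pytest.approx(1 / 1000)


def test_permutation_rejects_bad_config():
    gs = GroupedSample([("a", 1.0, "all"), ("b", 2.0, "all")])
    with pytest.raises(ValueError):
        gini_permutation_test(gs, B=0, seed=1)
    with pytest.raises(ValueError):
        gini_permutation_test(gs, B=10, seed=1, null_model="bogus")


def test_permutation_dirichlet_null_runs():
    gs = GroupedSample([(f"u{i}", float(i + 1), "all") for i in range(8)])
    res = gini_permutation_test(gs, B=200, seed=3, null_model="dirichlet_uniform")
    assert 0 < res.p_value <= 1
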