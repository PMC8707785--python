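"""Exact Wilcoxon machinery against independent enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytosig.errors import ValidationError
from cytosig.ranktests import wilcoxon

from _oracles import ranksum_p_enumeration, signedrank_p_enumeration

# small pool with ties so mid-rank handling is exercised
GRID_VALUES = (0.0, 1.0, 1.0, 1.5, 2.0, 3.0, 3.0, 5.0)


def test_unpaired_separated_samples_exact_p():
    """Fully separated 3-vs-3 samples: 2 of the 20 rank splits are as
    extreme, so the two-sided exact p is 0.1."""
    res = wilcoxon([1, 2, 3], [4, 5, 6])
    assert res.p_two_sided == 0.1
    assert res.method == "exact"
    assert res.statistic == 0.0          # U for the smaller sample
    assert not res.tie_flag


def test_paired_all_positive_differences_exact_p():
    """Five distinct positive differences: 2 of the 32 sign patterns are as
    extreme -> two-sided exact p = 0.0625."""
    res = wilcoxon([2, 3, 4, 5, 6], [1, 1, 1, 1, 1], mode="paired")
    assert res.p_two_sided == 0.0625
    assert res.p_greater == 1 / 32


def test_paired_identical_samples_is_no_evidence():
    res = wilcoxon([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], mode="paired")
    assert res.p_two_sided == 1.0
    assert res.n_zero_dropped == 3


@pytest.mark.parametrize("mode,bad", [
    ("paired", ([1, 2], [1, 2, 3])),
    ("unpaired", ([], [1])),
    ("unpaired", ([1], [])),
])
def test_invalid_samples_rejected(mode, bad):
    with pytest.raises(ValidationError):
        wilcoxon(bad[0], bad[1], mode=mode)


def _random_pairs(rng, n_pairs, max_total):
    for _ in range(n_pairs):
        n_x = int(rng.integers(1, max_total))
        n_y = int(rng.integers(1, max_total + 1 - n_x))
        x = rng.choice(GRID_VALUES, size=n_x).tolist()
        y = rng.choice(GRID_VALUES, size=n_y).tolist()
        yield x, y


def test_unpaired_exact_equals_full_enumeration():
    """The subset-sum DP must agree bit-exactly with enumerating every
    C(n, n_x) rank split, ties included."""
    rng = np.random.default_rng(2024)
    for x, y in _random_pairs(rng, 150, 10):
        res = wilcoxon(x, y)
        p_two, p_gt = ranksum_p_enumeration(x, y)
        assert res.method == "exact"
        assert res.p_two_sided == p_two, (x, y)
        assert res.p_greater == p_gt, (x, y)


def test_paired_exact_equals_sign_enumeration():
    rng = np.random.default_rng(2025)
    for _ in range(150):
        n = int(rng.integers(1, 11))
        x = rng.choice(GRID_VALUES, size=n).tolist()
        y = rng.choice(GRID_VALUES, size=n).tolist()
        res = wilcoxon(x, y, mode="paired")
        p_two, p_gt = signedrank_p_enumeration(x, y)
        assert res.method == "exact"
        assert res.p_two_sided == p_two, (x, y)
        assert res.p_greater == p_gt, (x, y)


def test_exact_matches_scipy_when_tie_free():
    """Cross-check against scipy's exact method on tie-free samples."""
    import scipy.stats as sps
    rng = np.random.default_rng(7)
    for _ in range(25):
        n_x, n_y = int(rng.integers(2, 9)), int(rng.integers(2, 9))
        pool = rng.permutation(200)[: n_x + n_y].astype(float)
        x, y = pool[:n_x], pool[n_x:]
        res = wilcoxon(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)


def test_normal_approximation_used_beyond_cutoff():
    rng = np.random.default_rng(11)
    x = rng.normal(1.0, 1.0, size=30)
    y = rng.normal(0.0, 1.0, size=30)
    res = wilcoxon(x, y)
    assert res.method == "normal_approx"
    assert 0.0 <= res.p_two_sided <= 1.0
    assert res.p_greater < 0.05
    res_p = wilcoxon(x, y, mode="paired")
    assert res_p.method == "normal_approx"
    assert res_p.p_greater < 0.05


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.lists(st.integers(-40, 40), min_size=1, max_size=8),
       st.lists(st.integers(-40, 40), min_size=1, max_size=8))
def test_two_sided_p_symmetric_in_samples(xs, ys):
    a = wilcoxon(xs, ys)
    b = wilcoxon(ys, xs)
    assert a.p_two_sided == b.p_two_sided


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.lists(st.integers(-40, 40), min_size=1, max_size=8),
       st.lists(st.integers(-40, 40), min_size=1, max_size=8))
def test_p_invariant_under_strictly_increasing_transform(xs, ys):
    """Rank tests see only the ordering: cubing (strictly increasing,
    exact on small integers) must not change any p-value."""
    base = wilcoxon(xs, ys)
    cubed = wilcoxon([v ** 3 for v in xs], [v ** 3 for v in ys])
    assert base.p_two_sided == cubed.p_two_sided
    assert base.p_greater == cubed.p_greater


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.lists(st.integers(-40, 40), min_size=1, max_size=10))
def test_p_values_are_probabilities(xs):
    res = wilcoxon(xs, [v + 1 for v in xs], mode="paired")
    assert 0.0 <= res.p_two_sided <= 1.0
    assert 0.0 <= res.p_greater <= 1.0


def test_zero_alpha_grid_has_no_significant_cells(small_study):
    from cytosig.normalize import normalize_by_global_sd
    from cytosig.ranktests import significance_grid
    from cytosig.study import apply_censoring, average_replicates

    table, _ = small_study
    avg = average_replicates(
        normalize_by_global_sd(apply_censoring(table).data).data)
    grid = significance_grid(avg, table.design, table.panel, alpha=0.0)
    assert not grid["significant"].any()
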