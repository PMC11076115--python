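import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from tricksterbiogeo.biome_stats import (
    ContingencyTable2xK,
    chisq_2xk,
    conditional_probability,
    fdr_bh,
)
from tricksterbiogeo.gridding import CellId, ValidationError


def _cells(ids):
    return {CellId(f"FV1-{i}", 1) for i in ids}


def _pearson_by_hand(row_a, row_b):
    """Independent oracle: Pearson's statistic from first principles."""
    a, b = np.asarray(row_a, float), np.asarray(row_b, float)
    keep = (a + b) > 0
    a, b = a[keep], b[keep]
    n = a.sum() + b.sum()
    stat = 0.0
    for row in (a, b):
        for j in range(len(a)):
            expected = row.sum() * (a[j] + b[j]) / n
            stat += (row[j] - expected) ** 2 / expected
    return stat, len(a) - 1


class TestChiSquared:
    def test_identical_rows_give_zero_statistic(self):
        res = chisq_2xk(ContingencyTable2xK(("x", "y"), (10, 10), (10, 10)))
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_fully_separated_rows(self):
        res = chisq_2xk(ContingencyTable2xK(("x", "y"), (20, 0), (0, 20)))
        assert res.statistic == pytest.approx(40.0)
        assert res.df == 1
        assert res.p == pytest.approx(2.54e-10, rel=0.01)

    def test_zero_columns_dropped_before_test(self):
        res = chisq_2xk(ContingencyTable2xK(("x", "y", "z"), (5, 0, 3), (2, 0, 4)))
        assert res.df == 1 and res.n_dropped_columns == 1

    @given(
        st.lists(
            st.tuples(st.integers(0, 30), st.integers(0, 30)),
            min_size=3,
            max_size=8,
        ).filter(
            lambda cols: sum(1 for a, b in cols if a + b > 0) >= 2
            and sum(a for a, _ in cols) > 0
            and sum(b for _, b in cols) > 0
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_first_principles_oracle(self, cols):
        row_a = tuple(a for a, _ in cols)
        row_b = tuple(b for _, b in cols)
        res = chisq_2xk(ContingencyTable2xK(tuple("c%d" % i for i in range(len(cols))), row_a, row_b))
        stat, df = _pearson_by_hand(row_a, row_b)
        assert res.statistic == pytest.approx(stat, rel=1e-9)
        assert res.df == df
        assert res.p == pytest.approx(chi2.sf(stat, df), rel=1e-9)

    def test_invariant_under_row_swap_and_column_permutation(self):
        a, b = (5, 9, 1, 7), (3, 3, 8, 2)
        labels = ("w", "x", "y", "z")
        base = chisq_2xk(ContingencyTable2xK(labels, a, b))
        swapped = chisq_2xk(ContingencyTable2xK(labels, b, a))
        perm = [2, 0, 3, 1]
        permuted = chisq_2xk(
            ContingencyTable2xK(
                tuple(labels[i] for i in perm),
                tuple(a[i] for i in perm),
                tuple(b[i] for i in perm),
            )
        )
        assert base.statistic == pytest.approx(swapped.statistic)
        assert base.statistic == pytest.approx(permuted.statistic)

    def test_scaling_both_rows_scales_statistic(self):
        a, b = (5, 9, 1), (3, 3, 8)
        base = chisq_2xk(ContingencyTable2xK(("x", "y", "z"), a, b))
        scaled = chisq_2xk(
            ContingencyTable2xK(("x", "y", "z"), tuple(4 * v for v in a), tuple(4 * v for v in b))
        )
        assert scaled.statistic == pytest.approx(4 * base.statistic)
        assert scaled.df == base.df

    def test_too_few_columns_is_error(self):
        with pytest.raises(ValidationError):
            chisq_2xk(ContingencyTable2xK(("x", "y"), (5, 0), (3, 0)))

    def test_zero_row_sum_is_error(self):
        with pytest.raises(ValidationError):
            chisq_2xk(ContingencyTable2xK(("x", "y"), (0, 0), (3, 4)))

    def test_simulated_p_close_to_asymptotic_for_large_counts(self):
        t = ContingencyTable2xK(("x", "y", "z"), (50, 60, 40), (45, 70, 30))
        asym = chisq_2xk(t)
        sim = chisq_2xk(t, simulate_p=True, n_sim=2000, seed=7)
        assert sim.p == pytest.approx(asym.p, abs=0.05)


def _bh_by_hand(pvals):
    """Step-up recursion from the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, pvals[i] * m / rank)
        adjusted[i] = prev
    return adjusted


class TestFdrBH:
    def test_hand_computed_example(self):
        assert fdr_bh([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert fdr_bh([0.3]) == [0.3]

    def test_all_ones(self):
        assert fdr_bh([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            fdr_bh([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=15))
    @settings(max_examples=80)
    def test_matches_step_up_recursion_and_preserves_rank_order(self, pvals):
        adjusted = fdr_bh(pvals)
        assert adjusted == pytest.approx(_bh_by_hand(pvals), rel=1e-12)
        assert all(a >= p - 1e-15 and a <= 1.0 for a, p in zip(adjusted, pvals))
        order = sorted(range(len(pvals)), key=lambda i: pvals[i])
        ranked = [adjusted[i] for i in order]
        assert ranked == sorted(ranked)


class TestConditionalProbability:
    def test_subset_gives_probability_one(self):
        res = conditional_probability(_cells(range(5)), _cells(range(10)))
        assert res.p_hat == 1.0 and res.ci_high == pytest.approx(1.0)

    def test_disjoint_sets_give_zero(self):
        res = conditional_probability(_cells(range(5)), _cells(range(10, 20)))
        assert res.p_hat == 0.0 and res.ci_low == pytest.approx(0.0)

    def test_wilson_interval_closed_form(self):
        res = conditional_probability(_cells(range(10)), _cells(range(8)))
        assert res.p_hat == pytest.approx(0.8)
        # closed-form Wilson at z = 1.95996
        z = 1.959963984540054
        n, p = 10, 0.8
        denom = 1 + z**2 / n
        center = (p + z**2 / (2 * n)) / denom
        half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        assert res.ci_low == pytest.approx(center - half, abs=1e-9)
        assert res.ci_high == pytest.approx(center + half, abs=1e-9)
        assert (res.ci_low, res.ci_high) == pytest.approx((0.490, 0.943), abs=2e-3)

    def test_monotone_in_real_cells(self):
        trick = _cells(range(10))
        p1 = conditional_probability(trick, _cells(range(4))).p_hat
        p2 = conditional_probability(trick, _cells(range(5))).p_hat
        assert p2 >= p1

    def test_empty_trickster_set_is_error(self):
        with pytest.raises(ValidationError):
            conditional_probability(set(), _cells(range(3)))

    def test_invariants_on_result(self):
        res = conditional_probability(_cells(range(7)), _cells(range(3)))
        assert res.ci_low <= res.p_hat <= res.ci_high
        assert res.n_joint_cells <= res.n_trickster_cells

    def test_wilson_coverage_near_nominal(self):
        # known Bernoulli rate p=0.85, n=50, 10k simulated proportions
        rng = np.random.default_rng(12345)
        p_true, n, sims = 0.85, 50, 10_000
        k = rng.binomial(n, p_true, size=sims)
        from statsmodels.stats.proportion import proportion_confint

        low, high = proportion_confint(k, n, alpha=0.05, method="wilson")
        coverage = np.mean((low <= p_true) & (p_true <= high))
        assert abs(coverage - 0.95) <= 0.02
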