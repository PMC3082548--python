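import itertools
import statistics

import numpy as np
import pytest
from scipy import stats

from dyeswapde import (
    DegenerateStatisticError,
    SAMOneClass,
    choose_s0,
    fdr_table,
    permutation_null,
    sam_statistic,
)


# ---------------------------------------------------------------------------
# independent oracles: naive, loop-based re-derivations used only in tests
# ---------------------------------------------------------------------------

def oracle_d(values, s0):
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    se = (var ** 0.5) / n ** 0.5
    return mean, se, mean / (se + s0) if se + s0 > 0 else 0.0


def oracle_expected_order_stats(matrix, s0):
    """Enumerate all 2^n sign vectors; average sorted d across them."""
    n = matrix.shape[1]
    acc = None
    count = 0
    for signs in itertools.product((1, -1), repeat=n):
        ds = sorted(oracle_d([s * v for s, v in zip(signs, row)], s0)[2]
                    for row in matrix)
        acc = ds if acc is None else [a + b for a, b in zip(acc, ds)]
        count += 1
    return [a / count for a in acc], count


def oracle_fdr(matrix, s0, d_obs, expected, delta):
    """Cutpoints, called count and median false calls by direct loops."""
    pairs = sorted(zip(sorted(d_obs), expected))
    cut_up, cut_low = float("inf"), float("-inf")
    for d, e in pairs:
        if d - e >= delta:
            cut_up = min(cut_up, d)
        if d - e <= -delta:
            cut_low = max(cut_low, d)
    n_called = sum(1 for d in d_obs if d >= cut_up or d <= cut_low)
    counts = []
    n = matrix.shape[1]
    for signs in itertools.product((1, -1), repeat=n):
        c = 0
        for row in matrix:
            d = oracle_d([s * v for s, v in zip(signs, row)], s0)[2]
            if d >= cut_up or d <= cut_low:
                c += 1
        counts.append(c)
    med = statistics.median(counts)
    fdr = 0.0 if n_called == 0 else min(1.0, med / n_called)
    return cut_up, cut_low, n_called, med, fdr


class TestSamStatistic:
    @pytest.mark.parametrize(
        "values, s0, expected",
        [
            ((1.0, 1.2, 0.8, 1.0), 0.0, (1.0, 0.0816497, 12.2474487)),
            ((-1.0, 1.0), 5.0, (0.0, 1.0, 0.0)),
            ((1.0, 1.0, 1.0, 1.0), 1.0, (1.0, 0.0, 1.0)),
        ],
    )
    def test_worked_examples(self, values, s0, expected):
        x_bar, se, d = sam_statistic(np.array([values]), s0)
        assert x_bar[0] == pytest.approx(expected[0], abs=1e-6)
        assert se[0] == pytest.approx(expected[1], abs=1e-6)
        assert d[0] == pytest.approx(expected[2], abs=1e-6)

    def test_zero_denominator_with_nonzero_mean_is_an_error(self):
        with pytest.raises(DegenerateStatisticError):
            sam_statistic(np.array([[2.0, 2.0, 2.0]]), 0.0)

    def test_s0_zero_equals_one_sample_t(self):
        rng = np.random.default_rng(0)
        m = rng.normal(0.2, 1.0, size=(1000, 4))
        _, _, d = sam_statistic(m, 0.0)
        t = stats.ttest_1samp(m, 0.0, axis=1).statistic
        np.testing.assert_allclose(d, t, atol=1e-10)

    def test_d_decreases_with_se_for_fixed_positive_mean(self):
        base = np.array([1.0, 1.0, 1.0, 1.0])
        spreads = [0.01, 0.1, 0.5, 1.0]
        ds = []
        for s in spreads:
            v = base + s * np.array([-1.5, -0.5, 0.5, 1.5])
            v = v - v.mean() + 1.0
            ds.append(sam_statistic(v[None, :], 0.05)[2][0])
        assert all(a > b for a, b in zip(ds, ds[1:]))


class TestChooseS0:
    def test_identical_se_returns_that_value(self):
        m = np.tile([1.0, 2.0, 3.0, 4.0], (20, 1))
        m = m + np.arange(20)[:, None]  # same spread, shifted means
        se = np.std(m, axis=1, ddof=1) / 2
        assert choose_s0(m) == pytest.approx(se[0])

    def test_matches_naive_grid_scan(self):
        """Oracle: brute-force the CV criterion over the same grid."""
        rng = np.random.default_rng(1)
        scale = rng.uniform(0.2, 3.0, size=500)
        m = rng.normal(0, 1, size=(500, 4)) * scale[:, None]
        chosen = choose_s0(m)

        x = m.mean(axis=1)
        se = m.std(axis=1, ddof=1) / 2
        order = np.argsort(se, kind="stable")
        windows = np.array_split(order, min(100, 250))
        best, best_cv = None, np.inf
        for alpha in range(0, 101, 5):
            cand = np.percentile(se, alpha)
            d = x / (se + cand)
            v = [np.median(np.abs(d[w] - np.median(d[w]))) / 0.64
                 for w in windows]
            cv = np.std(v) / np.mean(v)
            if cv < best_cv - 1e-15:
                best_cv, best = cv, cand
        assert chosen == pytest.approx(best)

    def test_user_fixed_s0_skips_selection(self):
        m = np.random.default_rng(2).normal(size=(50, 4))
        res = SAMOneClass(m).fit(s0=0.0, permutations="exhaustive")
        assert res.s0 == 0.0


class TestPermutationNull:
    def test_exhaustive_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        m = rng.normal(0, 1, size=(20, 4))
        s0 = 0.1
        null = permutation_null(m, s0, "exhaustive")
        assert null.signs.shape == (16, 4)
        expected, count = oracle_expected_order_stats(m, s0)
        assert count == 16
        np.testing.assert_allclose(null.expected, expected, atol=1e-12)

    def test_all_zero_matrix_has_zero_expected(self):
        null = permutation_null(np.zeros((10, 4)), 0.5, "exhaustive")
        np.testing.assert_array_equal(null.expected, 0.0)

    def test_sampled_mode_is_seeded_deterministic(self):
        rng = np.random.default_rng(4)
        m = rng.normal(size=(30, 6))
        a = permutation_null(m, 0.1, 40, seed=123)
        b = permutation_null(m, 0.1, 40, seed=123)
        np.testing.assert_array_equal(a.expected, b.expected)

    def test_sampled_converges_to_exhaustive(self):
        rng = np.random.default_rng(5)
        m = rng.normal(size=(100, 4))
        s0 = 0.2
        ex = permutation_null(m, s0, "exhaustive")
        sm = permutation_null(m, s0, 1000, seed=7)
        assert np.abs(sm.expected - ex.expected).max() < 0.05


class TestFdrAndCalling:
    def separable_matrix(self):
        """5 genes with huge effects, 15 genes exactly zero."""
        rng = np.random.default_rng(6)
        strong = 5.0 + rng.normal(0, 0.05, size=(5, 4))
        strong[2:] *= -1
        null = np.zeros((15, 4))
        return np.vstack([strong, null])

    def test_fdr_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        m = rng.normal(0, 1, size=(12, 4))
        m[:3] += 4.0
        s0 = 0.1
        _, _, d = sam_statistic(m, s0)
        null = permutation_null(m, s0, "exhaustive")
        deltas = [0.5, 1.0, 2.0]
        table = fdr_table(d, null, deltas=np.array(deltas))
        for row, delta in zip(table.itertuples(), deltas):
            cu, cl, n_called, med, fdr = oracle_fdr(m, s0, d, null.expected,
                                                    delta)
            assert row.cut_up == pytest.approx(cu, abs=1e-12)
            assert row.cut_low == pytest.approx(cl, abs=1e-12)
            assert row.n_called == n_called
            assert row.median_false == pytest.approx(med, abs=1e-12)
            assert row.fdr == pytest.approx(fdr, abs=1e-12)

    def test_infinite_delta_calls_nothing_with_fdr_zero(self):
        m = self.separable_matrix()
        _, _, d = sam_statistic(m, 0.1)
        null = permutation_null(m, 0.1, "exhaustive")
        table = fdr_table(d, null, deltas=np.array([np.inf]))
        assert table["n_called"].iloc[0] == 0
        assert table["fdr"].iloc[0] == 0.0

    def test_separable_instance_called_exactly_at_zero_fdr(self):
        res = SAMOneClass(self.separable_matrix()).fit(
            s0="auto", permutations="exhaustive", fdr_max=0.0)
        assert sorted(res.called["gene_id"]) == [0, 1, 2, 3, 4]
        assert list(res.called.sort_values("gene_id")["direction"]) == [
            "up", "up", "down", "down", "down"]
        row = res.delta_table[res.delta_table["n_called"] == 5]
        assert (row["median_false"] == 0).any()

    def test_moderate_delta_on_pure_null_has_high_fdr(self):
        rng = np.random.default_rng(8)
        m = rng.normal(size=(50, 4))
        _, _, d = sam_statistic(m, 0.1)
        null = permutation_null(m, 0.1, "exhaustive")
        table = fdr_table(d, null)
        bulk = table[table["n_called"] >= 25]
        assert (bulk["fdr"] >= 0.5).all()

    def test_vacuous_threshold_calls_everything_past_smallest_delta(self):
        m = self.separable_matrix()
        res = SAMOneClass(m).fit(s0=0.1, permutations="exhaustive",
                                 fdr_max=1.0)
        first = res.delta_table.sort_values("delta").iloc[0]
        assert res.n_called == first["n_called"]

    def test_no_qualifying_delta_warns_and_returns_empty(self):
        m = np.array([[0.1, -0.1, 0.05, -0.05]] * 4)
        model = SAMOneClass(m + np.random.default_rng(9).normal(
            0, 0.01, m.shape))
        res = model.fit(s0=0.1, permutations="exhaustive", fdr_max=-1.0)
        assert res.n_called == 0

    def test_n_called_monotone_and_call_sets_nested(self):
        rng = np.random.default_rng(10)
        m = rng.normal(size=(80, 4))
        m[:10] += 3.0
        res0 = SAMOneClass(m).fit(s0="auto", permutations="exhaustive",
                                  fdr_max=0.0)
        tab = res0.delta_table.sort_values("delta")
        assert (np.diff(tab["n_called"]) <= 0).all()
        res10 = SAMOneClass(m).fit(s0="auto", permutations="exhaustive",
                                   fdr_max=0.10)
        assert set(res0.called["gene_id"]) <= set(res10.called["gene_id"])

    def test_null_matrices_rarely_call_many_genes(self):
        """Regression bound: at the 0% FDR threshold, pure-null matrices
        yield tiny call sets (the median-based estimate can admit a handful
        of knife-edge calls, but never a substantial set)."""
        rng = np.random.default_rng(11)
        n_called = []
        for _ in range(60):
            m = rng.normal(size=(100, 4))
            res = SAMOneClass(m).fit(s0="auto", permutations="exhaustive",
                                     fdr_max=0.0)
            n_called.append(res.n_called)
        assert np.mean(n_called) < 1.5
        assert np.quantile(n_called, 0.9) <= 3

    def test_summary_reports_counts(self):
        res = SAMOneClass(self.separable_matrix()).fit(
            s0="auto", permutations="exhaustive", fdr_max=0.0)
        text = res.summary()
        assert "called:          5 (up 2, down 3)" in text
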