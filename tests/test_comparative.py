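import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from reactionome import (
    aphaenogaster_category_counts,
    chi_square_independence,
    deviation_matrix,
    one_proportion_test,
    paired_rank_test,
    students_t_test,
    stuart_maxwell,
)
from reactionome.errors import ContractError, DegenerateDataError

TABLE = aphaenogaster_category_counts()

count_tables = st.integers(2, 5).flatmap(
    lambda r: st.integers(2, 5).flatmap(
        lambda c: st.lists(
            st.lists(st.integers(1, 200), min_size=c, max_size=c),
            min_size=r, max_size=r)))


class TestChiSquareIndependence:
    def test_category_table_statistic(self):
        r = chi_square_independence(TABLE.to_numpy(), yates=False)
        assert r.statistic == pytest.approx(302.896, abs=5e-4)
        assert r.df == 4 and r.p < 0.001

    def test_two_by_two_with_yates(self):
        r = chi_square_independence([[278, 1800], [117, 1961]], yates=True)
        assert r.statistic == pytest.approx(71.617, abs=5e-4)
        assert r.df == 1

    def test_identical_rows_give_zero(self):
        r = chi_square_independence([[5, 10, 15], [5, 10, 15]])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_yates_on_non_2x2_is_contract_error(self):
        with pytest.raises(ContractError):
            chi_square_independence([[1, 2, 3], [4, 5, 6]], yates=True)

    def test_zero_margin_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            chi_square_independence([[0, 0], [3, 4]])

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(count_tables)
    def test_matches_brute_force_and_scipy(self, rows):
        obs = np.array(rows, dtype=float)
        got = chi_square_independence(obs)
        # independent brute-force loop over cells
        r_m, c_m, n = obs.sum(axis=1), obs.sum(axis=0), obs.sum()
        acc = 0.0
        for i in range(obs.shape[0]):
            for j in range(obs.shape[1]):
                e = r_m[i] * c_m[j] / n
                acc += (obs[i, j] - e) ** 2 / e
        assert got.statistic == pytest.approx(acc, abs=1e-10)
        ref = stats.chi2_contingency(obs, correction=False)
        assert got.statistic == pytest.approx(ref[0], abs=1e-9)
        assert got.p == pytest.approx(ref[1], abs=1e-9)


class TestOneProportion:
    def test_exact_null_proportion_is_zero(self):
        r = one_proportion_test(50, 100, 0.5, correction=False)
        assert r.statistic == 0.0 and r.p == pytest.approx(1.0)

    def test_responsive_totals_with_correction(self):
        r = one_proportion_test(1968, 3917, 0.5, correction=True)
        assert r.statistic == pytest.approx(0.0827, abs=5e-5)
        assert r.p == pytest.approx(0.77, abs=5e-3)

    def test_correction_off_closed_form(self):
        r = one_proportion_test(1968, 3917, 0.5, correction=False)
        assert r.statistic == pytest.approx((1968 - 3917 * 0.5) ** 2
                                            / (3917 * 0.25), abs=1e-10)
        assert r.statistic == pytest.approx(0.0922, abs=5e-5)

    def test_empty_sample_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            one_proportion_test(0, 0, 0.5)


class TestStuartMaxwell:
    def test_symmetric_table_gives_zero(self):
        t = np.array([[10, 3, 2], [3, 8, 5], [2, 5, 12]])
        r = stuart_maxwell(t)
        assert r.statistic == pytest.approx(0.0, abs=1e-10)
        assert r.df == 2

    def test_2x2_equals_mcnemar_closed_form(self):
        r = stuart_maxwell([[10, 5], [1, 10]])
        assert r.statistic == pytest.approx(16.0 / 6.0, abs=1e-12)
        assert r.df == 1

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.lists(st.lists(st.integers(0, 50), min_size=2, max_size=2),
                    min_size=2, max_size=2))
    def test_2x2_mcnemar_equivalence_random(self, rows):
        b, c = rows[0][1], rows[1][0]
        if b + c == 0:
            return
        r = stuart_maxwell(rows)
        assert r.statistic == pytest.approx((b - c) ** 2 / (b + c), abs=1e-9)

    def test_invariant_under_simultaneous_permutation(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            t = rng.integers(1, 60, size=(5, 5))
            base = stuart_maxwell(t).statistic
            perm = rng.permutation(5)
            permuted = t[np.ix_(perm, perm)]
            assert stuart_maxwell(permuted).statistic == pytest.approx(
                base, rel=1e-8)

    def test_all_diagonal_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            stuart_maxwell(np.diag([4, 5, 6]))

    def test_matches_bhapkar_free_r_construction(self):
        """Independent oracle: explicit solve of d' S^-1 d via numpy."""
        t = np.array([[20, 10, 5, 2, 1],
                      [3, 30, 8, 4, 2],
                      [2, 6, 25, 9, 3],
                      [1, 3, 7, 18, 6],
                      [4, 2, 2, 5, 22]], dtype=float)
        rows_m, cols_m = t.sum(axis=1), t.sum(axis=0)
        d = (rows_m - cols_m)[:4]
        S = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                S[i, j] = (rows_m[i] + cols_m[i] - 2 * t[i, i]) if i == j \
                    else -(t[i, j] + t[j, i])
        expected = float(d @ np.linalg.solve(S, d))
        assert stuart_maxwell(t).statistic == pytest.approx(expected,
                                                            rel=1e-10)


class TestDeviationMatrix:
    def test_independent_table_is_all_zero(self):
        rows = np.array([10.0, 20.0])
        cols = np.array([0.3, 0.7])
        table = np.rint(np.outer(rows, cols * 10)).astype(int)
        dev = deviation_matrix(table).to_numpy()
        np.testing.assert_allclose(dev, 0.0, atol=1e-9)

    def test_diagonal_2x2(self):
        dev = deviation_matrix([[2, 0], [0, 2]]).to_numpy()
        np.testing.assert_allclose(dev, [[1, -1], [-1, 1]], atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(count_tables)
    def test_cells_always_sum_to_zero(self, rows):
        dev = deviation_matrix(np.array(rows)).to_numpy()
        assert abs(dev.sum()) < 1e-9


class TestStudentsT:
    def test_identical_samples_give_zero(self):
        r = students_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0

    def test_hand_computed_pooled_example(self):
        r = students_t_test([1, 2, 3, 4], [2, 3, 4, 5])
        assert r.statistic == pytest.approx(-1.0954, abs=5e-5)
        assert r.df == 6

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
        t1 = students_t_test(x, y).statistic
        t2 = students_t_test(7.3 * x, 7.3 * y).statistic
        assert t1 == pytest.approx(t2, rel=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(0, 1, 15), rng.normal(0.3, 1.2, 11)
        r = students_t_test(x, y)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert r.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert r.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_variance_unequal_means_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            students_t_test([1.0, 1.0], [2.0, 2.0])


class TestRankTests:
    def test_paired_all_positive_gives_maximal_v(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r = paired_rank_test(x, x + 1.0, paired=True)
        assert r.statistic == 15.0

    def test_paired_identical_is_degenerate(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateDataError):
            paired_rank_test(x, x, paired=True)

    def test_unpaired_symmetric_u(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        r = paired_rank_test(x, y, paired=False)
        assert r.statistic == pytest.approx(len(x) * len(y) / 2)

    def test_unpaired_matches_scipy(self):
        rng = np.random.default_rng(27)
        x, y = rng.normal(0, 1, 20), rng.normal(0.8, 1, 18)
        r = paired_rank_test(x, y, paired=False)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided")
        assert r.statistic == ref.statistic
        assert r.p == pytest.approx(ref.pvalue, rel=1e-9)
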