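"""Statistical procedures: t, chi-square, ANOVA, Pearson, alpha, LOWESS."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import qeegnorm as q
from qeegnorm.exceptions import ConfigError, DegenerateDataError


def summaries(rng, n_max=60):
    a = rng.normal(0, 1, rng.integers(5, n_max))
    b = rng.normal(0.4, 1.7, rng.integers(5, n_max))
    return a, b, q.summarize(a), q.summarize(b)


class TestTTest:
    def test_depression_scores_reproduce_published_welch_t(self):
        hc = q.TwoSampleSummary(260, 4.23, 3.52)
        mdd = q.TwoSampleSummary(221, 31.93, 10.50)
        res = q.t_test_from_summary(hc, mdd, "welch")
        assert res.t == pytest.approx(-37.47, abs=0.02)
        assert res.p < 0.001

    def test_anxiety_scores_reproduce_published_welch_df(self):
        hc = q.TwoSampleSummary(260, 1.95, 1.93)
        mdd = q.TwoSampleSummary(221, 22.28, 9.91)
        res = q.t_test_from_summary(hc, mdd, "welch")
        assert res.df == pytest.approx(234.21, abs=0.05)
        assert res.t == pytest.approx(-30.00, abs=0.05)

    @pytest.mark.parametrize("variant", ["pooled", "welch"])
    def test_matches_scipy_from_stats(self, variant, rng):
        _, _, sa, sb = summaries(rng)
        res = q.t_test_from_summary(sa, sb, variant)
        t_ref, p_ref = sps.ttest_ind_from_stats(
            sa.mean, sa.sd, sa.n, sb.mean, sb.sd, sb.n,
            equal_var=(variant == "pooled"))
        assert res.t == pytest.approx(t_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, abs=1e-12)

    @pytest.mark.parametrize("variant", ["pooled", "welch"])
    def test_summary_path_equals_raw_data_test(self, variant, rng):
        a, b, sa, sb = summaries(rng)
        res = q.t_test_from_summary(sa, sb, variant)
        t_ref, p_ref = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
        assert res.t == pytest.approx(t_ref, abs=1e-10)
        assert res.p == pytest.approx(p_ref, abs=1e-10)

    def test_equal_means_give_zero_t(self):
        s = q.TwoSampleSummary(10, 5.0, 2.0)
        assert q.t_test_from_summary(
            s, q.TwoSampleSummary(15, 5.0, 7.0), "welch").t == 0.0

    def test_degenerate_variances_raise(self):
        s = q.TwoSampleSummary(10, 5.0, 0.0)
        with pytest.raises(DegenerateDataError):
            q.t_test_from_summary(s, s, "pooled")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(n1=st.integers(3, 200), n2=st.integers(3, 200),
           sd1=st.floats(0.1, 20), sd2=st.floats(0.1, 20))
    def test_welch_df_never_exceeds_pooled_df(self, n1, n2, sd1, sd2):
        a = q.TwoSampleSummary(n1, 0.0, sd1)
        b = q.TwoSampleSummary(n2, 1.0, sd2)
        welch_df = q.t_test_from_summary(a, b, "welch").df
        assert welch_df <= n1 + n2 - 2 + 1e-9
        if n1 == n2 and sd1 == sd2:
            assert welch_df == pytest.approx(n1 + n2 - 2)


class TestChiSquare:
    def test_sex_by_group_table(self):
        res = q.chi_square([[130, 130], [163, 58]])
        assert res.chi2 == pytest.approx(28.32, abs=0.005)
        assert res.df == 1
        assert res.p < 0.001

    def test_education_by_group_table(self):
        table = [[2, 4, 32, 33, 113, 76], [6, 20, 66, 32, 77, 20]]
        res = q.chi_square(table)
        assert res.chi2 == pytest.approx(61.21, abs=0.005)
        assert res.df == 5

    def test_perfect_fit_gives_zero(self):
        res = q.chi_square([[10, 20], [20, 40]])
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_adjusted_residuals_flag_departing_cells(self):
        res = q.chi_square([[2, 4, 32, 33, 113, 76],
                            [6, 20, 66, 32, 77, 20]])
        flags = np.abs(res.adjusted_residuals) > 1.96
        # graduate-school and junior-high cells drive the association
        assert flags[0, 5] and flags[0, 1]
        # junior-college cell does not
        assert not flags[0, 3]

    def test_invariant_under_permutation(self, rng):
        table = rng.integers(5, 50, (3, 4))
        base = q.chi_square(table).chi2
        perm = q.chi_square(table[::-1, ::-1]).chi2
        assert base == pytest.approx(perm, rel=1e-12)

    def test_observed_minus_expected_margins_vanish(self, rng):
        table = rng.integers(5, 50, (3, 4))
        res = q.chi_square(table)
        o_minus_e = table - res.expected
        assert np.allclose(o_minus_e.sum(axis=0), 0, atol=1e-9)
        assert np.allclose(o_minus_e.sum(axis=1), 0, atol=1e-9)

    def test_continuity_correction_flag(self):
        uncorrected = q.chi_square([[130, 130], [163, 58]]).chi2
        corrected = q.chi_square([[130, 130], [163, 58]],
                                 correction=True).chi2
        assert corrected < uncorrected

    def test_degenerate_margin_rejected(self):
        with pytest.raises(DegenerateDataError):
            q.chi_square([[0, 0], [5, 10]])


class TestAnova:
    def test_two_groups_f_equals_t_squared(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(1, 1, 25)
        res = q.one_way_anova([a, b])
        t = sps.ttest_ind(a, b, equal_var=True).statistic
        assert res.F == pytest.approx(t ** 2, rel=1e-10)
        assert (res.df_between, res.df_within) == (1, 43)

    def test_identical_constant_groups_rejected(self):
        with pytest.raises(DegenerateDataError):
            q.one_way_anova([[3.0, 3.0], [3.0, 3.0]])

    def test_posthoc_flags_only_shifted_group(self, rng):
        groups = [rng.normal(0, 1, 50), rng.normal(0, 1, 50),
                  rng.normal(3, 1, 50)]
        comparisons = q.bonferroni_posthoc(groups)
        flagged = {(c.i, c.j) for c in comparisons if c.significant}
        assert flagged == {(0, 2), (1, 2)}

    def test_bonferroni_inflates_and_caps(self, rng):
        groups = [rng.normal(0, 1, 10) for _ in range(4)]
        for c in q.bonferroni_posthoc(groups):
            assert c.p_adjusted >= c.p_raw
            assert c.p_adjusted <= 1.0


class TestPearson:
    def test_identity_and_affine_extremes(self):
        x = np.arange(10.0)
        assert q.pearson_r(x, x)[0] == pytest.approx(1.0)
        assert q.pearson_r(x, -2 * x + 7)[0] == pytest.approx(-1.0)

    def test_matches_direct_covariance_formula(self):
        x = np.array([1.2, 3.4, 2.2, 5.6, 4.4, 7.1, 0.3, 6.6, 5.0, 2.8])
        y = np.array([0.7, 2.9, 1.5, 4.8, 5.2, 6.0, 1.1, 5.9, 4.1, 3.3])
        r, _ = q.pearson_r(x, y)
        direct = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert r == pytest.approx(direct, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            q.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCronbachAlpha:
    def test_identical_items_give_one(self, rng):
        v = rng.normal(0, 1, 30)
        assert q.cronbach_alpha(np.column_stack([v, v, v])) == \
            pytest.approx(1.0)

    def test_independent_items_near_zero(self, rng):
        m = rng.normal(0, 1, (3000, 3))
        assert abs(q.cronbach_alpha(m)) < 0.1

    def test_hand_matrix_matches_direct_formula(self):
        m = np.array([[1.0, 2.0, 3.0],
                      [2.0, 3.0, 2.0],
                      [4.0, 5.0, 6.0],
                      [3.0, 3.0, 4.0]])
        k = 3
        expected = k / (k - 1) * (1 - m.var(axis=0, ddof=1).sum()
                                  / m.sum(axis=1).var(ddof=1))
        assert q.cronbach_alpha(m) == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        m = rng.normal(10, 2, (40, 3)) + rng.normal(0, 1, (40, 1))
        ours = q.cronbach_alpha(m)
        theirs = pingouin.cronbach_alpha(data=pd.DataFrame(m))[0]
        assert ours == pytest.approx(theirs, abs=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(shift=st.floats(-50, 50), perm=st.permutations([0, 1, 2]))
    def test_invariant_to_item_shift_and_relabeling(self, shift, perm):
        rng = np.random.default_rng(7)
        m = rng.normal(0, 1, (20, 3)) + rng.normal(0, 1, (20, 1))
        shifted = m.copy()
        shifted[:, 0] += shift
        assert q.cronbach_alpha(shifted) == pytest.approx(
            q.cronbach_alpha(m), abs=1e-9)
        assert q.cronbach_alpha(m[:, perm]) == pytest.approx(
            q.cronbach_alpha(m), abs=1e-9)

    def test_central_electrode_alpha_is_high_on_shared_signal(self, rng):
        # participants x {C3, Cz, C4}: shared subject effect dominates
        subject = rng.normal(15, 4, (100, 1))
        m = subject + rng.normal(0, 1, (100, 3))
        assert q.cronbach_alpha(m) > 0.9


class TestLowess:
    def test_reproduces_linear_trend(self):
        x = np.linspace(20, 70, 60)
        y = 0.5 * x + 3
        curve = q.lowess_trend(x, y, fraction=0.5)
        np.testing.assert_allclose(curve[:, 1], 0.5 * curve[:, 0] + 3,
                                   atol=1e-6)

    def test_constant_input_gives_constant_curve(self):
        x = np.linspace(0, 10, 30)
        curve = q.lowess_trend(x, np.full(30, 4.2), fraction=0.4)
        np.testing.assert_allclose(curve[:, 1], 4.2, atol=1e-9)

    def test_tracks_noisy_quadratic_within_noise_sd(self, rng):
        x = np.sort(rng.uniform(-2, 2, 400))
        noise_sd = 0.3
        y = x ** 2 + rng.normal(0, noise_sd, 400)
        curve = q.lowess_trend(x, y, fraction=0.3)
        inner = (curve[:, 0] > -1.5) & (curve[:, 0] < 1.5)
        dev = np.abs(curve[inner, 1] - curve[inner, 0] ** 2)
        assert dev.max() < noise_sd

    def test_bad_fraction_rejected(self):
        with pytest.raises(ConfigError):
            q.lowess_trend(np.arange(10.0), np.arange(10.0), fraction=0.0)
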