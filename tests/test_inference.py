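"""The 2x2 repeated-measures battery and its companion tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netstress import (CohortTable, ancova_interaction, chi_square_2x2,
                       correlation_p, correlation_test, duration_analysis,
                       fdr_adjust, group_contrast, mann_whitney,
                       mixed_anova_2x2, percent_difference, simple_effect)


def make_cohort(pre_ptsd, post_ptsd, pre_mdd, post_mdd, **extra_cols):
    n1, n2 = len(pre_ptsd), len(pre_mdd)
    df = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n1 + n2)],
        "group": ["PTSD"] * n1 + ["MDD"] * n2,
        "strength_pre": list(pre_ptsd) + list(pre_mdd),
        "strength_post": list(post_ptsd) + list(post_mdd),
    })
    for k, v in extra_cols.items():
        df[k] = v
    return CohortTable(subjects=df)


def random_cohort(rng, n1=10, n2=10):
    return make_cohort(rng.normal(0.13, 0.03, n1), rng.normal(0.12, 0.03, n1),
                       rng.normal(0.14, 0.03, n2), rng.normal(0.14, 0.03, n2))


class TestMixedAnova:
    def test_constant_cohort_gives_zero_F(self):
        cohort = make_cohort([1.0] * 3, [1.0] * 3, [1.0] * 3, [1.0] * 3)
        res = mixed_anova_2x2(cohort)
        for effect in ("group", "stress", "interaction"):
            assert res[effect].F == 0.0
            assert res[effect].p == 1.0

    def test_f_equals_t_squared_oracles(self, rng):
        """Group F = t^2 on subject means; interaction F = t^2 on diffs."""
        for _ in range(100):
            cohort = random_cohort(rng)
            res = mixed_anova_2x2(cohort)
            g = (cohort.subjects["group"] == "PTSD").to_numpy()
            t_g = stats.ttest_ind(cohort.means[g], cohort.means[~g]).statistic
            t_i = stats.ttest_ind(cohort.diffs[g], cohort.diffs[~g]).statistic
            assert res["group"].F == pytest.approx(t_g**2, abs=1e-10)
            assert res["interaction"].F == pytest.approx(t_i**2, abs=1e-10)
            assert res["group"].df2 == res["interaction"].df2 == cohort.n - 2

    def test_interaction_equals_contrast_difference_identity(self, rng):
        """(delta_PTSD - delta_MDD) == (group diff post - group diff pre)."""
        for _ in range(100):
            cohort = random_cohort(rng, n1=rng.integers(3, 15), n2=rng.integers(3, 15))
            d_ptsd = simple_effect(cohort, "PTSD").signed_difference
            d_mdd = simple_effect(cohort, "MDD").signed_difference
            gd_post = group_contrast(cohort, "post").signed_difference
            gd_pre = group_contrast(cohort, "pre").signed_difference
            assert d_ptsd - d_mdd == pytest.approx(gd_post - gd_pre, abs=1e-12)

    def test_too_small_group_errors(self):
        with pytest.raises(ValueError):
            mixed_anova_2x2(make_cohort([1.0], [2.0], [1.0, 2.0], [2.0, 1.0]))

    def test_p_consistent_with_F(self, rng):
        res = mixed_anova_2x2(random_cohort(rng))
        for r in res.values():
            assert r.p == pytest.approx(stats.f.sf(r.F, r.df1, r.df2), abs=1e-12)


class TestSimpleEffect:
    def test_hand_computed_paired_t(self):
        # differences (post - pre) of 1, 2, 3, 6
        cohort = make_cohort([0, 0, 0, 0], [1, 2, 3, 6], [0, 0], [0, 0.5])
        eff = simple_effect(cohort, "PTSD")
        assert eff.signed_difference == pytest.approx(3.0)
        assert eff.sem == pytest.approx(1.0801234, abs=1e-6)
        assert eff.t == pytest.approx(2.7775, abs=1e-4)
        assert eff.p == pytest.approx(2 * stats.t.sf(2.7775, 3), abs=1e-4)

    def test_constant_shift_is_degenerate(self):
        pre = [0.1, 0.2, 0.3]
        post = [x + 0.05 for x in pre]
        cohort = make_cohort(pre, post, [0.1, 0.2], [0.1, 0.25])
        with pytest.raises(ValueError, match="identical"):
            simple_effect(cohort, "PTSD")

    def test_direction_reported_as_magnitude(self):
        cohort = make_cohort([0.2, 0.3, 0.4], [0.1, 0.25, 0.3],
                             [0.1, 0.2], [0.1, 0.25])
        eff = simple_effect(cohort, "PTSD")
        assert eff.direction == "decrease"
        assert eff.mean_difference > 0
        assert eff.signed_difference < 0

    def test_recovers_injected_decrement(self, rng):
        n = 28
        pre = rng.normal(0.13, 0.03, n)
        post = pre - 0.013 + rng.normal(0, 0.026, n)
        cohort = make_cohort(pre, post, [0.1, 0.2], [0.12, 0.21])
        eff = simple_effect(cohort, "PTSD")
        assert abs(eff.signed_difference - (-0.013)) < 3 * eff.sem


class TestGroupContrast:
    def test_hand_computed_independent_t(self):
        cohort = make_cohort([4.0, 5.0, 6.0], [4, 5, 6], [1.0, 2.0, 3.0], [1, 2, 3])
        eff = group_contrast(cohort, "pre")
        assert eff.mean_difference == pytest.approx(3.0)
        assert eff.sem == pytest.approx(0.8165, abs=1e-4)
        assert eff.t == pytest.approx(3.674, abs=1e-3)
        assert eff.df == 4

    def test_identical_groups_give_p_one(self):
        cohort = make_cohort([1.0, 2.0, 3.0], [1, 2, 3], [1.0, 2.0, 3.0], [1, 2, 3])
        eff = group_contrast(cohort, "pre")
        assert eff.mean_difference == 0.0
        assert eff.p == pytest.approx(1.0)


class TestPercentDifference:
    @pytest.mark.parametrize("effect,ref,expected", [
        (0.0, 0.5, 0.0),
        (0.013, 0.13, 10.0),
        (-0.5, 2.0, -25.0),
    ])
    def test_values(self, effect, ref, expected):
        assert percent_difference(effect, ref) == pytest.approx(expected)

    def test_zero_reference_errors(self):
        with pytest.raises(ValueError):
            percent_difference(0.1, 0.0)


class TestAncova:
    def test_constant_covariate_dropped(self, rng):
        cohort = random_cohort(rng)
        base = mixed_anova_2x2(cohort)["interaction"]
        cohort2 = CohortTable(subjects=cohort.subjects.assign(zeros=0.0))
        adj = ancova_interaction(cohort2, ["zeros"])
        assert adj.F == pytest.approx(base.F, abs=1e-12)
        assert adj.df2 == base.df2

    def test_df2_accounting_n52_k11(self, rng):
        n1, n2, k = 28, 24, 11
        cov = {f"c{i}": rng.normal(size=n1 + n2) for i in range(k)}
        cohort = make_cohort(rng.normal(size=n1), rng.normal(size=n1),
                             rng.normal(size=n2), rng.normal(size=n2), **cov)
        adj = ancova_interaction(cohort, list(cov))
        assert adj.df2 == 39

    def test_collinear_covariates_named(self, rng):
        x = rng.normal(size=20)
        cohort = make_cohort(rng.normal(size=10), rng.normal(size=10),
                             rng.normal(size=10), rng.normal(size=10),
                             age=x, age2=2 * x + 1)
        with pytest.raises(ValueError, match="age.*age2"):
            ancova_interaction(cohort, ["age", "age2"])

    def test_noise_covariate_preserves_type_i_error(self, rng):
        """Adding a pure-noise covariate keeps the null rejection rate at
        alpha (reduced replicate count; the band widens accordingly)."""
        reps, rej = 800, 0
        for _ in range(reps):
            pre = rng.normal(0.13, 0.03, 20)
            post = pre + rng.normal(0, 0.026, 20)
            cohort = make_cohort(pre[:10], post[:10], pre[10:], post[10:],
                                 noise=rng.normal(size=20))
            rej += ancova_interaction(cohort, ["noise"]).p <= 0.05
        assert 0.03 <= rej / reps <= 0.07


class TestCorrelation:
    def test_zero_r_gives_p_one(self):
        assert correlation_p(0.0, 28).p == pytest.approx(1.0)

    @pytest.mark.parametrize("r,n,printed", [
        (0.25, 28, 0.20),
        (0.34, 28, 0.08),
        (0.14, 24, 0.51),
        (0.376, 28, 0.048),  # avoidance subscale; recomputes to 0.049
    ])
    def test_reported_severity_pvalues(self, r, n, printed):
        tol = 0.002 if r == 0.376 else 0.005
        assert abs(correlation_p(r, n).p - printed) <= tol

    def test_perfect_correlation_flagged(self):
        res = correlation_p(1.0, 10)
        assert res.p == 0.0 and res.degenerate

    def test_small_n_errors(self):
        with pytest.raises(ValueError):
            correlation_p(0.5, 3)

    def test_correlation_test_matches_scipy(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = correlation_test(x, y)
        ref = stats.pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)


class TestChiSquare:
    @pytest.mark.parametrize("table,printed", [
        ((19, 9, 16, 8), 0.93),    # sex (male) by group
        ((8, 20, 3, 21), 0.16),    # panic disorder
        ((3, 25, 2, 22), 0.77),    # substance use
        ((5, 23, 2, 22), 0.32),    # alcohol use
    ])
    def test_reported_comorbidity_pvalues(self, table, printed):
        assert round(chi_square_2x2(*table).p, 2) == printed

    def test_balanced_table_is_null(self):
        res = chi_square_2x2(5, 5, 5, 5)
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_matches_scipy_without_correction(self):
        res = chi_square_2x2(8, 20, 3, 21)
        ref = stats.chi2_contingency([[8, 20], [3, 21]], correction=False)
        assert res.chi2 == pytest.approx(ref.statistic, abs=1e-12)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            chi_square_2x2(0, 0, 3, 4)


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        assert mann_whitney([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_fully_separated_small_samples_exact(self):
        # U = 0; 2 of the 20 arrangements are as extreme
        assert mann_whitney([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_null_p_is_uniform(self, rng):
        """Large-sample asymptotic p-values are uniform under the null."""
        ps = [mann_whitney(rng.normal(size=30), rng.normal(size=30))
              for _ in range(400)]
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestFDR:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.037]), [0.037])

    def test_step_up_hand_computation(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_adjusted_dominate_raw_and_bonferroni_dominates_bh(self, rng):
        p = rng.uniform(size=25)
        bh = fdr_adjust(p)
        bonf = fdr_adjust(p, method="bonferroni")
        assert (bh >= p - 1e-15).all() and (bh <= 1.0).all()
        assert (bonf >= bh - 1e-15).all()

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestDurationAnalysis:
    def test_identical_halves_null_time_effects(self):
        cohort = make_cohort([0.1, 0.2, 0.3], [0.1, 0.2, 0.3],
                             [0.2, 0.4], [0.2, 0.4])
        res = duration_analysis(cohort)
        assert res["time"].F == 0.0
        assert res["interaction"].F == 0.0

    def test_t_squared_oracle(self, rng):
        cohort = random_cohort(rng)
        res = duration_analysis(cohort)
        g = (cohort.subjects["group"] == "PTSD").to_numpy()
        t_i = stats.ttest_ind(cohort.diffs[g], cohort.diffs[~g]).statistic
        assert res["interaction"].F == pytest.approx(t_i**2, abs=1e-10)

    def test_group_specific_drift_detected_at_predicted_power(self, rng):
        """A +delta second-half shift in one group is detected at the rate
        the two-sample power model predicts."""
        from netstress import PowerQuery, power_of

        n1 = n2 = 12
        d = 1.1
        sigma = 0.03
        predicted = power_of(PowerQuery(design="between_on_differences",
                                        n1=n1, n2=n2, d=d)).power
        reps, rej = 600, 0
        for _ in range(reps):
            h1 = rng.normal(0.13, 0.03, n1 + n2)
            shift = np.r_[np.full(n1, d * sigma), np.zeros(n2)]
            h2 = h1 + shift + rng.normal(0, sigma, n1 + n2)
            cohort = make_cohort(h1[:n1], h2[:n1], h1[n1:], h2[n1:])
            rej += duration_analysis(cohort)["interaction"].p <= 0.05
        assert abs(rej / reps - predicted) < 0.05
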