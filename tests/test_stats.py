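"""Group statistics, correlations, bootstrap CIs and multiplicity handling."""

import numpy as np
import pytest
from scipy import stats as sps

import restconn as rc
from restconn import synthetic


class TestTwoSampleT:
    def test_printed_mmse_summary_reproduces_t(self):
        t, p, df = rc.two_sample_t((29.65, 0.6, 17), (28.41, 1.4, 17))
        assert round(t, 1) == 3.4
        assert df == 32
        assert p < 0.01

    def test_identical_samples_null(self):
        x = np.arange(10.0)
        t, p, _ = rc.two_sample_t(x, x.copy())
        assert t == 0.0 and p == 1.0

    def test_large_n_unit_shift(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(1000)
        y = rng.standard_normal(1000) + 1.0
        _, p, _ = rc.two_sample_t(x, y)
        assert p < 1e-10

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError):
            rc.two_sample_t(np.ones(5), np.zeros(5))


class TestChiSquare:
    @pytest.mark.parametrize(
        "table,expected",
        [([[10, 10], [10, 10]], 0.0), ([[13, 5], [13, 5]], 0.0), ([[20, 0], [0, 20]], 40.0)],
    )
    def test_known_tables(self, table, expected):
        chi2, _p = rc.chi_square(np.array(table))
        assert chi2 == pytest.approx(expected)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            rc.chi_square(np.array([[0, 0], [5, 5]]))


class TestFriedman:
    def test_identical_conditions_null(self):
        m = np.tile(np.arange(10.0)[:, None], (1, 3))
        stat, _ = rc.friedman_test(m)
        assert stat == 0.0

    def test_perfect_ordering_significant(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal((10, 1))
        m = np.hstack([base, base + 10, base + 20])
        _, p = rc.friedman_test(m)
        assert p < 0.05

    def test_condition_permutation_invariance(self):
        rng = np.random.default_rng(2)
        m = rng.standard_normal((8, 4))
        s1, _ = rc.friedman_test(m)
        s2, _ = rc.friedman_test(m[:, [2, 0, 3, 1]])
        assert s1 == pytest.approx(s2)


class TestSpearman:
    def test_monotone_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
        r, _ = rc.spearman(x, np.exp(x))
        assert r == pytest.approx(1.0)

    def test_antitone_is_minus_one(self):
        x = np.arange(10.0)
        r, _ = rc.spearman(x, x[::-1])
        assert r == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            rc.spearman(np.ones(10), np.arange(10.0))


class TestPartialCorr:
    def test_independent_covariate_preserves_r(self):
        rng = np.random.default_rng(3)
        n = 500
        x = rng.standard_normal(n)
        y = 0.6 * x + 0.8 * rng.standard_normal(n)
        covar = rng.standard_normal(n)
        r_u, _ = rc.spearman(x, y)
        r_p, _ = rc.partial_corr(x, y, covar)
        assert r_p == pytest.approx(r_u, abs=0.05)

    def test_fully_explained_variable(self):
        rng = np.random.default_rng(4)
        covar = rng.standard_normal(200)
        x = rng.standard_normal(200)
        r, _ = rc.partial_corr(x, covar, covar, method="pearson")
        assert abs(r) < 0.1

    def test_known_trivariate_normal_partial(self):
        # construct exact partial correlation 0.5 given the covariate
        rng = np.random.default_rng(5)
        n = 2000
        z = rng.standard_normal(n)
        ex, ey = rng.standard_normal((2, n))
        x = z + ex
        y = z + 0.5 * ex + np.sqrt(1 - 0.25) * ey
        # residual corr = corr(ex, 0.5 ex + sqrt(.75) ey) = 0.5
        r, _ = rc.partial_corr(x, y, z, method="pearson")
        assert 0.45 <= r <= 0.55

    def test_fully_explained_by_covariate_gives_null(self):
        x = np.arange(10.0)
        r, p = rc.partial_corr(x, np.arange(10.0) * 2, x, method="pearson")
        assert r == 0.0 and p == 1.0


class TestBootstrapCI:
    def test_exactly_linear_data_degenerate_ci(self):
        x = np.arange(20.0)
        lo, hi, sig = rc.bootstrap_ci(
            lambda a, b: sps.pearsonr(a, b)[0], (x, 2 * x + 1), n_boot=200, seed=0
        )
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)
        assert sig

    def test_null_correlation_rarely_flagged(self):
        flags = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            x, y = rng.standard_normal((2, 50))
            _, _, sig = rc.bootstrap_ci(
                lambda a, b: sps.pearsonr(a, b)[0], (x, y), n_boot=200, seed=seed
            )
            flags += int(sig)
        assert flags <= 8  # <= ~10% of 40 runs at the 95% level

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(10)
        x, y = rng.standard_normal((2, 30))
        a = rc.bootstrap_ci(lambda u, v: sps.pearsonr(u, v)[0], (x, y), seed=3)
        b = rc.bootstrap_ci(lambda u, v: sps.pearsonr(u, v)[0], (x, y), seed=3)
        assert a == b

    def test_coverage_of_normal_mean(self):
        # 95% CI covers the true mean in [90%, 99%] of 100 draws at n = 100
        covered = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            x = rng.standard_normal(100)
            lo, hi, _ = rc.bootstrap_ci(np.mean, x, n_boot=300, seed=seed)
            covered += int(lo <= 0.0 <= hi)
        assert 90 <= covered <= 99


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expected", [(0.01, 5, 0.05), (0.5, 30, 1.0), (0.0, 100, 0.0)]
    )
    def test_adjustment(self, p, m, expected):
        assert rc.bonferroni([p], m=m)[0] == pytest.approx(expected)

    def test_family_smaller_than_pvals_rejected(self):
        with pytest.raises(ValueError):
            rc.bonferroni([0.1, 0.2, 0.3], m=2)


class TestKSNormality:
    def test_normal_sample_usually_passes(self):
        hits = 0
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(1000)
            _, p = rc.ks_normality(x)
            hits += int(p > 0.05)
        assert hits >= 18

    def test_exponential_sample_rejected(self):
        x = np.random.default_rng(0).exponential(size=1000)
        _, p = rc.ks_normality(x)
        assert p < 0.01

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            rc.ks_normality(np.arange(5.0))


class TestBatteriesOnCohort:
    def test_subject_order_invariance(self):
        t, _ = synthetic.simulate_cohort(synthetic.CohortSpec(seed=0))
        shuffled = t.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = rc.group_comparison_battery(t)
        b = rc.group_comparison_battery(shuffled)
        np.testing.assert_allclose(
            a.sort_values(["measure", "band"]).t.to_numpy(),
            b.sort_values(["measure", "band"]).t.to_numpy(),
        )

    def test_battery_flags_designed_effects(self):
        t, _ = synthetic.simulate_cohort(synthetic.CohortSpec(seed=2))
        bat = rc.group_comparison_battery(t)
        sig = set(zip(bat[bat.significant].measure, bat[bat.significant].band))
        assert ("power", "alpha") in sig and ("power", "beta") in sig

    def test_clinical_interactions_find_suvr_link(self):
        t, _ = synthetic.simulate_cohort(
            synthetic.CohortSpec(n_per_group=60, seed=3)
        )
        out = rc.clinical_interaction_analysis(
            t, covariates=("suvr",), n_boot=300, seed=0
        )
        alpha_coh = out[(out.measure == "coherence") & (out.band == "alpha")].iloc[0]
        assert alpha_coh.r < -0.3
        assert alpha_coh.significant
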