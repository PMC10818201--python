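import numpy as np
import pytest
from scipy import stats

from morphgreml.datasets import cohort_model_comparison
from morphgreml.greml import (GREML, ConvergenceOrderingError, clean_design,
                              compare_models, fdr_adjust, fit_greml,
                              likelihood_ratio_test, restricted_loglik,
                              wald_p_value)
from conftest import random_pd_matrix


class TestRestrictedLoglik:
    def test_intercept_only_maximized_at_sample_variance(self):
        """For V = s2*I the REML maximum is the divisor-(n-1) variance;
        y = [1,2,3] has sample variance exactly 1."""
        y = np.array([1.0, 2.0, 3.0])
        X = np.ones((3, 1))
        I = np.eye(3)
        at_one = restricted_loglik(y, X, [I], [1.0])
        for s2 in (0.5, 0.8, 1.2, 2.0):
            assert at_one > restricted_loglik(y, X, [I], [s2])
        eps = 1e-6
        deriv = (restricted_loglik(y, X, [I], [1.0 + eps])
                 - restricted_loglik(y, X, [I], [1.0 - eps])) / (2 * eps)
        assert abs(deriv) < 1e-4

    def test_matches_naive_dense_oracle(self, rng):
        """Twenty random n=10 instances against a direct explicit-inverse,
        explicit-determinant evaluation."""
        for _ in range(20):
            n = 10
            y = rng.standard_normal(n)
            X = np.column_stack([np.ones(n), rng.standard_normal(n)])
            K1 = random_pd_matrix(rng, n)
            K2 = random_pd_matrix(rng, n)
            theta = rng.uniform(0.2, 1.5, size=3)
            Ks = [K1, K2, np.eye(n)]
            V = sum(t * K for t, K in zip(theta, Ks))
            Vinv = np.linalg.inv(V)
            M = X.T @ Vinv @ X
            P = Vinv - Vinv @ X @ np.linalg.inv(M) @ X.T @ Vinv
            naive = -0.5 * (np.log(np.linalg.det(V))
                            + np.log(np.linalg.det(M)) + y @ P @ y)
            assert restricted_loglik(y, X, Ks, theta) == pytest.approx(naive, abs=1e-8)

    def test_invariant_to_duplicated_design_column(self, rng):
        n = 12
        y = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        X_dup = np.column_stack([X, X[:, 1]])
        K = random_pd_matrix(rng, n)
        base = restricted_loglik(y, X, [K, np.eye(n)], [0.5, 0.5])
        assert restricted_loglik(y, X_dup, [K, np.eye(n)], [0.5, 0.5]) == \
            pytest.approx(base, abs=1e-10)

    def test_clean_design_drops_aliased_columns_only(self, rng):
        X = np.column_stack([np.ones(10), rng.standard_normal(10)])
        cleaned = clean_design(np.column_stack([X, X @ [2.0, -1.0]]))
        assert cleaned.shape[1] == 2


class TestFitGreml:
    def test_identity_only_fit_equals_ols_residual_variance(self, rng):
        n, p = 40, 3
        X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
        y = X @ rng.standard_normal(p) + rng.standard_normal(n)
        fit = fit_greml(y, X, [])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(((y - X @ beta) ** 2).sum())
        assert fit.varcomp_["sigma2_e"] == pytest.approx(rss / (n - p), rel=1e-6)

    def test_missing_rows_dropped_before_fit(self, small_cohort):
        c = small_cohort
        y = c.phenotype.copy()
        y[:5] = np.nan
        fit = fit_greml(y, c.X, [c.grm, c.brm])
        assert fit.n_ == c.config.n_subjects - 5

    def test_estimates_scale_with_phenotype_units(self, small_cohort):
        """Multiplying y by c scales components by c^2, ratios unchanged."""
        c = small_cohort
        f1 = fit_greml(c.phenotype, c.X, [c.grm, c.brm])
        f2 = fit_greml(3.0 * c.phenotype, c.X, [c.grm, c.brm])
        for name in ("sigma2_g", "sigma2_b", "sigma2_e"):
            assert f2.varcomp_[name] == pytest.approx(9.0 * f1.varcomp_[name],
                                                      rel=1e-4, abs=1e-8)
        m1, h1 = f1.variance_proportions()
        m2, h2 = f2.variance_proportions()
        assert m2.value == pytest.approx(m1.value, abs=1e-6)
        assert h2.value == pytest.approx(h1.value, abs=1e-6)

    def test_no_spurious_suboptimum(self, small_cohort):
        """The maximized restricted likelihood is at least the value at the
        generating truth."""
        c = small_cohort
        fit = fit_greml(c.phenotype, c.X, [c.grm, c.brm])
        truth = [c.config.sigma2_g, c.config.sigma2_b, c.config.sigma2_e]
        at_truth = restricted_loglik(c.phenotype, c.X,
                                     [c.grm, c.brm, np.eye(c.grm.n_subjects)],
                                     truth)
        assert fit.loglik_ >= at_truth - 1e-6

    def test_proportions_sum_to_one(self, small_cohort):
        c = small_cohort
        fit = fit_greml(c.phenotype, c.X, [c.grm, c.brm])
        m2, h2 = fit.variance_proportions()
        resid = fit.varcomp_["sigma2_e"] / sum(fit.varcomp_.values())
        assert m2.value + h2.value + resid == pytest.approx(1.0, abs=1e-10)

    def test_model2_with_fixed_zero_covariance_reproduces_model1(self, small_cohort):
        c = small_cohort
        f1 = fit_greml(c.phenotype, c.X, [c.grm, c.brm])
        f2 = fit_greml(c.phenotype, c.X, [c.grm, c.brm, c.core],
                       fix_covariance_zero=True)
        for name in ("sigma2_g", "sigma2_b", "sigma2_e"):
            assert f2.varcomp_[name] == pytest.approx(f1.varcomp_[name], abs=1e-6)
        assert f2.varcomp_["sigma_bg"] == 0.0
        assert f2.loglik_ == pytest.approx(f1.loglik_, abs=1e-6)

    def test_iteration_cap_reports_nonconvergence(self, small_cohort):
        c = small_cohort
        fit = fit_greml(c.phenotype, c.X, [c.grm, c.brm], max_iter=1, tol=1e-14)
        assert fit.converged_ is False
        assert fit.n_iter_ == 1


class TestRatioEstimates:
    @staticmethod
    def _manual_fit(theta, names, acov=None, model=1):
        fit = GREML()
        fit.theta_ = np.asarray(theta, dtype=float)
        fit.param_names_ = names
        fit.is_covariance_ = np.array([n == "sigma_bg" for n in names])
        fit.free_ = np.ones(len(names), dtype=bool)
        fit.acov_ = np.eye(len(names)) * 0.01 if acov is None else acov
        fit.floor_ = 1e-9
        fit.converged_ = True
        fit.model_ = model
        return fit

    def test_equal_variance_arithmetic(self):
        fit = self._manual_fit([1.0, 1.0, 2.0],
                               ["sigma2_g", "sigma2_b", "sigma2_e"])
        m2, h2 = fit.variance_proportions()
        assert (m2.name, h2.name) == ("m2", "h2")
        assert m2.value == pytest.approx(0.25)
        assert h2.value == pytest.approx(0.25)

    def test_zero_morphological_variance_boundary(self):
        acov = np.diag([0.01, 0.04, 0.01])
        fit = self._manual_fit([1.0, 0.0, 3.0],
                               ["sigma2_g", "sigma2_b", "sigma2_e"], acov)
        m2, _ = fit.variance_proportions()
        assert m2.value == 0.0
        # at sigma2_b = 0 the gradient reduces to e_b / total
        assert m2.se == pytest.approx(np.sqrt(0.04) / 4.0)

    def test_model2_denominator_includes_twice_covariance(self):
        names = ["sigma2_g", "sigma2_b", "sigma_bg", "sigma2_e"]
        fit = self._manual_fit([0.3, 0.3, 0.1, 0.3], names, model=2)
        m2, h2 = fit.variance_proportions()
        assert m2.value == pytest.approx(0.3 / 1.1)
        fit.denominator_includes_covariance = False
        m2b, _ = fit.variance_proportions()
        assert m2b.value == pytest.approx(0.3 / 0.9)

    def test_effect_correlation_boundaries(self):
        names = ["sigma2_g", "sigma2_b", "sigma_bg", "sigma2_e"]
        fit = self._manual_fit([0.4, 0.9, 0.0, 0.5], names, model=2)
        assert fit.effect_correlation().value == 0.0
        fit = self._manual_fit([0.4, 0.9, 0.6, 0.5], names, model=2)
        assert fit.effect_correlation().value == pytest.approx(1.0)

    def test_delta_se_matches_parametric_draws(self, small_cohort):
        """Delta-method SE of m2 against the SD of the ratio over 1e5 draws
        from the fitted asymptotic covariance (interior fit)."""
        c = small_cohort
        fit = fit_greml(c.phenotype, c.X, [c.grm, c.brm])
        m2, _ = fit.variance_proportions()
        rng = np.random.default_rng(7)
        draws = rng.multivariate_normal(fit.theta_, fit.acov_, size=100_000)
        totals = draws.sum(axis=1)
        ratios = draws[:, 1] / totals
        ok = totals > 0
        assert abs(m2.se - ratios[ok].std()) / ratios[ok].std() < 0.10


class TestInference:
    def test_wald_reference_values(self):
        assert wald_p_value(2.0, 1.0) == pytest.approx(
            stats.chi2.sf(4.0, 1), abs=1e-12)
        assert wald_p_value(2.0, 1.0) == pytest.approx(0.0455, abs=1e-4)
        assert wald_p_value(0.0, 1.0) == 1.0
        with pytest.raises(ZeroDivisionError):
            wald_p_value(1.0, 0.0)

    def test_lrt_equal_likelihoods(self):
        stat, p = likelihood_ratio_test(-100.0, -100.0)
        assert stat == 0.0 and p == 1.0

    def test_lrt_ordering_violation(self):
        with pytest.raises(ConvergenceOrderingError):
            likelihood_ratio_test(-100.0, -101.0)

    def test_published_loglik_pairs_reproduce_adjusted_p(self):
        """The 19 published log-likelihood pairs: the age-at-pregnancy LRT is
        2 x (-3308.9 + 3311.9) = 6.0 and its BH-adjusted p across the 19
        traits is ~0.27 (printed as 0.267 from unrounded inputs)."""
        df = cohort_model_comparison()
        table = compare_models(df["loglik_model1"], df["loglik_model2"],
                               df["trait"])
        row = table[table["trait"] == "Age at pregnancy"].iloc[0]
        assert row["lrt_stat"] == pytest.approx(6.0, abs=1e-9)
        assert row["lrt_p_fdr"] == pytest.approx(0.267, abs=0.04)

    def test_bh_adjustment_hand_example(self):
        adjusted = fdr_adjust([0.005, 0.01, 0.03, 0.04])
        np.testing.assert_allclose(adjusted, [0.02, 0.02, 0.04, 0.04], atol=1e-12)

    def test_bh_single_and_tied_inputs(self):
        np.testing.assert_allclose(fdr_adjust([0.3]), [0.3])
        np.testing.assert_allclose(fdr_adjust([0.5, 0.5]), [0.5, 0.5])

    def test_bh_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])
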