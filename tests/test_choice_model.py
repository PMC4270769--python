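import warnings

import numpy as np
import pytest
from scipy import stats

from emochoice.choice_model import (ChoiceDesign, ConditionalLogit,
                                    ConvergenceError, SeparationError,
                                    fit_conditional_logit, fit_null,
                                    hausman_mcfadden, log_likelihood, lr_test,
                                    mcfadden_adj_r2, predict_probs)

from conftest import simulate_design


class TestLogLikelihood:
    def test_zero_parameters_give_uniform_likelihood(self):
        rng = np.random.default_rng(0)
        design = simulate_design(rng, n=13, J=7)
        ll, _, _ = log_likelihood(np.zeros(2 + 6), design)
        assert ll == pytest.approx(13 * np.log(1.0 / 7.0))

    def test_gradient_matches_central_finite_differences(self):
        rng = np.random.default_rng(1)
        design = simulate_design(rng, n=30, J=4)
        theta = rng.normal(scale=0.4, size=2 + 3)
        _, grad, _ = log_likelihood(theta, design)
        eps = 1e-6
        for k in range(len(theta)):
            step = np.zeros_like(theta)
            step[k] = eps
            lp, _, _ = log_likelihood(theta + step, design)
            lm, _, _ = log_likelihood(theta - step, design)
            assert grad[k] == pytest.approx((lp - lm) / (2 * eps), abs=1e-5)

    def test_hessian_matches_gradient_differences(self):
        rng = np.random.default_rng(2)
        design = simulate_design(rng, n=20, J=3, beta=(0.5,))
        theta = rng.normal(scale=0.3, size=1 + 2)
        _, _, H = log_likelihood(theta, design)
        eps = 1e-6
        for k in range(len(theta)):
            step = np.zeros_like(theta)
            step[k] = eps
            _, gp, _ = log_likelihood(theta + step, design)
            _, gm, _ = log_likelihood(theta - step, design)
            np.testing.assert_allclose(H[:, k], (gp - gm) / (2 * eps), atol=1e-4)

    def test_two_alternative_case_reduces_to_binary_logistic(self):
        """Closed-form oracle: conditional logit with J=2 equals a binary
        logistic regression on the covariate differences (statsmodels)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        design = simulate_design(rng, n=200, J=2, beta=(0.7, -0.4), asc=(0.0, 0.3))
        fit = fit_conditional_logit(design)
        diff = design.X[:, 1, :] - design.X[:, 0, :]
        y = (design.chosen == 1).astype(float)
        sm_fit = sm.Logit(y, sm.add_constant(diff, prepend=False)).fit(disp=0)
        np.testing.assert_allclose(fit.loglik_, sm_fit.llf, atol=1e-8)
        np.testing.assert_allclose(fit.beta_, sm_fit.params[:2], atol=1e-6)
        assert fit.asc_[1] == pytest.approx(sm_fit.params[2], abs=1e-6)


class TestFitConditionalLogit:
    def test_parameter_recovery_within_three_standard_errors(self):
        rng = np.random.default_rng(4)
        true_beta = np.array([0.8, -0.5])
        design = simulate_design(rng, n=600, J=7, beta=true_beta)
        fit = fit_conditional_logit(design)
        assert fit.converged_
        np.testing.assert_array_less(np.abs(fit.beta_ - true_beta),
                                     3.0 * fit.se_[:2])

    def test_null_covariate_zero_slope_and_log_share_ascs(self):
        rng = np.random.default_rng(5)
        design = simulate_design(rng, n=400, J=4, beta=(0.9,), asc=(0, 0.8, -0.4, 0.2))
        zeroed = ChoiceDesign(np.zeros_like(design.X), design.chosen,
                              design.alternatives, design.covariate_names)
        fit = fit_conditional_logit(zeroed)
        assert fit.beta_[0] == pytest.approx(0.0, abs=1e-8)
        shares = np.bincount(design.chosen, minlength=4) / design.n_choosers
        np.testing.assert_allclose(fit.asc_ - fit.asc_[0],
                                   np.log(shares) - np.log(shares[0]), atol=1e-6)

    def test_cold_and_random_starts_reach_same_optimum(self):
        rng = np.random.default_rng(6)
        design = simulate_design(rng, n=150, J=5)
        cold = fit_conditional_logit(design)
        warm = ConditionalLogit().fit(design, start=rng.normal(scale=2.0, size=2 + 4))
        assert warm.loglik_ == pytest.approx(cold.loglik_, abs=1e-8)
        np.testing.assert_allclose(warm.params_, cold.params_, atol=1e-6)

    def test_reference_relabeling_is_reparameterization(self):
        rng = np.random.default_rng(7)
        design = simulate_design(rng, n=200, J=4, asc=(0, 0.5, -0.3, 0.1))
        f0 = ConditionalLogit(reference=0).fit(design)
        f2 = ConditionalLogit(reference=2).fit(design)
        np.testing.assert_allclose(f0.beta_, f2.beta_, atol=1e-6)
        np.testing.assert_allclose(f0.asc_ - f0.asc_[2], f2.asc_ - f2.asc_[2],
                                   atol=1e-6)
        np.testing.assert_allclose(f0.predict_proba(design),
                                   f2.predict_proba(design), atol=1e-8)

    def test_perfect_separation_is_detected(self):
        # one covariate exactly indicates the chosen alternative
        n, J = 60, 3
        rng = np.random.default_rng(8)
        chosen = rng.integers(0, J, size=n)
        X = np.zeros((n, J, 1))
        X[np.arange(n), chosen, 0] = 1.0
        design = ChoiceDesign(X, chosen, ["A", "B", "C"], ["winner"])
        with pytest.raises((SeparationError, ConvergenceError)):
            fit_conditional_logit(design)

    def test_collinear_covariates_raise_informative_error(self):
        rng = np.random.default_rng(9)
        base = simulate_design(rng, n=100, J=4, beta=(0.5,))
        X = np.concatenate([base.X, 2.0 * base.X], axis=2)
        design = ChoiceDesign(X, base.chosen, base.alternatives, ["x", "x2"])
        with pytest.raises(ConvergenceError, match="collinear"):
            fit_conditional_logit(design)


class TestPredictProbs:
    def test_rows_sum_to_one_and_zero_fit_is_uniform(self):
        rng = np.random.default_rng(10)
        design = simulate_design(rng, n=50, J=7)
        fit = fit_conditional_logit(design)
        P = predict_probs(fit, design)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert ((P > 0) & (P < 1)).all()
        fit.params_ = np.zeros_like(fit.params_)
        np.testing.assert_allclose(fit.predict_proba(design), 1.0 / 7.0)

    def test_hand_computed_three_alternative_probabilities(self):
        X = np.array([[[1.0], [0.0], [2.0]]])
        design = ChoiceDesign(X, np.array([0]), ["A", "B", "C"], ["x"])
        fit = ConditionalLogit(include_asc=False).fit(
            simulate_design(np.random.default_rng(11), n=80, J=3, beta=(0.5,)))
        fit.params_ = np.array([0.3])
        expected = np.exp(0.3 * X[0, :, 0])
        expected /= expected.sum()
        np.testing.assert_allclose(fit.predict_proba(design)[0], expected,
                                   atol=1e-12)

    def test_raising_a_covariate_raises_that_probability(self):
        rng = np.random.default_rng(12)
        design = simulate_design(rng, n=300, J=4, beta=(0.8,))
        fit = fit_conditional_logit(design)
        assert fit.beta_[0] > 0
        bumped = ChoiceDesign(design.X.copy(), design.chosen,
                              design.alternatives, design.covariate_names)
        bumped.X[:, 2, 0] += 0.5
        assert (fit.predict_proba(bumped)[:, 2]
                > fit.predict_proba(design)[:, 2]).all()


class TestLrTest:
    def test_model_against_itself_is_zero(self):
        rng = np.random.default_rng(13)
        design = simulate_design(rng, n=80, J=4)
        fit = fit_conditional_logit(design)
        comp = lr_test(fit, fit)
        assert comp.chi2 == pytest.approx(0.0, abs=1e-10)
        assert comp.df == 0 and not comp.nested and comp.p is None

    def test_nested_addition_never_decreases_loglik(self):
        rng = np.random.default_rng(14)
        design = simulate_design(rng, n=120, J=5, beta=(0.6, 0.0))
        small = ChoiceDesign(design.X[:, :, :1], design.chosen,
                             design.alternatives, ["x0"])
        comp = lr_test(fit_conditional_logit(small), fit_conditional_logit(design))
        assert comp.chi2 >= -1e-10
        assert comp.df == 1 and comp.nested

    def test_null_distribution_is_chisquare(self):
        """Irrelevant added covariate: 2 dLL across replicates ~ chi2(1)."""
        rng = np.random.default_rng(15)
        chi2s = []
        for _ in range(250):
            design = simulate_design(rng, n=120, J=4, beta=(0.7, 0.0))
            small = ChoiceDesign(design.X[:, :, :1], design.chosen,
                                 design.alternatives, ["x0"])
            comp = lr_test(fit_conditional_logit(small),
                           fit_conditional_logit(design))
            chi2s.append(comp.chi2)
        ks = stats.kstest(chi2s, stats.chi2(1).cdf)
        assert ks.pvalue > 0.01

    def test_different_choosers_rejected(self):
        rng = np.random.default_rng(16)
        d1 = simulate_design(rng, n=40, J=3)
        d2 = simulate_design(rng, n=50, J=3)
        with pytest.raises(ValueError, match="same choosers"):
            lr_test(fit_conditional_logit(d1), fit_conditional_logit(d2))


class TestMcfaddenAdjR2:
    def test_null_self_comparison_is_penalty_only(self):
        rng = np.random.default_rng(17)
        design = simulate_design(rng, n=100, J=5)
        null = fit_null(design)
        # unadjusted pseudo-r2 of the null against itself is exactly 0;
        # the adjustment subtracts the parameter count
        assert 1.0 - null.loglik_ / null.loglik_ == pytest.approx(0.0)
        val = mcfadden_adj_r2(null, null)
        assert val == pytest.approx(null.n_params_ / null.loglik_)
        assert val < 0

    def test_better_fit_raises_r2_and_separable_design_approaches_bound(self):
        rng = np.random.default_rng(18)
        design = simulate_design(rng, n=300, J=4, beta=(3.5,))
        fit = fit_conditional_logit(design, param_bound=200.0)
        null = fit_null(design)
        strong = mcfadden_adj_r2(fit, null)
        # near-perfect prediction: r2 approaches the 1 - K/LL0 ceiling
        ceiling = 1.0 - fit.n_params_ / null.loglik_
        assert 0.3 < strong <= ceiling + 1e-12

    def test_slopes_penalty_convention(self):
        rng = np.random.default_rng(19)
        design = simulate_design(rng, n=200, J=4, beta=(0.8, -0.2))
        fit = fit_conditional_logit(design)
        null = fit_null(design)
        assert mcfadden_adj_r2(fit, null, penalty="slopes") > \
            mcfadden_adj_r2(fit, null, penalty="all")


class TestHausmanMcfadden:
    def test_statistic_nonnegative_with_correct_df(self):
        rng = np.random.default_rng(20)
        design = simulate_design(rng, n=300, J=7, beta=(0.8, -0.5))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = hausman_mcfadden(design, "D")
        assert res.chi2 >= 0.0
        assert res.df == 2 + 5  # slopes + remaining non-reference ASCs
        assert 0.0 <= res.p <= 1.0

    def test_rejection_rate_near_nominal_on_iia_true_data(self):
        """IIA holds by construction; the asymptotic size is 5%.  The test is
        known to over-reject in finite samples, so the band is one-sided and
        generous at n=1500."""
        rng = np.random.default_rng(21)
        rejections = 0
        reps = 120
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(reps):
                design = simulate_design(rng, n=1500, J=4, beta=(0.8,))
                rejections += hausman_mcfadden(design, "B").p < 0.05
        assert rejections / reps <= 0.15
        assert rejections / reps >= 0.0

    def test_degenerate_removals_rejected(self):
        n, J = 30, 3
        rng = np.random.default_rng(22)
        X = rng.normal(size=(n, J, 1))
        design = ChoiceDesign(X, np.zeros(n, dtype=int), ["A", "B", "C"], ["x"])
        with pytest.raises(ValueError, match="nothing left"):
            design.drop_alternative("A")
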