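"""Estimating-equation solver, links, and the three variance estimators."""

import numpy as np
import pytest

import ijpseudo as ij
from ijpseudo import (
    ModelSpec,
    PseudoRegression,
    asymptotic_variance,
    bootstrap_variance,
    fit_pseudo_glm,
    ij_pseudo,
    sandwich_variance,
    second_order_influence,
)

T = 1.0


class TestFit:
    def test_intercept_only_identity_is_mean(self, censored_sample):
        ps = ij_pseudo(censored_sample, T, 1)
        fit = fit_pseudo_glm(ps, np.empty((censored_sample.n, 0)))
        assert fit.beta[0] == pytest.approx(ps.values.mean(), abs=1e-12)
        assert fit.beta[0] == pytest.approx(ps.base_estimate, abs=1e-10)

    def test_binary_covariate_identity_is_group_difference(self, censored_sample):
        s = censored_sample
        z = s.covariates[:, 0]
        ps = ij_pseudo(s, T, 1)
        fit = fit_pseudo_glm(ps, s.covariates)
        diff = ps.values[z == 1].mean() - ps.values[z == 0].mean()
        assert fit.beta[1] == pytest.approx(diff, abs=1e-12)

    @pytest.mark.parametrize("link", ["identity", "log", "logit", "cloglog"])
    def test_ee_residual_norm_small(self, censored_sample, link):
        ps = ij_pseudo(censored_sample, T, 1)
        fit = fit_pseudo_glm(ps, censored_sample.covariates, ModelSpec(link))
        assert fit.converged
        assert fit.ee_norm < 1e-8

    def test_identity_closed_form_equals_iteration(self, censored_sample):
        """Weighted-least-squares closed form vs generic scoring loop."""
        from ijpseudo.regression import LINKS, _design, _ee

        ps = ij_pseudo(censored_sample, T, 1)
        fit = fit_pseudo_glm(ps, censored_sample.covariates)
        X = _design(censored_sample.covariates, True)
        beta = np.array([0.1, 0.0])
        link = LINKS["identity"]
        w = np.ones(censored_sample.n)
        for _ in range(50):
            U, J, _ = _ee(beta, X, ps.values, w, link)
            beta = beta + np.linalg.solve(-J, U)
        assert np.max(np.abs(beta - fit.beta)) < 1e-10

    def test_matches_statsmodels_quasiscore(self, censored_sample):
        """The EE with quasi-score A is the Gaussian-family GLM score."""
        import statsmodels.api as sm

        ps = ij_pseudo(censored_sample, T, 1)
        X = sm.add_constant(censored_sample.covariates)
        for link, smlink in [("identity", sm.families.links.Identity()),
                             ("logit", sm.families.links.Logit()),
                             ("cloglog", sm.families.links.CLogLog())]:
            fit = fit_pseudo_glm(ps, censored_sample.covariates, ModelSpec(link))
            glm = sm.GLM(ps.values, X,
                         family=sm.families.Gaussian(link=smlink,
                                                     check_link=False)).fit()
            assert np.allclose(fit.beta, glm.params, atol=1e-6)

    def test_rank_deficient_design_rejected(self, censored_sample):
        Z = np.column_stack([censored_sample.covariates,
                             censored_sample.covariates])
        ps = ij_pseudo(censored_sample, T, 1)
        with pytest.raises(np.linalg.LinAlgError):
            fit_pseudo_glm(ps, Z)


class TestSandwich:
    def test_matches_textbook_ols_sandwich(self):
        """Homoskedastic uncorrelated responses, identity link = OLS HC0."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n = 200
        z = rng.random(n)
        y = 0.3 + 0.5 * z + rng.normal(0, 0.2, n)
        fit = fit_pseudo_glm(y, z[:, None])
        vc = sandwich_variance(fit, y, z[:, None])
        ols = sm.OLS(y, sm.add_constant(z)).fit(cov_type="HC0")
        assert np.allclose(vc, ols.cov_params(), atol=1e-10)

    def test_scale_equivariance(self, censored_sample):
        ps = ij_pseudo(censored_sample, T, 1)
        fit = fit_pseudo_glm(ps, censored_sample.covariates)
        v1 = sandwich_variance(fit, ps.values, censored_sample.covariates)
        c = 3.7
        fit2 = fit_pseudo_glm(c * ps.values, censored_sample.covariates)
        v2 = sandwich_variance(fit2, c * ps.values, censored_sample.covariates)
        assert np.allclose(v2, c * c * v1, rtol=1e-10)


class TestSecondOrderInfluence:
    def test_symmetry(self, censored_sample):
        a = second_order_influence(censored_sample, T, 1, 3, 10)
        b = second_order_influence(censored_sample, T, 1, 10, 3)
        assert a == pytest.approx(b, abs=1e-10)

    def test_zero_without_censoring(self):
        s = ij.simulate_cohort(ij.ScenarioConfig(p_oc=0.0, n=60), seed=2)
        v = second_order_influence(s, T, 1, 3, 10)
        assert abs(v) < 1e-6

    def test_empirical_mean_zero(self):
        s = ij.simulate_cohort(ij.ScenarioConfig(p_oc=0.3, n=60), seed=3)
        mz = np.mean([second_order_influence(s, T, 1, k, 5)
                      for k in range(s.n)])
        assert abs(mz) < 1e-6


class TestAsymptoticVariance:
    def test_equals_sandwich_without_censoring(self):
        s = ij.simulate_cohort(ij.ScenarioConfig(p_oc=0.0, n=80), seed=2)
        ps = ij_pseudo(s, T, 1)
        fit = fit_pseudo_glm(ps, s.covariates)
        hw = sandwich_variance(fit, ps, s.covariates)
        sg = asymptotic_variance(fit, s, ps, s.covariates)
        assert np.allclose(hw, sg, rtol=1e-6)

    def test_h1_shrinks_variance_under_heavy_censoring(self):
        """SE_Sigma < SE_HW for the exposure effect when the risk
        difference is large and censoring heavy (the documented
        conservative direction of the sandwich)."""
        s = ij.simulate_cohort(
            ij.ScenarioConfig(p_oc=0.5, beta1=0.55, n=400), seed=9)
        ps = ij_pseudo(s, T, 1)
        fit = fit_pseudo_glm(ps, s.covariates)
        hw = sandwich_variance(fit, ps, s.covariates)
        sg = asymptotic_variance(fit, s, ps, s.covariates)
        assert sg[1, 1] < hw[1, 1]


class TestBootstrap:
    def test_fixed_seed_is_bit_identical(self, censored_sample):
        v1 = bootstrap_variance(censored_sample, T, 1, B=40, seed=5)
        v2 = bootstrap_variance(censored_sample, T, 1, B=40, seed=5)
        assert np.array_equal(v1, v2)

    def test_degenerate_sample_zero_variance(self):
        s = ij.make_sample([2.0] * 30, [1] * 30,
                           covariates=np.ones((30, 1)) * 0.5)
        v = bootstrap_variance(s, T, 1, ModelSpec(intercept=False),
                               B=20, seed=1)
        assert np.allclose(v, 0.0, atol=1e-20)

    def test_agrees_with_sandwich_scale(self, censored_sample):
        v = bootstrap_variance(censored_sample, T, 1, B=150, seed=2)
        ps = ij_pseudo(censored_sample, T, 1)
        fit = fit_pseudo_glm(ps, censored_sample.covariates)
        hw = sandwich_variance(fit, ps, censored_sample.covariates)
        assert np.sqrt(v[1, 1]) == pytest.approx(np.sqrt(hw[1, 1]), rel=0.35)

    def test_b_below_two_rejected(self, censored_sample):
        with pytest.raises(ValueError):
            bootstrap_variance(censored_sample, T, 1, B=1)


class TestPseudoRegressionEstimator:
    def test_sklearn_contract(self, censored_sample):
        df = ij.sample_to_frame(censored_sample)
        reg = PseudoRegression(t=T, cause=1, link="identity", method="ij")
        reg.fit(df)
        assert reg.converged_
        assert reg.coef_.shape == (2,)
        assert reg.vcov_hw_.shape == (2, 2)
        p = reg.get_params()
        assert p["link"] == "identity"
        mu = reg.predict(np.array([[0.0], [1.0]]))
        assert mu[1] - mu[0] == pytest.approx(reg.coef_[1], abs=1e-12)
        tab = reg.summary()
        assert list(tab["term"]) == ["(Intercept)", "z1"]

    def test_truncated_input_switches_to_weighted_path(self, truncated_sample):
        reg = PseudoRegression(t=T, cause=1, method="ij").fit(truncated_sample)
        assert reg.pseudo_set_.method == "ij_truncated"
        assert np.any(reg.sample_weights_ > 1.0)

    def test_gridsearch_compatible(self, censored_sample):
        from sklearn.base import clone

        reg = PseudoRegression(t=T, link="logit")
        reg2 = clone(reg)
        assert reg2.get_params() == reg.get_params()
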