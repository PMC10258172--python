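"""Jackknife, IJ, truncated-IJ pseudo-observations and sampling weights."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ijpseudo as ij
from ijpseudo import (
    ij_pseudo,
    ij_pseudo_survival,
    ij_pseudo_truncated,
    ij_weight_derivative,
    ipcw_pseudo,
    jackknife_pseudo,
    make_sample,
    sampling_weights,
)
from ijpseudo.curves import _curve_arrays
from ijpseudo.pseudo import PseudoObservations, aalen_johansen_weighted

from conftest import random_tied_sample

T = 1.0


@pytest.fixture(scope="module")
def uncensored():
    return ij.simulate_cohort(ij.ScenarioConfig(p_oc=0.0, n=150), seed=3)


class TestNoCensoringCollapse:
    """Without censoring every method returns the indicator 1(T<=t, D=j)."""

    @pytest.mark.parametrize("method", ["ij", "jackknife", "ipcw",
                                        "weight_derivative"])
    def test_indicator(self, uncensored, method):
        s = uncensored
        ind = ((s.time <= T) & (s.status == 1)).astype(float)
        if method == "ij":
            vals = ij_pseudo(s, T, 1).values
        elif method == "jackknife":
            vals = jackknife_pseudo(s, T, 1).values
        elif method == "ipcw":
            vals = ipcw_pseudo(s, T, 1).values
        else:
            vals = ij_weight_derivative(s, T, 1).values
        assert np.max(np.abs(vals - ind)) < 1e-12

    def test_survival_indicator(self, uncensored):
        s = uncensored
        vals = ij_pseudo_survival(s, T).values
        assert np.max(np.abs(vals - (s.time > T))) < 1e-12


class TestIJ:
    def test_mean_identity(self, censored_sample):
        ps = ij_pseudo(censored_sample, T, 1)
        assert abs(ps.values.mean() - ps.base_estimate) < 1e-10
        assert ps.base_estimate == pytest.approx(
            ij.aalen_johansen(censored_sample, T, 1), abs=1e-12)

    def test_martingale_residuals_sum_to_zero(self, censored_sample):
        """sum_i M^_{0i}(s) = 0 at every s, by construction of Lambda^_0."""
        s = censored_sample
        u, G, G_left, F, S, dL0, _, _ = _curve_arrays(s, False)
        # sum_i dN_{0i}(u_k) = n * dH^_0, sum_i Y_{c,i}(u_k) = n * H^_c(u_k)
        cs = ij.empirical_summary(s)
        dH0 = np.diff(np.concatenate([[0.0], np.atleast_1d(cs.counts[0](u))]))
        Hc = np.atleast_1d(cs.at_risk_cens(u))
        dM_total = dH0 - Hc * dL0
        assert np.max(np.abs(np.cumsum(dM_total))) < 1e-12

    def test_survival_complement_single_cause(self):
        rng = np.random.default_rng(5)
        time = rng.uniform(0.1, 2.0, 120)
        status = rng.integers(0, 2, 120)
        s = make_sample(time, status, d=1)
        sv = ij_pseudo_survival(s, T).values
        cif = ij_pseudo(s, T, 1).values
        assert np.allclose(sv, 1.0 - cif, atol=1e-12)
        assert ij_pseudo_survival(s, T).base_estimate == pytest.approx(
            float(ij.fit_curves(s).S(T)), abs=1e-12)

    @settings(max_examples=15, deadline=None)
    @given(st.integers(0, 10_000))
    def test_mean_identity_property(self, seed):
        rng = np.random.default_rng(seed)
        s = random_tied_sample(rng, n=int(rng.integers(4, 60)))
        ps = ij_pseudo(s, T, 1)
        assert abs(ps.values.mean() - ps.base_estimate) < 1e-10

    def test_jk_ij_gap_shrinks_with_n(self):
        """sqrt(n) * max_i |jk - ij| stays bounded as n grows (asymptotic
        equivalence of the two pseudo-observation flavours)."""
        gaps = {}
        for n in (100, 1600):
            g = []
            for seed in range(8):
                s = ij.simulate_cohort(ij.ScenarioConfig(p_oc=0.3, n=n),
                                       seed=1000 + seed)
                jk = jackknife_pseudo(s, T, 1).values
                ji = ij_pseudo(s, T, 1).values
                g.append(np.sqrt(n) * np.max(np.abs(jk - ji)))
            gaps[n] = np.median(g)
        assert gaps[1600] < 4 * gaps[100]
        # and the raw gap itself shrinks
        assert gaps[1600] / np.sqrt(1600) < gaps[100] / np.sqrt(100)


class TestJackknife:
    @settings(max_examples=10, deadline=None)
    @given(st.integers(0, 10_000))
    def test_efficient_equals_naive_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        s = random_tied_sample(rng, n=50)
        eff = jackknife_pseudo(s, T, 1, "efficient").values
        nai = jackknife_pseudo(s, T, 1, "naive").values
        assert np.max(np.abs(eff - nai)) < 1e-12

    def test_efficient_equals_naive_truncated(self, truncated_sample):
        eff = jackknife_pseudo(truncated_sample, T, 1, "efficient").values
        nai = jackknife_pseudo(truncated_sample, T, 1, "naive").values
        assert np.max(np.abs(eff - nai)) < 1e-12

    def test_n_below_two_rejected(self):
        s = make_sample([1.0], [1])
        with pytest.raises(ValueError):
            jackknife_pseudo(s, T, 1)

    def test_sole_at_risk_subject_fallback(self):
        # late entrant alone at risk at its own event time exercises the
        # degenerate-window branch
        s = make_sample(time=[0.3, 0.35, 0.9], status=[1, 0, 1],
                        entry=[0.0, 0.0, 0.8])
        eff = jackknife_pseudo(s, T, 1, "efficient").values
        nai = jackknife_pseudo(s, T, 1, "naive").values
        assert np.allclose(eff, nai, atol=1e-12)


class TestTruncatedIJ:
    def test_zero_entries_reduce_to_plain(self, censored_sample):
        a = ij_pseudo_truncated(censored_sample, T, 1)
        b = ij_pseudo(censored_sample, T, 1)
        assert np.array_equal(a.values, b.values)
        assert np.all(a.weights == 1.0)

    def test_weights_all_one_without_truncation(self, censored_sample):
        assert np.all(sampling_weights(censored_sample) == 1.0)

    def test_weight_reciprocal_hand_value(self):
        # F^_L steps 0.5 at 0 then 1 at tau: early follow-up gets weight 2
        s = make_sample([0.3, 2.0, 2.5, 3.0], [1, 1, 1, 1],
                        entry=[0.0, 1.0, 0.0, 1.0])
        w = sampling_weights(s)
        tc = ij.truncation_cdf(s)
        assert w[0] == pytest.approx(1.0 / tc.FL(0.3))
        assert w[1] == pytest.approx(1.0)  # follow-up beyond tau

    def test_weighted_mean_zero_at_truth(self):
        """E{w (pseudo - mu)} ~ 0 at the true beta over replications."""
        cfg = ij.ScenarioConfig(p_oc=0.2, n=800, truncation=True)
        resid = []
        for seed in range(30):
            s = ij.simulate_truncated_cohort(cfg, seed=seed)
            ps = ij_pseudo_truncated(s, T, 1)
            mu = cfg.beta0 + cfg.beta1 * s.covariates[:, 0]
            resid.append(np.average(ps.values - mu, weights=ps.weights))
        m = np.mean(resid)
        se = np.std(resid, ddof=1) / np.sqrt(len(resid))
        assert abs(m) < 4 * se + 0.003

    def test_unmodified_pseudo_bias_direction(self):
        """Without the modification E(pseudo | Z) is distorted by the
        P(T~>=L)/P(T~>=L|Z) factor: beta1 overestimated at p_Z=0.2 and
        underestimated at p_Z=0.8 (jackknife on truncated risk sets)."""
        est = {0.2: [], 0.8: []}
        for p_Z in est:
            cfg = ij.ScenarioConfig(p_Z=p_Z, beta0=0.10, beta1=0.40,
                                    p_oc=0.20, n=4000, truncation=True)
            for seed in range(10):
                s = ij.simulate_truncated_cohort(cfg, seed=100 + seed)
                ps = jackknife_pseudo(s, T, 1)
                fit = ij.fit_pseudo_glm(ps, s.covariates)
                est[p_Z].append(fit.beta[1])
        assert np.mean(est[0.2]) > 0.40 + 0.01
        assert np.mean(est[0.8]) < 0.40 - 0.01


class TestWeightDerivative:
    def test_matches_influence_plugin_to_machine_precision(self, scenario1_sample):
        a = ij_pseudo(scenario1_sample, T, 1).values
        b = ij_weight_derivative(scenario1_sample, T, 1).values
        assert np.max(np.abs(a - b)) < 1e-14

    def test_truncated_sample_rejected(self, truncated_sample):
        with pytest.raises(ValueError):
            ij_weight_derivative(truncated_sample, T, 1)

    def test_finite_difference_oracle(self):
        """Central finite differences in each subject's own weight."""
        rng = np.random.default_rng(12)
        s = random_tied_sample(rng, n=50)
        ps = ij_weight_derivative(s, T, 1)
        n = s.n
        h = 1e-6
        base = np.full(n, 1.0 / n)
        for i in [0, 7, 23, 49]:
            wp, wm = base.copy(), base.copy()
            wp[i] += h
            wm[i] -= h
            fd = (aalen_johansen_weighted(s, T, 1, wp)
                  - aalen_johansen_weighted(s, T, 1, wm)) / (2 * h)
            assert ps.values[i] - ps.base_estimate == pytest.approx(fd, abs=5e-6)


class TestIpcw:
    def test_mean_is_aalen_johansen(self, censored_sample):
        ps = ipcw_pseudo(censored_sample, T, 1)
        assert ps.values.mean() == pytest.approx(
            ij.aalen_johansen(censored_sample, T, 1), abs=1e-12)


class TestTransformer:
    def test_fit_transform_and_params(self, censored_sample):
        po = PseudoObservations(t=T, cause=1, method="ij")
        vals = po.fit_transform(censored_sample)
        assert vals.shape == (censored_sample.n, 1)
        assert po.get_params()["method"] == "ij"
        po.set_params(method="jackknife")
        assert po.get_params()["method"] == "jackknife"

    def test_dataframe_input(self, censored_sample):
        df = ij.sample_to_frame(censored_sample)
        po = PseudoObservations(t=T, cause=1, method="ij").fit(df)
        ref = ij_pseudo(censored_sample, T, 1).values
        assert np.allclose(po.pseudo_values_, ref)
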