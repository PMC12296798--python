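import numpy as np
import pytest
from dataclasses import replace

import survweight as sw

from _reference import naive_nelson_aalen


class TestDGPSpec:
    def test_negative_additive_hazard_rejected(self):
        with pytest.raises(ValueError):
            sw.DGPSpec("ah", [-2.0], baseline=("constant", 1.0),
                       covariate_law=[("bernoulli", 0.5)])

    def test_weibull_additive_requires_nonnegative_effect(self):
        with pytest.raises(ValueError):
            sw.DGPSpec("ah", [-0.1], baseline=("weibull", 2.0, 1.0),
                       covariate_law=[("bernoulli", 0.5)])

    def test_coef_and_law_lengths_must_match(self):
        with pytest.raises(ValueError):
            sw.DGPSpec("ph", [0.5, 0.3], covariate_law=[("bernoulli", 0.5)])


class TestSimulate:
    def test_null_ph_times_are_exponential(self):
        spec = sw.DGPSpec("ph", [0.0], baseline=("constant", 1.0),
                          censoring=None, n=10000, seed=1)
        d = sw.simulate(spec)
        se = 1.0 / np.sqrt(d.n)
        assert abs(d.times.mean() - 1.0) < 3 * se
        assert d.n_events == d.n

    def test_additive_group_hazard_via_nelson_aalen(self):
        """z=1 subjects have hazard lambda0 + alpha = 1.5."""
        spec = sw.DGPSpec("ah", [0.5], baseline=("constant", 1.0),
                          censoring=None, n=20000, seed=2)
        d = sw.simulate(spec)
        g1 = d.covariates[:, 0] == 1
        et, na = naive_nelson_aalen(d.times[g1], d.events[g1])
        keep = et <= 1.0                     # estimate the slope on [0, 1]
        slope = np.polyfit(et[keep], na[keep], 1)[0]
        assert abs(slope - 1.5) < 0.08

    def test_seeded_determinism(self):
        spec = sw.DGPSpec("ph", [0.7], n=200, seed=5)
        d1, d2 = sw.simulate(spec), sw.simulate(spec)
        np.testing.assert_array_equal(d1.times, d2.times)
        np.testing.assert_array_equal(d1.covariates, d2.covariates)

    def test_weibull_baseline_inverse_transform(self):
        """Null-model Weibull times have the specified distribution."""
        spec = sw.DGPSpec("ph", [0.0], baseline=("weibull", 2.0, 3.0),
                          censoring=None, n=20000, seed=8)
        d = sw.simulate(spec)
        # E[T] = scale * Gamma(1 + 1/shape)
        from scipy.special import gamma
        expect = 3.0 * gamma(1.5)
        assert abs(d.times.mean() - expect) < 0.05

    def test_weibull_additive_bisection_inversion(self):
        spec = sw.DGPSpec("ah", [0.5], baseline=("weibull", 2.0, 1.0),
                          covariate_law=[("bernoulli", 0.5)],
                          censoring=None, n=5000, seed=9)
        d = sw.simulate(spec)
        # check Lambda(T|Z) is Exp(1): mean 1
        H = spec.conditional_cumhaz(d.times, d.covariates)
        assert abs(H.mean() - 1.0) < 3.0 / np.sqrt(d.n)

    def test_km_tracks_true_survival_at_null(self):
        spec = sw.DGPSpec("ph", [0.0], baseline=("constant", 1.0),
                          censoring=("uniform", 3.0), n=10000, seed=3)
        d = sw.simulate(spec)
        et, na = naive_nelson_aalen(d.times, d.events)
        keep = et <= 2.0
        np.testing.assert_allclose(np.exp(-na[keep]), np.exp(-et[keep]),
                                   atol=0.03)


class TestCensoringCalibration:
    @pytest.mark.parametrize("target", [0.2, 0.5])
    def test_realized_fraction_close_to_target(self, target):
        spec = sw.DGPSpec("ph", [0.7], censoring=None, n=10000, seed=4)
        cal = sw.calibrate_censoring(spec, target)
        d = sw.simulate(cal)
        realized = 1.0 - d.n_events / d.n
        assert abs(realized - target) < 0.02

    def test_out_of_range_target_rejected(self):
        spec = sw.DGPSpec("ph", [0.7], n=100, seed=0)
        with pytest.raises(ValueError):
            sw.calibrate_censoring(spec, 0.99)


class TestExternalPredictions:
    def test_oracle_true_null_model_gives_constant_weights(self):
        spec = sw.DGPSpec("ph", [0.0], baseline=("constant", 1.0),
                          censoring=("uniform", 4.0), n=300, seed=6)
        d = sw.simulate(spec)
        pr = sw.external_predictions(
            d, sw.ExternalModelSpec("oracle_true", horizon=1.0), spec)
        np.testing.assert_allclose(pr.surv_prob, np.exp(-1.0), atol=1e-12)
        w = pr.as_weights("survival_prob")
        f_w = sw.cox_fit(d, w.values, compute_sandwich=False)
        f_u = sw.cox_fit(d, compute_sandwich=False)
        np.testing.assert_allclose(f_w.beta_hat, f_u.beta_hat, atol=1e-9)

    def test_prediction_scales_are_consistent(self):
        spec = sw.DGPSpec("ph", [0.7, -0.4], covariate_law=[
            ("bernoulli", 0.5), ("truncnorm", 0.0, 1.0, -2.0, 2.0)],
            censoring=("uniform", 4.0), n=300, seed=7)
        d = sw.simulate(spec)
        for builder in ("oracle_true", "ph_fit", "ah_fit"):
            ext = sw.ExternalModelSpec(builder, covariate_subset=[0, 1],
                                       external_n=800, horizon=1.0)
            pr = sw.external_predictions(d, ext, spec)
            np.testing.assert_allclose(pr.surv_prob, np.exp(-pr.cum_hazard),
                                       atol=1e-12)
            assert np.all(pr.cum_hazard >= 0)

    def test_omitting_a_covariate_decorrelates_predictions(self):
        """An external model without z2 cannot track z2."""
        spec = sw.DGPSpec("ph", [0.3, 1.2], covariate_law=[
            ("bernoulli", 0.5), ("truncnorm", 0.0, 1.0, -2.0, 2.0)],
            censoring=("uniform", 4.0), n=2000, seed=10)
        d = sw.simulate(spec)
        full = sw.external_predictions(
            d, sw.ExternalModelSpec("ph_fit", covariate_subset=[0, 1],
                                    external_n=4000, horizon=1.0), spec)
        reduced = sw.external_predictions(
            d, sw.ExternalModelSpec("ph_fit", covariate_subset=[0],
                                    external_n=4000, horizon=1.0), spec)
        z2 = d.covariates[:, 1]
        r_full = abs(np.corrcoef(full.surv_prob, z2)[0, 1])
        r_red = abs(np.corrcoef(reduced.surv_prob, z2)[0, 1])
        assert r_full > 0.8 and r_red < 0.1

    def test_user_table_passthrough(self):
        spec = sw.DGPSpec("ph", [0.7], n=50, seed=12)
        d = sw.simulate(spec)
        H = np.linspace(0.1, 2.0, 50)
        pr = sw.external_predictions(
            d, sw.ExternalModelSpec("user_table", table=H, horizon=5.0), spec)
        np.testing.assert_array_equal(pr.cum_hazard, H)


class TestLeastFalseOracle:
    def test_correct_specification_recovers_truth(self):
        dgp = sw.DGPSpec("ph", [0.7], censoring=("uniform", 4.0), n=1, seed=0)
        orc = sw.least_false_oracle(dgp, "survival_prob", "cox",
                                    n_oracle=50000, seed=1, horizon=1.0)
        assert abs(orc.estimate[0] - 0.7) < max(3 * orc.mc_se[0], 0.02)

    def test_unit_weights_reproduce_the_mle_target(self):
        dgp = sw.DGPSpec("ph", [0.5], censoring=("uniform", 4.0), n=1, seed=0)
        orc = sw.least_false_oracle(dgp, "unit", "cox", n_oracle=50000, seed=2)
        assert abs(orc.estimate[0] - 0.5) < max(3 * orc.mc_se[0], 0.02)

    def test_misspecified_additive_target_is_stable(self):
        """Two oracle seeds agree on alpha* for a PH truth fit as AH."""
        dgp = sw.DGPSpec("ph", [0.7], censoring=("uniform", 4.0), n=1, seed=0)
        o1 = sw.least_false_oracle(dgp, "unit", "additive",
                                   n_oracle=50000, seed=3)
        o2 = sw.least_false_oracle(dgp, "unit", "additive",
                                   n_oracle=50000, seed=4)
        comb = np.hypot(o1.mc_se[0], o2.mc_se[0])
        assert abs(o1.estimate[0] - o2.estimate[0]) < 3 * comb
        # an n=4000 fit lands near the oracle target
        d = sw.simulate(replace(dgp, n=4000), seed=99)
        fit = sw.linying_fit(d)
        se = np.sqrt(fit.sandwich_cov[0, 0])
        z = (fit.alpha_hat[0] - o1.estimate[0]) / np.hypot(se, o1.mc_se[0])
        assert abs(z) < 3
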