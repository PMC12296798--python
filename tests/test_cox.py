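import numpy as np
import pytest

import survweight as sw
from survweight.cox import _score_residuals
from survweight.exceptions import NonConvergence, SingularInformation

from _reference import (grid_search_cox, naive_cox_loglik, naive_cox_score,
                        naive_nelson_aalen, random_small_instance)


class TestScore:
    def test_hand_evaluated_two_subject_score(self):
        # events at t=1 (z=1, risk-set mean 0.5) and t=2 (z=0, mean 0)
        d = sw.SurvivalDataset([1.0, 2.0], [1, 1], [[1.0], [0.0]])
        s = sw.cox_score([0.0], d, ties="breslow")
        np.testing.assert_allclose(s, [0.5], atol=1e-12)

    def test_identical_covariates_give_zero_score(self):
        d = sw.SurvivalDataset([1, 2, 3], [1, 1, 0], np.ones((3, 1)))
        for beta in (-1.0, 0.0, 2.0):
            np.testing.assert_allclose(sw.cox_score([beta], d), [0.0], atol=1e-12)

    def test_score_is_homogeneous_in_weights(self):
        d = sw.SurvivalDataset([1.0, 2.0], [1, 1], [[1.0], [0.0]])
        s1 = sw.cox_score([0.0], d, sw.user_weights([1.0, 1.0]), ties="breslow")
        s2 = sw.cox_score([0.0], d, sw.user_weights([2.0, 2.0]), ties="breslow")
        np.testing.assert_allclose(s2, 2.0 * s1, atol=1e-12)

    def test_score_matches_naive_loops_on_random_instances(self, rng):
        for _ in range(15):
            t, e, z, w = random_small_instance(rng)
            d = sw.SurvivalDataset(t, e, z)
            for beta in (-0.7, 0.0, 1.3):
                ours = sw.cox_score([beta], d, sw.user_weights(w), ties="breslow")
                ref = naive_cox_score(beta, t, e, z, w)
                np.testing.assert_allclose(ours, ref, atol=1e-10)


class TestFit:
    def test_beta_matches_grid_search_oracle(self, tiny_dataset):
        d = tiny_dataset
        fit = sw.cox_fit(d, ties="breslow")
        ref = grid_search_cox(d.times, d.events, d.covariates, np.ones(d.n))
        assert abs(fit.beta_hat[0] - ref) <= 1e-4

    def test_integer_weights_equal_row_duplication(self):
        t = np.array([1.0, 2.0, 3.5, 4.0, 6.0])
        e = np.array([1, 1, 0, 1, 1])
        z = np.array([[0.5], [-1.0], [0.3], [1.2], [0.0]])
        k = np.array([1, 3, 2, 1, 2])
        d_w = sw.SurvivalDataset(t, e, z)
        f_w = sw.cox_fit(d_w, k.astype(float), ties="breslow", compute_sandwich=False)
        rep = np.repeat(np.arange(5), k)
        d_r = sw.SurvivalDataset(t[rep], e[rep], z[rep])
        f_r = sw.cox_fit(d_r, ties="breslow", compute_sandwich=False)
        np.testing.assert_allclose(f_w.beta_hat, f_r.beta_hat, atol=1e-8)

    def test_matches_lifelines_weighted_fit(self, ph_cohort, rng):
        """Independent cross-check against lifelines' weighted Cox (Efron)."""
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd
        w = rng.exponential(1.0, ph_cohort.n) + 0.1
        df = pd.DataFrame({"t": ph_cohort.times, "e": ph_cohort.events,
                           "z": ph_cohort.covariates[:, 0], "w": w})
        cph = lifelines.CoxPHFitter().fit(df, "t", "e", weights_col="w", robust=True)
        fit = sw.cox_fit(ph_cohort, w, ties="efron")
        np.testing.assert_allclose(fit.beta_hat, cph.params_.values, atol=1e-6)
        np.testing.assert_allclose(np.sqrt(np.diag(fit.sandwich_cov)),
                                   cph.standard_errors_.values, rtol=1e-5)

    def test_efron_handles_heavily_tied_data(self, rng):
        """Efron and Breslow agree without ties and differ with them."""
        t = rng.integers(1, 5, 60).astype(float)
        e = rng.integers(0, 2, 60)
        e[:5] = 1
        z = rng.normal(0, 1, (60, 1))
        d = sw.SurvivalDataset(t, e, z)
        fe = sw.cox_fit(d, ties="efron", compute_sandwich=False)
        fb = sw.cox_fit(d, ties="breslow", compute_sandwich=False)
        assert abs(fe.beta_hat[0] - fb.beta_hat[0]) > 1e-6
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd
        df = pd.DataFrame({"t": t, "e": e, "z": z[:, 0]})
        cph = lifelines.CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(fe.beta_hat, cph.params_.values, atol=1e-6)

    def test_loglik_is_the_maximum(self, ph_cohort):
        fit = sw.cox_fit(ph_cohort, ties="breslow", compute_sandwich=False)
        d = ph_cohort
        for db in (-0.05, 0.05):
            ll = naive_cox_loglik(fit.beta_hat + db, d.times, d.events,
                                  d.covariates, np.ones(d.n))
            assert ll < fit.loglik

    def test_separation_raises_nonconvergence(self):
        # perfect separation: the single event has the largest covariate,
        # so the partial likelihood is monotone and beta diverges
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 0, 0, 0])
        z = np.array([[0.1], [0.0], [0.0], [0.0]])
        with pytest.raises(NonConvergence):
            sw.cox_fit(sw.SurvivalDataset(t, e, z), compute_sandwich=False)

    def test_collinear_covariates_raise_singular(self, ph_cohort):
        Z = np.hstack([ph_cohort.covariates, 2.0 * ph_cohort.covariates])
        d = sw.SurvivalDataset(ph_cohort.times, ph_cohort.events, Z)
        with pytest.raises((SingularInformation, NonConvergence)):
            sw.cox_fit(d, compute_sandwich=False)

    def test_multivariate_fit_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd
        spec = sw.DGPSpec("ph", [0.5, -0.3], covariate_law=[
            ("bernoulli", 0.4), ("truncnorm", 0.0, 1.0, -2.5, 2.5)],
            censoring=("uniform", 3.0), n=500, seed=9)
        d = sw.simulate(spec)
        w = rng.uniform(0.2, 2.0, d.n)
        df = pd.DataFrame({"t": d.times, "e": d.events, "z1": d.covariates[:, 0],
                           "z2": d.covariates[:, 1], "w": w})
        cph = lifelines.CoxPHFitter().fit(df, "t", "e", weights_col="w", robust=True)
        fit = sw.cox_fit(d, w, ties="efron")
        np.testing.assert_allclose(fit.beta_hat, cph.params_.values, atol=1e-6)
        np.testing.assert_allclose(np.sqrt(np.diag(fit.sandwich_cov)),
                                   cph.standard_errors_.values, rtol=1e-5)


class TestBaseline:
    def test_reduces_to_nelson_aalen_at_zero_beta(self, ph_cohort):
        d = sw.SurvivalDataset(ph_cohort.times, ph_cohort.events,
                               np.zeros((ph_cohort.n, 1)))
        fit = sw.cox_fit(sw.SurvivalDataset(
            ph_cohort.times, ph_cohort.events, ph_cohort.covariates),
            compute_sandwich=False)
        # evaluate at beta forced to 0 via a null covariate
        from survweight.cox import CoxFit
        null_fit = CoxFit(np.zeros(1), 0.0, np.eye(1), np.eye(1), np.eye(1),
                          np.eye(1), True, 0, 0.0, ties="breslow")
        L0 = sw.breslow_baseline(null_fit, d)
        et, na = naive_nelson_aalen(d.times, d.events)
        np.testing.assert_allclose(L0(et), na, atol=1e-12)

    def test_step_function_properties(self, ph_cohort):
        fit = sw.cox_fit(ph_cohort, compute_sandwich=False)
        L0 = sw.breslow_baseline(fit, ph_cohort)
        ts = np.linspace(0, ph_cohort.times.max(), 50)
        vals = L0(ts)
        assert L0(0.0) == 0.0
        assert np.all(np.diff(vals) >= 0)

    def test_weight_rescaling_leaves_baseline_unchanged(self, ph_cohort, rng):
        w = rng.uniform(0.5, 1.5, ph_cohort.n)
        f1 = sw.cox_fit(ph_cohort, w, compute_sandwich=False)
        L1 = sw.breslow_baseline(f1, ph_cohort, w)
        f2 = sw.cox_fit(ph_cohort, 2.0 * w, compute_sandwich=False)
        L2 = sw.breslow_baseline(f2, ph_cohort, 2.0 * w)
        ts = np.linspace(0, ph_cohort.times.max(), 25)
        np.testing.assert_allclose(L1(ts), L2(ts), atol=1e-9)


class TestSandwich:
    def test_score_residuals_sum_to_zero_at_beta_hat(self, ph_cohort, rng):
        w = rng.uniform(0.3, 2.0, ph_cohort.n)
        fit = sw.cox_fit(ph_cohort, w, ties="breslow")
        V = _score_residuals(fit, ph_cohort, w)
        np.testing.assert_allclose(V.sum(axis=0), 0.0, atol=1e-7)

    def test_sandwich_is_symmetric_psd(self, ph_cohort, rng):
        w = rng.uniform(0.3, 2.0, ph_cohort.n)
        fit = sw.cox_fit(ph_cohort, w)
        S = fit.sandwich_cov
        np.testing.assert_allclose(S, S.T, atol=1e-14)
        assert np.all(np.linalg.eigvalsh(S) >= -1e-14)

    def test_sandwich_approaches_model_se_when_correctly_specified(self):
        """Unweighted, correctly specified PH: A = B asymptotically."""
        spec = sw.DGPSpec("ph", [0.7], censoring=("uniform", 4.0), n=5000, seed=21)
        d = sw.simulate(spec)
        fit = sw.cox_fit(d, ties="breslow")
        se_m = np.sqrt(fit.model_cov[0, 0])
        se_s = np.sqrt(fit.sandwich_cov[0, 0])
        assert abs(se_s / se_m - 1.0) < 0.10


def test_weight_placement_flag_changes_risk_sums(ph_cohort, rng):
    """events-only weighting is a different estimator from case weighting."""
    w = rng.uniform(0.1, 2.0, ph_cohort.n)
    f_case = sw.cox_fit(ph_cohort, w, compute_sandwich=False)
    f_ev = sw.cox_fit(ph_cohort, w, weight_placement="events-only",
                      compute_sandwich=False)
    assert abs(f_case.beta_hat[0] - f_ev.beta_hat[0]) > 1e-6
    # events-only score matches loops with unweighted risk sets
    s = sw.cox_score([0.3], ph_cohort, w, ties="breslow",
                     weight_placement="events-only")
    ref = naive_cox_score(0.3, ph_cohort.times, ph_cohort.events,
                          ph_cohort.covariates, w, risk_w=np.ones(ph_cohort.n))
    np.testing.assert_allclose(s, ref, atol=1e-8)
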