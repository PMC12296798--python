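"""Weighted Lin-Ying additive-hazards regression.

Simulates a cohort where the covariate acts additively on the hazard
(lambda(t|z) = 1 + 0.5 z), fits the closed-form Lin-Ying estimator
with cumulative-hazard-based weights from a noise-free external model,
and reports the estimated hazard difference with model-based, sandwich
and perturbation standard errors plus the fitted baseline.
"""

import numpy as np

import survweight as sw

dgp = sw.DGPSpec("ah", [0.5], baseline=("constant", 1.0),
                 covariate_law=[("bernoulli", 0.5)],
                 censoring=("uniform", 2.0), n=2000, seed=11)
data = sw.simulate(dgp)

preds = sw.external_predictions(
    data, sw.ExternalModelSpec("oracle_true", horizon=1.0), dgp)
weights = preds.as_weights("cumulative_hazard")   # w = 1 - exp(-H(1|z))

fit = sw.linying_fit(data, weights.values)
res = sw.perturbation_run(data, weights.values, model="additive",
                          B=1000, seed=3)
L0 = sw.linying_baseline(fit, data, weights.values)

print(f"n={data.n}, events={data.n_events}, true hazard difference = 0.5")
print(f"alpha_hat          = {fit.alpha_hat[0]:+.4f}")
print(f"se (model-based)   = {np.sqrt(fit.model_cov[0, 0]):.4f}")
print(f"se (sandwich)      = {np.sqrt(fit.sandwich_cov[0, 0]):.4f}")
print(f"se (perturbation)  = {res.se[0]:.4f}")
print(f"95% percentile CI  = [{res.ci[0, 0]:+.4f}, {res.ci[0, 1]:+.4f}]")
print(f"baseline Lambda0(1.0) = {L0(1.0):.4f}  (truth: 1.0)")
print()
print("alpha_hat estimates the additive hazard difference per unit of z;")
print("the closed-form estimator needs no iteration, and its sandwich and")
print("resampling SEs remain valid if the additive model is wrong.")
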