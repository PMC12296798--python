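"""What a misspecified weighted fit actually estimates.

When the fitted model is wrong (here: the truth has additive hazards
but a weighted Cox model is fitted), the estimator still converges —
to the least-false parameter beta*, the solution of the population
weighted estimating equation. This script estimates beta* with the
large-sample Monte-Carlo oracle and shows that finite-sample fits
concentrate on it as n grows.
"""

import numpy as np
from dataclasses import replace

import survweight as sw

truth = sw.DGPSpec("ah", [0.5], baseline=("constant", 1.0),
                   covariate_law=[("bernoulli", 0.5)],
                   censoring=("uniform", 2.0), n=1, seed=0)

oracle = sw.least_false_oracle(truth, weight_rule="survival_prob",
                               model="cox", n_oracle=200000, seed=5,
                               horizon=1.0)
print("additive-hazards truth (alpha = 0.5), weighted Cox working model")
print(f"least-false log hazard ratio beta* = {oracle.estimate[0]:.4f} "
      f"(MC se {oracle.mc_se[0]:.4f})\n")

for n in (500, 2000, 8000):
    d = sw.simulate(replace(truth, n=n), seed=100 + n)
    preds = sw.external_predictions(
        d, sw.ExternalModelSpec("oracle_true", horizon=1.0), truth)
    w = preds.as_weights("survival_prob")
    fit = sw.cox_fit(d, w.values)
    se = np.sqrt(fit.sandwich_cov[0, 0])
    print(f"n={n:5d}: beta_hat = {fit.beta_hat[0]:+.4f}  "
          f"sandwich se = {se:.4f}  "
          f"|beta_hat - beta*|/se = {abs(fit.beta_hat[0] - oracle.estimate[0]) / se:.2f}")

print()
print("The fits close in on beta*, not on the additive-model alpha: under")
print("misspecification the weighted Cox coefficient is a measure of")
print("association whose target is defined by the weights and the truth.")
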