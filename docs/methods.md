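# Methods

## Model and estimands

`survweight` fits two semiparametric working models to right-censored data
(X_i, δ_i, Z_i) with per-subject weights ŵ_i ≥ 0:

- proportional hazards, λ(t|Z) = λ₀(t)exp(β′Z);
- additive hazards (Lin–Ying), λ(t|Z) = λ₀(t) + α′Z.

Both estimators solve weighted martingale estimating equations
Σ_i ∫₀^τ ŵ_i {Z_i − Z̄_w(t)} dM̂_i(t;θ) = 0. The weights carry external
risk-prediction information; they are treated as deterministic functions of
each subject's covariates (regularity: bounded covariates, i.i.d. sampling,
positive probability of follow-up beyond τ, weights converging to
deterministic limits). Because a weighted working model is generically
misspecified, the estimand is the least-false parameter θ\*: the root of the
population version of the estimating equation under the true law. When the
fitted model is correct and the weights depend only on Z, θ\* coincides with
the true parameter; all parameter-recovery tests exploit this.

Weights are scalar per subject (constant in t). Time-varying weight
functions appear in the general theory but not in either worked algorithm;
they are a declared non-goal of this package.

## Weight construction

Two recipes map external predictions at a horizon h to weights:

- survival-probability scale: w = Ŝ(h|Z) (identity map);
- cumulative-hazard scale: w = 1 − exp(−Ĥ(h|Z)).

The second transform is a package choice: no canonical formula exists for
hazard-based weights, and mapping onto the event-probability scale makes the
two recipes commensurable (both live in [0,1]). Raw values can be supplied
verbatim as user weights. Each constructor takes `complement=True` to flip
direction (up-weight predicted high-risk subjects instead of predicted
survivors); the default is the survival-probability direction used by the
probability recipe. Both estimating equations are homogeneous of degree one
in the weights, so any positive rescaling (including the provided mean-one
normalisation) leaves point estimates unchanged — this is tested to 1e-8.

## Weight placement

With per-subject weights there are two readings of the weighted score: the
case-weight convention (weights multiply both the event terms and the
risk-set sums S⁽ᵏ⁾ / the at-risk mean Z̄) and an events-only convention
(ancillary risk-set quantities stay unweighted). Standard survival software
with a `weights=` argument implements the case-weight convention, which is
what the underlying methodology prescribes operationally; it is the default
here. The alternative is exposed as `weight_placement="events-only"` for
sensitivity analysis. Under case weights, an integer weight k is exactly
equivalent to duplicating the subject k times (Breslow ties) — the
replication tests rely on this identity.

## Proportional hazards: solver and ties

Newton–Raphson on the weighted log partial likelihood with step-halving (up
to 20 halvings; a step is accepted only if the concave objective does not
decrease beyond rounding at its own scale). Convergence is declared when
‖U(β)‖∞ ≤ tol × (total event weight); the proportional scaling keeps the
criterion invariant to weight rescaling, with default tol = 1e-9 and at
most 100 iterations. Divergence (‖β‖∞ > 50) raises `NonConvergence` —
the monotone-likelihood/separation signature. Singular information raises
`SingularInformation`. exp-overflow is guarded by centering β′Z at its
maximum inside every risk-set computation.

Ties: Efron (default, using the mean event weight within each tied group,
the convention of standard weighted survival software) and Breslow. The
Efron path is implemented as a correction applied on top of the vectorised
Breslow pass, touching only tied event-time groups, so tie-free data incur
no cost and the two methods coincide exactly without ties.

## Additive hazards

The weighted Lin–Ying estimator is closed-form:
α̂ = A⁻¹b with A = Σ_i ŵ_i ∫₀^τ Y_i(t){Z_i − Z̄_w(t)}Z_i′dt and
b = Σ_i ŵ_i δ_i {Z_i − Z̄_w(X_i)} (events in [0,τ]). All time integrals are
evaluated exactly over the inter-exit-time step structure — the at-risk
processes are piecewise constant — with no quadrature. τ defaults to the
largest observed time and is configurable on the dataset to guard against a
sparse tail. A condition number above 1e12 on A raises
`SingularDispersion` (collinear covariates, or no covariate variation).

## Robust (sandwich) covariance

- PH: Â = observed weighted information / n; B̂ = n⁻¹ Σ V_i V_i′ where V_i
  is the per-subject weighted score residual (the event term minus the
  subject's accumulated risk-set contributions over earlier event times).
  The residuals sum exactly to the score, hence to zero at β̂ — asserted in
  tests. Residuals are computed under the Breslow convention; tied event
  times have probability zero under the continuous-time conditions where
  the sandwich is validated. Covariance of β̂: Â⁻¹B̂Â⁻¹/n.
- AH: D̂ = A/n; Ê = n⁻¹ Σ Û_i Û_i′ with Û_i the integral of Z_i − Z̄_w
  against the *full* estimated martingale residual, including the estimated
  baseline increments. Including the baseline term is the correct i.i.d.
  representation under misspecification; the contributions still sum to
  zero at α̂ because the weighted at-risk covariate residuals integrate to
  zero against any baseline. Covariance of α̂: D̂⁻¹ÊD̂⁻¹/n.

The reported model-based covariances are the inverse information (PH) and
the D⁻¹(event-term outer products)D⁻¹ estimator (AH, with squared weights
so the unweighted case reduces to the classical Lin–Ying form). They are
reported for comparison; the sandwich is the inferential default.

## Perturbation resampling

B refits with weights G_i = V_i ŵ_i, V_i i.i.d. Exp(1) (mean = variance
= 1), warm-started at the point estimate; percentile confidence intervals
use linear-interpolation empirical quantiles at (1−level)/2 and
1−(1−level)/2, and the perturbation SE is the SD of the draws. The
uncentered multiplier form is implemented — it is what refitting standard
weighted software with V_i·ŵ_i produces, and it is the standard multiplier
bootstrap; the theoretical writings sometimes center the multipliers, which
differs only in presentation for unit-mean draws. The equivalence of the
conditional perturbation distribution and the unconditional sampling
distribution is not assumed: it is checked empirically (perturbation SE vs
sandwich SE on a fixed dataset; CI coverage across outer replicates).

Each draw's multiplier stream comes from `SeedSequence(seed).spawn(B)`, so
results are bit-identical for fixed (data, weights, model, B, seed)
regardless of internal batching. Failed refits are dropped and counted; a
failure rate above 10% raises, since percentile validity degrades. Cox
refits on tie-free data (or with Breslow ties) are solved by a batched
Newton iteration across all draws simultaneously, chunked to bound memory;
Efron-with-ties falls back to sequential refits. The batched and sequential
paths are asserted to agree in the tests.

## Synthetic data and the least-false oracle

The generator draws event times by inverse-transform sampling of the
conditional cumulative hazard (closed-form for constant and Weibull-PH
baselines; vectorised bisection for Weibull-AH), with independent uniform
or exponential censoring; `calibrate_censoring` tunes an exponential rate
to a target censoring fraction by root-finding on a pilot sample of true
event times. Covariate laws are Bernoulli and truncated-normal components,
compactly supported by construction. Additive specifications that permit a
negative hazard anywhere on the support are rejected at construction rather
than clipped — clipping would silently corrupt the oracle targets.

External models are emulated by fitting a PH or AH model, possibly on a
proper covariate subset (omitted-covariate misspecification), to a freshly
simulated independent cohort; `oracle_true` bypasses fitting and returns
noise-free true-model predictions, and `user_table` passes supplied
cumulative hazards through. Predictions are always returned on both scales,
related by S = exp(−H).

The least-false oracle solves the weighted estimating equation on a single
cohort of n = 200,000 with oracle-true weights (removing external-fit
noise), and attaches a block-jackknife Monte-Carlo SE from 10 contiguous
blocks. Monte-Carlo solution at large n was chosen over numerical
integration of the population score: it is model-agnostic, reuses the
estimators under test only through their defining equations, and its error
is directly quantifiable. Oracle stability across seeds is itself tested.

What the generator does not emulate: covariate measurement error, dependent
censoring, delayed entry, non-proportional or time-varying effects, and the
covariate-shift between external and local cohorts that arises in real
transportability problems (external cohorts are drawn from the same law).
Passing tests therefore demonstrate correctness of the estimators and
calibration of the inference under the stated sampling conditions, not
robustness to those additional real-data features.

## Study conditions used in the validation suite

The acceptance-style tests and `scripts/acceptance.py` use: a PH truth
(λ₀ = 1, β = 0.7, Z ~ Bernoulli(0.5), U(0,4) censoring) and an AH truth
(λ₀ = 1, α = 0.5, same covariate, U(0,2) censoring); informative weights
from noise-free predicted survival at horizon 1 (one unit of baseline mean
survival time); oracle size 200,000; a consistency check at n = 20,000;
error-decay medians over 50 replicates at n ∈ {250, 1000, 4000}; one fixed
n = 500 cohort with B = 1000 for the perturbation-vs-sandwich comparison;
200 outer replicates (n = 500, B = 1000) per coverage scenario; and 1000
replicates at n = 1000 per sandwich-validity cell. Tiny-instance oracle
checks (50 random datasets, n ≤ 8) compare the Cox solution against
grid-search maximisation (step 1e-4 on [−5,5]) and the additive solution
against bisection, skipping degenerate draws whose partial likelihood is
flat (singleton risk sets), where the maximiser is not unique.

## Known limitations

- No time-dependent covariates, left truncation, competing risks,
  stratification, or penalised estimation.
- Scalar (time-constant) weights only.
- The events-only weight placement is provided for sensitivity analysis;
  its sandwich variance reuses the case-weight construction and is not
  separately validated.
- Calibration of the external model is not assessed; poorly calibrated
  external predictions simply define a different (still well-defined)
  least-false estimand.
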