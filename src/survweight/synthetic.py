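"""Synthetic data generation and the least-false-parameter oracle.

This module supplies everything needed to exercise the weighted
estimators without real data:

* :class:`DGPSpec` — a fully specified data-generating process: a
  proportional-hazards (``"ph"``) or additive-hazards (``"ah"``) truth
  with a constant or Weibull baseline, compactly supported covariates
  (Bernoulli and truncated-normal components, so boundedness holds by
  construction), and independent uniform or exponential censoring.
* :func:`simulate` — inverse-transform sampling of event times from
  the specified conditional hazard.
* :func:`external_predictions` — emulates the external-cohort workflow:
  a prediction model (possibly omitting covariates, i.e. deliberately
  misspecified) is built on an independently simulated cohort and its
  predictions at a horizon are returned for the analysis subjects.
* :func:`least_false_oracle` — a Monte-Carlo estimate of the
  least-false parameter: the weighted estimating equation is solved on
  one very large simulated cohort with noise-free (true-model) weights,
  giving the consistency target for any (model, weight-rule)
  combination, correctly specified or not, with a block-jackknife
  Monte-Carlo standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import brentq

from .additive import linying_baseline, linying_fit
from .core import SurvivalDataset
from .cox import breslow_baseline, cox_fit
from .weights import (WeightVector, user_weights, weights_from_cumulative_hazard,
                      weights_from_survival_prob)

__all__ = [
    "DGPSpec",
    "ExternalModelSpec",
    "ExternalPredictions",
    "OracleResult",
    "simulate",
    "external_predictions",
    "least_false_oracle",
    "calibrate_censoring",
]

# covariate components: ("bernoulli", q) or ("truncnorm", mean, sd, low, high)
CovComponent = Tuple


@dataclass(frozen=True)
class DGPSpec:
    """A fully specified true data-generating process.

    baseline: ("constant", lam0) or ("weibull", shape, scale) where the
    Weibull baseline hazard is (shape/scale) (t/scale)^(shape-1).
    censoring: ("uniform", c_max), ("exponential", rate) or None.
    """

    model: str                              # "ph" | "ah"
    true_coef: np.ndarray
    baseline: Tuple = ("constant", 1.0)
    covariate_law: Sequence[CovComponent] = (("bernoulli", 0.5),)
    censoring: Optional[Tuple] = ("uniform", 4.0)
    n: int = 1000
    seed: int = 0

    def __post_init__(self):
        coef = np.atleast_1d(np.asarray(self.true_coef, dtype=float))
        object.__setattr__(self, "true_coef", coef)
        if self.model not in ("ph", "ah"):
            raise ValueError(f"unknown model {self.model!r}")
        if len(self.covariate_law) != coef.size:
            raise ValueError("one covariate component per coefficient required")
        kind = self.baseline[0]
        if kind not in ("constant", "weibull"):
            raise ValueError(f"unknown baseline {kind!r}")
        if self.censoring is not None and self.censoring[0] not in ("uniform", "exponential"):
            raise ValueError(f"unknown censoring law {self.censoring!r}")
        if self.model == "ah":
            self._check_nonnegative_hazard()

    # -- support of alpha'Z ------------------------------------------
    def _coef_range(self):
        lo = hi = 0.0
        for a, comp in zip(self.true_coef, self.covariate_law):
            if comp[0] == "bernoulli":
                cl, ch = min(0.0, a), max(0.0, a)
            elif comp[0] == "truncnorm":
                _, _, _, low, high = comp
                cl, ch = min(a * low, a * high), max(a * low, a * high)
            else:
                raise ValueError(f"unknown covariate component {comp[0]!r}")
            lo += cl
            hi += ch
        return lo, hi

    def _check_nonnegative_hazard(self):
        lo, _ = self._coef_range()
        kind = self.baseline[0]
        if kind == "constant":
            if self.baseline[1] + lo < 0:
                raise ValueError(
                    "additive DGP allows a negative hazard: "
                    f"lambda0 + min(alpha'Z) = {self.baseline[1] + lo:.4g} < 0")
        else:
            # a Weibull baseline hazard approaches 0 somewhere on (0, inf)
            if lo < 0:
                raise ValueError(
                    "additive DGP with non-constant baseline requires "
                    "alpha'Z >= 0 over the covariate support")

    # -- baseline cumulative hazard and inverse ----------------------
    def baseline_cumhaz(self, t):
        t = np.asarray(t, dtype=float)
        if self.baseline[0] == "constant":
            return self.baseline[1] * t
        _, shape, scale = self.baseline
        return (t / scale) ** shape

    def _inv_baseline_cumhaz(self, u):
        if self.baseline[0] == "constant":
            return u / self.baseline[1]
        _, shape, scale = self.baseline
        return scale * u ** (1.0 / shape)

    def conditional_cumhaz(self, t, Z):
        """True Lambda(t | Z) for each row of Z (t scalar or (n,))."""
        Z = np.atleast_2d(Z)
        lin = Z @ self.true_coef
        if self.model == "ph":
            return self.baseline_cumhaz(t) * np.exp(lin)
        return self.baseline_cumhaz(t) + lin * np.asarray(t, dtype=float)

    @property
    def p(self) -> int:
        return self.true_coef.size


def _draw_covariates(law, n, rng):
    cols = []
    for comp in law:
        if comp[0] == "bernoulli":
            cols.append(rng.binomial(1, comp[1], size=n).astype(float))
        elif comp[0] == "truncnorm":
            _, mean, sd, low, high = comp
            x = np.empty(n)
            need = np.ones(n, dtype=bool)
            while need.any():            # rejection sampling on [low, high]
                k = int(need.sum())
                cand = rng.normal(mean, sd, size=k)
                okc = (cand >= low) & (cand <= high)
                idx = np.flatnonzero(need)[okc]
                x[idx] = cand[okc]
                need[idx] = False
            cols.append(x)
        else:
            raise ValueError(f"unknown covariate component {comp[0]!r}")
    return np.column_stack(cols)


def _draw_event_times(spec: DGPSpec, Z, rng):
    E = rng.exponential(1.0, size=Z.shape[0])
    lin = Z @ spec.true_coef
    if spec.model == "ph":
        return spec._inv_baseline_cumhaz(E * np.exp(-lin))
    if spec.baseline[0] == "constant":
        lam = spec.baseline[1] + lin
        with np.errstate(divide="ignore"):
            return np.where(lam > 0, E / np.where(lam > 0, lam, 1.0), np.inf)
    # Weibull-baseline additive hazard: invert Lambda(t|Z) = E by bisection
    return _bisect_increasing(lambda t: spec.conditional_cumhaz(t, Z) - E,
                              Z.shape[0])


def _bisect_increasing(f, n, iters=80):
    lo = np.zeros(n)
    hi = np.ones(n)
    for _ in range(200):
        bad = f(hi) < 0
        if not bad.any():
            break
        hi[bad] *= 2.0
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        neg = f(mid) < 0
        lo = np.where(neg, mid, lo)
        hi = np.where(neg, hi, mid)
    return 0.5 * (lo + hi)


def _draw_censoring(spec: DGPSpec, n, rng):
    if spec.censoring is None:
        return np.full(n, np.inf)
    kind = spec.censoring[0]
    if kind == "uniform":
        return rng.uniform(0.0, spec.censoring[1], size=n)
    return rng.exponential(1.0 / spec.censoring[1], size=n)


def simulate(spec: DGPSpec, seed: Optional[int] = None) -> SurvivalDataset:
    """Draw one right-censored cohort from the specified truth.

    Event times come from inverse-transform sampling of the conditional
    cumulative hazard; censoring is drawn independently. Reproducible:
    the spec's seed (or the `seed` override) fully determines the data.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    Z = _draw_covariates(spec.covariate_law, spec.n, rng)
    T = _draw_event_times(spec, Z, rng)
    C = _draw_censoring(spec, spec.n, rng)
    X = np.minimum(T, C)
    if not np.all(np.isfinite(X)):
        # zero-hazard additive subjects never fail; they must be censored
        raise ValueError("infinite observed time: add censoring to the DGP")
    delta = (T <= C).astype(int)
    names = [f"z{k + 1}" for k in range(spec.p)]
    return SurvivalDataset(X, delta, Z, None, covariate_names=names)


def realized_censoring_fraction(spec: DGPSpec, seed: Optional[int] = None) -> float:
    data = simulate(spec, seed=seed)
    return 1.0 - data.n_events / data.n


def calibrate_censoring(spec: DGPSpec, target: float, n_pilot: int = 100000,
                        seed: int = 12345) -> DGPSpec:
    """Return a copy with exponential censoring tuned to a target fraction.

    Uses a pilot sample of true event times T and solves
    ``mean(1 - exp(-rate * T)) = target`` — exact for exponential
    censoring — by root-finding in log(rate).
    """
    if not (0.0 <= target <= 0.95):
        raise ValueError("target censoring fraction must lie in [0, 0.95]")
    if target == 0.0:
        return replace(spec, censoring=None)
    rng = np.random.default_rng(seed)
    pilot = replace(spec, n=n_pilot, censoring=None)
    Z = _draw_covariates(pilot.covariate_law, n_pilot, rng)
    T = _draw_event_times(pilot, Z, rng)

    def frac(log_rate):
        return np.mean(-np.expm1(-np.exp(log_rate) * T)) - target

    lo, hi = -20.0, 20.0
    rate = float(np.exp(brentq(frac, lo, hi, xtol=1e-10)))
    return replace(spec, censoring=("exponential", rate))


# ---------------------------------------------------------------------------
# external prediction models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExternalModelSpec:
    """How the external risk model is built and applied.

    A proper subset in `covariate_subset` makes the external model
    deliberately misspecified (omitted covariates). ``builder
    "oracle_true"`` bypasses fitting and uses the true conditional
    model; ``"user_table"`` passes a supplied cumulative-hazard column
    through unchanged.
    """

    builder: str                             # ph_fit | ah_fit | oracle_true | user_table
    covariate_subset: Optional[Sequence[int]] = None
    external_n: int = 1000
    horizon: float = 5.0
    seed: Optional[int] = None
    table: Optional[np.ndarray] = None       # cumulative hazards for user_table

    def __post_init__(self):
        if self.builder not in ("ph_fit", "ah_fit", "oracle_true", "user_table"):
            raise ValueError(f"unknown builder {self.builder!r}")
        if self.covariate_subset is not None and len(self.covariate_subset) == 0:
            raise ValueError("covariate subset must be non-empty")
        if not self.horizon > 0:
            raise ValueError("horizon must be positive")
        if self.builder == "user_table" and self.table is None:
            raise ValueError("user_table builder requires a prediction table")


@dataclass(frozen=True)
class ExternalPredictions:
    """Per-subject predictions on both scales at a common horizon."""

    surv_prob: np.ndarray
    cum_hazard: np.ndarray
    horizon: float

    def as_weights(self, rule: str = "survival_prob", complement: bool = False) -> WeightVector:
        if rule == "survival_prob":
            return weights_from_survival_prob(self.surv_prob, self.horizon, complement)
        if rule == "cumulative_hazard":
            return weights_from_cumulative_hazard(self.cum_hazard, self.horizon, complement)
        if rule == "unit":
            return user_weights(np.ones_like(self.surv_prob))
        raise ValueError(f"unknown weight rule {rule!r}")


def external_predictions(analysis_data: SurvivalDataset, ext: ExternalModelSpec,
                         dgp: DGPSpec) -> ExternalPredictions:
    """Predictions at `ext.horizon` for every analysis subject.

    For fitted builders a fresh external cohort of size ``external_n``
    is simulated from the same truth, independently of the analysis
    cohort, and the prediction model uses only ``covariate_subset``.
    """
    Z = analysis_data.covariates
    h = ext.horizon
    if ext.builder == "user_table":
        H = np.asarray(ext.table, dtype=float)
        if H.shape[0] != analysis_data.n:
            raise ValueError("user table length does not match analysis cohort")
        return ExternalPredictions(np.exp(-H), H, h)
    if ext.builder == "oracle_true":
        H = np.maximum(dgp.conditional_cumhaz(h, Z), 0.0)
        return ExternalPredictions(np.exp(-H), H, h)
    sub = list(ext.covariate_subset) if ext.covariate_subset is not None \
        else list(range(dgp.p))
    ext_seed = ext.seed if ext.seed is not None else dgp.seed + 101
    cohort = simulate(replace(dgp, n=ext.external_n), seed=ext_seed)
    cohort_sub = SurvivalDataset(cohort.times, cohort.events,
                                 cohort.covariates[:, sub])
    Zsub = Z[:, sub]
    if ext.builder == "ph_fit":
        fit = cox_fit(cohort_sub, compute_sandwich=False)
        L0 = breslow_baseline(fit, cohort_sub)
        H = L0(h) * np.exp(Zsub @ fit.beta_hat)
    else:                                    # ah_fit
        fit = linying_fit(cohort_sub, compute_sandwich=False)
        L0 = linying_baseline(fit, cohort_sub)
        H = np.maximum(L0(h) + (Zsub @ fit.alpha_hat) * h, 0.0)
    return ExternalPredictions(np.exp(-H), np.asarray(H, dtype=float), h)


# ---------------------------------------------------------------------------
# least-false oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OracleResult:
    """Monte-Carlo least-false parameter with its uncertainty."""

    estimate: np.ndarray
    mc_se: np.ndarray
    n_oracle: int
    model: str
    weight_rule: str


def least_false_oracle(dgp: DGPSpec,
                       weight_rule: Union[str, Callable] = "unit",
                       model: str = "cox",
                       n_oracle: int = 200000,
                       seed: int = 0,
                       horizon: float = 5.0,
                       n_blocks: int = 10,
                       weight_complement: bool = False) -> OracleResult:
    """Monte-Carlo estimate of the least-false parameter beta*/alpha*.

    One cohort of size `n_oracle` is simulated from `dgp`; weights come
    from noise-free true-model predictions at `horizon` (removing
    external-fit noise), or from a callable ``weight_rule(predictions)
    -> array``. The weighted estimating equation is solved on the full
    cohort; the Monte-Carlo SE is the block-jackknife SE over
    `n_blocks` contiguous (i.i.d.) blocks.
    """
    big = simulate(replace(dgp, n=n_oracle), seed=seed)
    preds = external_predictions(big, ExternalModelSpec("oracle_true", horizon=horizon), dgp)
    if callable(weight_rule):
        wv = user_weights(weight_rule(preds))
        rule_name = getattr(weight_rule, "__name__", "callable")
    else:
        wv = preds.as_weights(weight_rule, complement=weight_complement)
        rule_name = weight_rule

    def _solve(ds, wvals):
        if model == "cox":
            return cox_fit(ds, wvals, ties="breslow", compute_sandwich=False).beta_hat
        return linying_fit(ds, wvals, compute_sandwich=False).alpha_hat

    est = _solve(big, wv.values)
    blocks = np.array_split(np.arange(n_oracle), n_blocks)
    block_est = np.stack([_solve(big.subset(b), wv.values[b]) for b in blocks])
    mc_se = block_est.std(axis=0, ddof=1) / np.sqrt(n_blocks)
    return OracleResult(est, mc_se, n_oracle, model, rule_name)
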