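"""Perturbation (multiplier) resampling inference.

The sampling distribution of the weighted estimator is approximated by
refitting the model B times with per-subject weights ``G_i = V_i w_i``,
where ``V_1..V_n`` are i.i.d. unit-mean, unit-variance Exp(1)
multipliers drawn fresh for each refit. Conditional on the data, the
spread of the perturbed estimates around the point estimate mimics the
unconditional spread of the estimator around its (least-false) target,
so percentile confidence intervals and a perturbation standard error
can be read off the B draws directly — no analytic variance needed and
no model-correctness assumption used.

Determinism: every multiplier stream is derived from the user seed via
``numpy.random.SeedSequence(seed).spawn(B)``, so a run is bit-for-bit
reproducible given ``(data, weights, model, B, seed)`` regardless of
how the refits are batched internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .additive import linying_fit
from .core import SurvivalDataset, require_valid
from .cox import _Sorted, _batched_breslow_newton, _resolve_weights, cox_fit
from .exceptions import NonConvergence, SingularDispersion, SingularInformation

__all__ = [
    "PerturbationResult",
    "draw_multipliers",
    "perturbed_fit",
    "perturbation_run",
    "percentile_ci",
]

_MAX_FAIL_FRACTION = 0.10


@dataclass
class PerturbationResult:
    """B perturbed estimates with percentile CIs and resampling SEs."""

    draws: np.ndarray            # (B_ok, p), failed refits excluded
    B: int
    seed: Optional[int]
    point_estimate: np.ndarray
    ci: np.ndarray               # (p, 2) lower/upper at `level`
    se: np.ndarray               # (p,) SD of draws
    level: float
    n_failed: int
    model: str = "cox"


def draw_multipliers(n: int, rng_seed) -> np.ndarray:
    """n i.i.d. Exp(1) multipliers (mean 1, variance 1); seeded."""
    if n < 1:
        raise ValueError("need n >= 1 multipliers")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    return rng.exponential(1.0, size=n)


def perturbed_fit(data: SurvivalDataset, w, model: str, rng,
                  multipliers=None, ties: str = "efron",
                  weight_placement: str = "case", beta_init=None):
    """One perturbed refit with weights V_i * w_i, warm-started.

    Returns ``(estimate, ok)``; non-convergence is flagged, not raised,
    so the caller can count and exclude failed draws.
    """
    V = np.asarray(multipliers, float) if multipliers is not None \
        else draw_multipliers(data.n, rng)
    base = data.weights if w is None else np.asarray(getattr(w, "values", w), float)
    gw = V * base
    try:
        if model == "cox":
            fit = cox_fit(data, gw, ties=ties, weight_placement=weight_placement,
                          beta_init=beta_init, compute_sandwich=False)
            return fit.beta_hat, True
        elif model == "additive":
            fit = linying_fit(data, gw, weight_placement=weight_placement,
                              compute_sandwich=False)
            return fit.alpha_hat, True
        raise ValueError(f"unknown model {model!r}")
    except (NonConvergence, SingularInformation, SingularDispersion):
        return np.full(data.p, np.nan), False


def percentile_ci(draws, level: float) -> np.ndarray:
    """Per-coefficient percentile interval of the perturbed estimates.

    Empirical quantiles at (1-level)/2 and 1-(1-level)/2, using the
    linear-interpolation quantile definition (numpy's default), which
    makes intervals reproducible bit-exactly.
    """
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    if draws.shape[0] < 2:
        raise ValueError("need at least 2 draws for a percentile interval")
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie strictly between 0 and 1")
    a = (1.0 - level) / 2.0
    qs = np.quantile(draws, [a, 1.0 - a], axis=0, method="linear")
    return qs.T                      # (p, 2)


def perturbation_run(data: SurvivalDataset, w=None, model: str = "cox",
                     B: int = 1000, seed: Optional[int] = None,
                     level: float = 0.95, ties: str = "efron",
                     weight_placement: str = "case") -> PerturbationResult:
    """Full resampling run: B perturbed refits, CIs and SEs.

    The baseline fit is computed first and used to warm-start every
    refit. Cox refits on tie-free data (or with Breslow tie handling)
    are solved in a single batched Newton iteration across all draws;
    otherwise draws are refit one at a time. Raises if more than 10% of
    refits fail (percentile validity degrades beyond that).
    """
    require_valid(data)
    if B < 2:
        raise ValueError("need B >= 2 perturbation draws")
    base = data.weights if w is None else np.asarray(getattr(w, "values", w), float)
    if model == "cox":
        fit0 = cox_fit(data, base, ties=ties, weight_placement=weight_placement,
                       compute_sandwich=False)
        point = fit0.beta_hat
    elif model == "additive":
        fit0 = linying_fit(data, base, weight_placement=weight_placement,
                           compute_sandwich=False)
        point = fit0.alpha_hat
    else:
        raise ValueError(f"unknown model {model!r}")

    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(B)]
    V = np.stack([draw_multipliers(data.n, g) for g in streams])   # (B, n)

    has_tied_events = _has_tied_events(data)
    if model == "cox" and (ties == "breslow" or not has_tied_events):
        draws, ok = _batched_cox(data, base, weight_placement, V, point)
    else:
        draws = np.empty((B, data.p))
        ok = np.zeros(B, dtype=bool)
        for b in range(B):
            draws[b], ok[b] = perturbed_fit(
                data, base, model, None, multipliers=V[b], ties=ties,
                weight_placement=weight_placement, beta_init=point)
    n_failed = int(B - ok.sum())
    if n_failed > _MAX_FAIL_FRACTION * B:
        raise NonConvergence(
            f"{n_failed}/{B} perturbed refits failed to converge")
    good = draws[ok]
    ci = percentile_ci(good, level)
    se = good.std(axis=0, ddof=1)
    return PerturbationResult(
        draws=good, B=B, seed=seed, point_estimate=point, ci=ci, se=se,
        level=level, n_failed=n_failed, model=model)


def _has_tied_events(data) -> bool:
    et = data.times[data.events == 1]
    return np.unique(et).size < et.size


def _batched_cox(data, base_w, weight_placement, V, beta0):
    ew, rw = _resolve_weights(data, base_w, weight_placement)
    sd = _Sorted(data, ew, rw)
    Vs = V[:, sd.order]
    EW = Vs * sd.ews[None, :]
    RW = Vs * sd.rws[None, :] if weight_placement == "case" else \
        np.broadcast_to(sd.rws, Vs.shape).copy()
    return _batched_breslow_newton(sd, EW, RW, beta0)
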