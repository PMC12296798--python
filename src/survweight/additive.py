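"""Weighted semiparametric additive-hazards (Lin–Ying) estimation.

The model is ``lambda(t|Z) = lambda_0(t) + alpha'Z`` with an
unspecified baseline; ``alpha`` is a vector of hazard differences and
is estimable in closed form. With per-subject weights ``w_i`` the
estimator solves

    U(alpha) = sum_i w_i \\int_0^tau (Z_i - Zbar_w(t)) {dN_i(t) - Y_i(t) alpha'Z_i dt} = 0,

where under the default case-weight convention ``Zbar_w(t)`` is the
weighted at-risk covariate mean; ``weight_placement="events-only"``
uses the unweighted mean (each subject's whole martingale increment is
still multiplied by its weight). All integrals are evaluated exactly
over the inter-exit-time step structure — the at-risk processes are
piecewise constant — so no quadrature is involved.

As with the proportional-hazards module the fitted model is treated as
a working model: ``alpha_hat`` targets a least-false parameter and the
robust covariance is the sandwich ``D^-1 E D^-1`` built from
per-subject martingale-residual integrals (:func:`additive_sandwich`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._stepfun import StepFunction
from .core import SurvivalDataset, require_valid
from .cox import _resolve_weights, _suffix_cumsum
from .exceptions import SingularDispersion

__all__ = ["AdditiveFit", "linying_fit", "linying_baseline", "additive_sandwich"]

_COND_LIMIT = 1e12


@dataclass
class AdditiveFit:
    """Closed-form weighted additive-hazards fit."""

    alpha_hat: np.ndarray
    D_hat: np.ndarray           # slope of the estimating function / n
    E_hat: np.ndarray           # sum_i U_i U_i' / n
    model_cov: np.ndarray       # D^-1 (event-term meat) D^-1 style estimator
    sandwich_cov: np.ndarray    # D^-1 E D^-1 / n
    converged: bool
    n_iter: int
    score_norm: float
    weight_placement: str = "case"
    covariate_names: list = field(default_factory=list)

    @property
    def estimate(self):
        return self.alpha_hat


class _AddParts:
    """Shared sorted quantities for the additive estimating function.

    Everything is expressed on the time grid of sorted exit times
    ``ts`` truncated at ``tau``; interval k is ``(ts[k-1], ts[k]]``
    with length ``dt[k]`` and at-risk suffix starting at ``first[k]``.
    """

    def __init__(self, data: SurvivalDataset, ew, rw):
        order = np.argsort(data.times, kind="stable")
        self.order = order
        self.ts = data.times[order]
        self.ds = data.events[order]
        self.Zs = data.covariates[order]
        self.ews = ew[order]
        self.rws = rw[order]
        self.tau = data.tau
        self.n, self.p = self.Zs.shape
        self.first = np.searchsorted(self.ts, self.ts, side="left")
        tcap = np.minimum(self.ts, self.tau)
        self.dt = np.diff(np.concatenate([[0.0], tcap]))   # interval lengths
        # risk-weighted suffix sums (placement-dependent mean Zbar)
        self.R0 = _suffix_cumsum(self.rws)
        self.R1 = _suffix_cumsum(self.rws[:, None] * self.Zs)
        # event-weighted suffix sums (always the subject weights)
        self.W0 = _suffix_cumsum(self.ews)
        self.W1 = _suffix_cumsum(self.ews[:, None] * self.Zs)
        self.W2 = _suffix_cumsum(
            self.ews[:, None, None] * self.Zs[:, None, :] * self.Zs[:, :, None])
        with np.errstate(invalid="ignore", divide="ignore"):
            self.Zbar = np.where(self.R0[:, None] > 0,
                                 self.R1 / np.where(self.R0 > 0, self.R0, 1.0)[:, None],
                                 0.0)
        # events observed within [0, tau] with positive weight risk sets
        self.ev = np.flatnonzero((self.ds == 1) & (self.ts <= self.tau))
        self.a_ev = self.first[self.ev]

    def dispersion(self):
        """A = sum_i w_i \\int_0^tau Y_i (Z_i - Zbar(t)) Z_i' dt  (p x p)."""
        a = self.first
        # on interval ending at ts[k], at-risk suffix starts at first[k]
        term = self.W2[a] - self.Zbar[a][:, :, None] * self.W1[a][:, None, :]
        return np.tensordot(self.dt, term, axes=(0, 0))

    def event_vector(self):
        """b = sum events w_i (Z_i - Zbar(X_i))."""
        ZE = self.Zs[self.ev]
        return (self.ews[self.ev, None] * (ZE - self.Zbar[self.a_ev])).sum(axis=0)


def _parts(data, w, weight_placement):
    require_valid(data)
    ew, rw = _resolve_weights(data, w, weight_placement)
    return _AddParts(data, ew, rw)


def linying_fit(data: SurvivalDataset, w=None,
                weight_placement: str = "case",
                compute_sandwich: bool = True) -> AdditiveFit:
    """Closed-form weighted Lin–Ying estimator.

    ``alpha_hat = A^{-1} b`` with the weighted covariate-dispersion
    matrix ``A`` and event vector ``b`` defined in the module docstring.
    Raises :class:`SingularDispersion` when A is (numerically) singular,
    e.g. for collinear covariates or a single distinct covariate value.
    """
    sp = _parts(data, w, weight_placement)
    A = sp.dispersion()
    b = sp.event_vector()
    if not np.all(np.isfinite(A)) or np.linalg.cond(A) > _COND_LIMIT:
        raise SingularDispersion(
            "covariate dispersion matrix is singular or near-singular")
    alpha = np.linalg.solve(A, b)
    n = sp.n
    score_norm = float(np.max(np.abs(b - A @ alpha)))
    # Lin–Ying style model-based covariance: event-term outer products
    ZE = sp.Zs[sp.ev]
    resid = sp.ews[sp.ev, None] * (ZE - sp.Zbar[sp.a_ev])
    meat_model = resid.T @ resid
    Ainv = np.linalg.inv(A)
    fit = AdditiveFit(
        alpha_hat=alpha, D_hat=A / n, E_hat=np.full((sp.p, sp.p), np.nan),
        model_cov=Ainv @ meat_model @ Ainv,
        sandwich_cov=np.full((sp.p, sp.p), np.nan),
        converged=True, n_iter=0, score_norm=score_norm,
        weight_placement=weight_placement,
        covariate_names=list(data.covariate_names),
    )
    if compute_sandwich:
        fit.sandwich_cov = additive_sandwich(fit, data, w)
    return fit


def additive_score(alpha, data: SurvivalDataset, w=None,
                   weight_placement: str = "case") -> np.ndarray:
    """Estimating function U(alpha) (un-normalised sum over subjects)."""
    sp = _parts(data, w, weight_placement)
    return sp.event_vector() - sp.dispersion() @ np.atleast_1d(np.asarray(alpha, float))


def linying_baseline(fit: AdditiveFit, data: SurvivalDataset, w=None) -> "_AdditiveBaseline":
    """Baseline cumulative hazard of the fitted additive model.

    ``Lambda0(t) = sum_{events <= t} w_e / R0(X_e) - \\int_0^t alpha'Zbar(u) du``
    — a jump part at event times plus a piecewise-linear drift. Returns
    a callable evaluating Lambda0 at arbitrary times.
    """
    sp = _parts(data, w, fit.weight_placement)
    a = sp.a_ev
    R0e = sp.R0[a]
    if np.any((R0e <= 0) & (sp.ews[sp.ev] > 0)):
        raise ZeroDivisionError("empty weighted risk set at an event time")
    jumps = np.where(R0e > 0, sp.ews[sp.ev] / np.where(R0e > 0, R0e, 1.0), 0.0)
    return _AdditiveBaseline(sp, fit.alpha_hat, sp.ts[sp.ev], jumps)


class _AdditiveBaseline:
    def __init__(self, sp: _AddParts, alpha, ev_times, jumps):
        uniq, inv = np.unique(ev_times, return_inverse=True)
        agg = np.zeros_like(uniq)
        np.add.at(agg, inv, jumps)
        self._jump = StepFunction(uniq, np.cumsum(agg))
        # cumulative integral of alpha'Zbar over the step structure
        drift_rate = sp.Zbar[sp.first] @ alpha       # value on interval k
        self._knots = sp.ts.copy()
        self._cumdrift = np.cumsum(drift_rate * np.diff(np.concatenate([[0.0], sp.ts])))
        self._rates = drift_rate

    def _drift(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self._knots, t, side="left")
        idx_c = np.clip(idx, 0, self._knots.size - 1)
        base = np.where(idx_c > 0, self._cumdrift[np.clip(idx_c - 1, 0, None)], 0.0)
        prev = np.where(idx_c > 0, self._knots[np.clip(idx_c - 1, 0, None)], 0.0)
        rate = self._rates[idx_c]
        return base + rate * np.clip(t - prev, 0.0, None)

    def __call__(self, t):
        out = self._jump(t) - self._drift(t)
        return out if np.ndim(out) else float(out)


def _contributions(fit: AdditiveFit, data: SurvivalDataset, w):
    """Per-subject estimating-function contributions U_i(alpha_hat).

    U_i = w_i [ delta_i (Z_i - Zbar(X_i))
               - sum_{events e <= X_i} (Z_i - Zbar(X_e)) dLambda0_jump(X_e)
               - \\int_0^{X_i ^ tau} (Z_i - Zbar(t)) alpha'(Z_i - Zbar(t)) dt ],

    i.e. the integral of (Z_i - Zbar) against the full estimated
    martingale residual, including the estimated baseline. The
    contributions sum to U(alpha_hat) = 0 under the case-weight
    convention.
    """
    sp = _parts(data, w, fit.weight_placement)
    alpha = fit.alpha_hat
    n, p = sp.n, sp.p
    ev = sp.ev
    a = sp.a_ev
    R0e = sp.R0[a]
    jumps = np.where(R0e > 0, sp.ews[ev] / np.where(R0e > 0, R0e, 1.0), 0.0)
    Zbar_e = sp.Zbar[a]
    # cumulative jump functionals over event times
    c0 = np.concatenate([[0.0], np.cumsum(jumps)])
    c1 = np.concatenate([np.zeros((1, p)), np.cumsum(jumps[:, None] * Zbar_e, axis=0)])
    pos = np.searchsorted(sp.ts[ev], np.minimum(sp.ts, sp.tau), side="right")
    jump_term = sp.Zs * c0[pos][:, None] - c1[pos]
    # drift integrals: for subject at sorted position j, integral over
    # intervals k = 0..j of dt[k] * f(Zbar at first[k]); subject j is at
    # risk on exactly those intervals (its own interval ends at ts[j]).
    Zb = sp.Zbar[sp.first]                     # (n, p), value on interval k
    g1 = np.cumsum(sp.dt[:, None] * Zb, axis=0)            # \int Zbar dt
    g0 = np.cumsum(sp.dt)                                   # \int dt
    g2 = np.cumsum(sp.dt[:, None] * Zb * (Zb @ alpha)[:, None], axis=0)
    g1a = np.cumsum(sp.dt * (Zb @ alpha))
    j = np.arange(n)
    Za = sp.Zs @ alpha
    # \int_0^{X_j} (Z_j - Zbar)(alpha'Z_j - alpha'Zbar) dt
    drift_term = (sp.Zs * (Za * g0[j])[:, None]
                  - sp.Zs * g1a[j][:, None]
                  - g1[j] * Za[:, None]
                  + g2[j])
    U = -(jump_term + drift_term)
    U[ev] += sp.Zs[ev] - Zbar_e
    U *= sp.ews[:, None]
    out = np.empty_like(U)
    out[sp.order] = U
    return out


def additive_sandwich(fit: AdditiveFit, data: SurvivalDataset, w=None) -> np.ndarray:
    """Model-robust covariance  D^-1 E D^-1 / n  of alpha_hat."""
    U = _contributions(fit, data, w)
    n = data.n
    E = (U.T @ U) / n
    fit.E_hat = E
    D = fit.D_hat
    if np.linalg.cond(D) > _COND_LIMIT:
        raise SingularDispersion("dispersion matrix singular")
    Dinv = np.linalg.inv(D)
    return Dinv @ E @ Dinv / n
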