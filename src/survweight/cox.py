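"""Weighted proportional-hazards estimation with model-robust inference.

The hazard model is ``lambda(t|Z) = lambda_0(t) exp(beta'Z)``.  With
per-subject weights ``w_i`` (typically built from an external risk
model, see :mod:`survweight.weights`), the coefficient solves the
weighted partial-likelihood score equation

    U(beta) = sum_i w_i * delta_i * { Z_i - S1(beta, X_i)/S0(beta, X_i) } = 0,

where under the default *case-weight* convention the risk-set sums
``S^(k)(beta, t) = sum_j w_j I(X_j >= t) Z_j^(k) exp(beta'Z_j)`` carry
the weights as well — exactly what standard survival software does with
per-subject weights.  The alternative ``weight_placement="events-only"``
leaves the risk-set sums unweighted.

Because the fitted model is in general a working (misspecified) model,
``beta_hat`` converges to a least-false parameter and its variance is
estimated by the sandwich ``A^-1 B A^-1`` built from per-subject
weighted score residuals (:func:`cox_sandwich`), not by the inverse
information alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._stepfun import StepFunction
from .core import SurvivalDataset, require_valid
from .exceptions import NonConvergence, SingularInformation

__all__ = ["CoxFit", "cox_score", "cox_loglik", "cox_fit", "breslow_baseline", "cox_sandwich"]

_DIVERGE_NORM = 50.0
_MAX_HALVINGS = 20


# ---------------------------------------------------------------------------
# sorted internal representation
# ---------------------------------------------------------------------------

class _Sorted:
    """Dataset sorted by ascending follow-up time.

    ``first[k]`` is the first sorted position carrying time ``ts[k]``,
    so the at-risk suffix at time ``ts[k]`` starts at ``first[k]``
    (events and censorings tied at ``t`` are both at risk at ``t``).
    """

    def __init__(self, data: SurvivalDataset, event_w, risk_w):
        order = np.argsort(data.times, kind="stable")
        self.order = order
        self.ts = data.times[order]
        self.ds = data.events[order]
        self.Zs = data.covariates[order]
        self.ews = np.asarray(event_w, dtype=float)[order]
        self.rws = np.asarray(risk_w, dtype=float)[order]
        self.first = np.searchsorted(self.ts, self.ts, side="left")
        self.ev = np.flatnonzero(self.ds == 1)
        self.a_ev = self.first[self.ev]          # risk-set start per event
        self.n, self.p = self.Zs.shape


def _resolve_weights(data: SurvivalDataset, w, weight_placement: str):
    if w is None:
        base = data.weights
    else:
        base = np.asarray(getattr(w, "values", w), dtype=float)
    if base.shape[0] != data.n:
        raise ValueError("weight vector length does not match dataset")
    if weight_placement not in ("case", "events-only"):
        raise ValueError(f"unknown weight_placement {weight_placement!r}")
    risk = base if weight_placement == "case" else np.ones(data.n)
    return base, risk


def _suffix_cumsum(a, axis=0):
    return np.flip(np.cumsum(np.flip(a, axis=axis), axis=axis), axis=axis)


def _breslow_parts(sd: _Sorted, beta):
    """Log-likelihood, score and information under Breslow tie handling."""
    eta = sd.Zs @ beta
    m = eta.max() if eta.size else 0.0
    r = sd.rws * np.exp(eta - m)
    S0 = _suffix_cumsum(r)
    S1 = _suffix_cumsum(r[:, None] * sd.Zs)
    # r_j Z_j Z_j' summed over the at-risk suffix; p^2 * n floats, p is small
    S2 = _suffix_cumsum(r[:, None, None] * sd.Zs[:, :, None] * sd.Zs[:, None, :])
    ew = sd.ews[sd.ev]
    a = sd.a_ev
    good = ew > 0
    S0a = np.where(S0[a] > 0, S0[a], 1.0)
    Zbar = S1[a] / S0a[:, None]
    Zev = sd.Zs[sd.ev]
    contrib_ll = ew * (eta[sd.ev] - m - np.log(S0a))
    contrib_sc = ew[:, None] * (Zev - Zbar)
    S2n = S2[a] / S0a[:, None, None]
    contrib_in = ew[:, None, None] * (S2n - Zbar[:, :, None] * Zbar[:, None, :])
    if not np.all(good):
        contrib_ll = np.where(good, contrib_ll, 0.0)
        contrib_sc = np.where(good[:, None], contrib_sc, 0.0)
        contrib_in = np.where(good[:, None, None], contrib_in, 0.0)
    ll = float(contrib_ll.sum())
    score = contrib_sc.sum(axis=0)
    info = contrib_in.sum(axis=0)
    if not (np.isfinite(ll) and np.all(np.isfinite(score)) and np.all(np.isfinite(info))):
        raise FloatingPointError("non-finite partial-likelihood quantities (exp overflow?)")
    return ll, score, info, (eta, m, S0, S1, Zbar, S0a)


def _efron_adjust(sd: _Sorted, beta, ll, score, info, cache):
    """Replace the Breslow contribution of tied-event groups by Efron's.

    Uses the mean event weight within a tie group (the convention of
    standard weighted survival software). With no tied events this is a
    no-op and Efron coincides with Breslow.
    """
    eta, m, S0, S1, _, _ = cache
    ev_times = sd.ts[sd.ev]
    uniq, start, counts = np.unique(ev_times, return_index=True, return_counts=True)
    tied = np.flatnonzero(counts >= 2)
    if tied.size == 0:
        return ll, score, info
    r = sd.rws * np.exp(eta - m)
    for g in tied:
        rows = sd.ev[start[g]: start[g] + counts[g]]   # sorted event rows at this time
        d = rows.size
        a = sd.first[rows[0]]
        ewD = sd.ews[rows]
        wbar = ewD.mean()
        rD = r[rows]
        ZD = sd.Zs[rows]
        S0t, S1t = S0[a], S1[a]
        S2t = _local_S2(sd, a)
        S0D = rD.sum()
        S1D = (rD[:, None] * ZD).sum(axis=0)
        S2D = np.einsum("i,ij,ik->jk", rD, ZD, ZD)
        # subtract the Breslow contribution of this group
        Zbar_t = S1t / S0t
        ll -= float(np.sum(ewD * (eta[rows] - m)) - ewD.sum() * np.log(S0t))
        score -= (ewD[:, None] * (ZD - Zbar_t)).sum(axis=0)
        info -= ewD.sum() * (S2t / S0t - np.outer(Zbar_t, Zbar_t))
        # add the Efron contribution
        k = np.arange(d) / d
        S0k = S0t - k * S0D
        S1k = S1t[None, :] - k[:, None] * S1D[None, :]
        S2k = S2t[None] - k[:, None, None] * S2D[None]
        Zbk = S1k / S0k[:, None]
        ll += float(np.sum(ewD * (eta[rows] - m)) - wbar * np.log(S0k).sum())
        score += (ewD[:, None] * ZD).sum(axis=0) - wbar * Zbk.sum(axis=0)
        info += wbar * (S2k / S0k[:, None, None]
                        - Zbk[:, :, None] * Zbk[:, None, :]).sum(axis=0)
    return ll, score, info


def _local_S2(sd: _Sorted, a):
    """Suffix sum of r_j Z_j Z_j' from sorted position `a` (tie groups only)."""
    eta = sd._eta_cache
    r = sd.rws[a:] * np.exp(eta[a:] - sd._m_cache)
    Z = sd.Zs[a:]
    return np.einsum("i,ij,ik->jk", r, Z, Z)


def _evaluate(sd: _Sorted, beta, ties):
    ll, score, info, cache = _breslow_parts(sd, beta)
    if ties == "efron":
        sd._eta_cache, sd._m_cache = cache[0], cache[1]
        ll, score, info = _efron_adjust(sd, beta, ll, score, info, cache)
    return ll, score, info, cache


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Converged weighted proportional-hazards fit."""

    beta_hat: np.ndarray
    loglik: float
    info: np.ndarray            # A-hat = observed weighted information / n
    meat: np.ndarray            # B-hat = sum_i V_i V_i' / n
    model_cov: np.ndarray       # inverse total information
    sandwich_cov: np.ndarray    # A^-1 B A^-1 / n
    converged: bool
    n_iter: int
    score_norm: float
    ties: str = "efron"
    weight_placement: str = "case"
    covariate_names: list = field(default_factory=list)

    @property
    def estimate(self):
        return self.beta_hat


def cox_score(beta, data: SurvivalDataset, w=None, ties: str = "breslow",
              weight_placement: str = "case") -> np.ndarray:
    """Weighted partial-likelihood score U(beta)."""
    require_valid(data)
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie method {ties!r}")
    ew, rw = _resolve_weights(data, w, weight_placement)
    sd = _Sorted(data, ew, rw)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    _, score, _, _ = _evaluate(sd, beta, ties)
    return score


def cox_loglik(beta, data: SurvivalDataset, w=None, ties: str = "breslow",
               weight_placement: str = "case") -> float:
    """Weighted log partial likelihood at `beta`."""
    require_valid(data)
    ew, rw = _resolve_weights(data, w, weight_placement)
    sd = _Sorted(data, ew, rw)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    ll, _, _, _ = _evaluate(sd, beta, ties)
    return ll


def _newton(sd: _Sorted, beta0, ties, tol, max_iter):
    beta = beta0.copy()
    ll, score, info, cache = _evaluate(sd, beta, ties)
    n_iter = 0
    # the score is a sum over events, so the attainable accuracy scales
    # with the total event weight; tol is interpreted per unit of it
    # (proportional scaling keeps convergence weight-scale invariant)
    tol = tol * max(float(sd.ews[sd.ev].sum()), 1e-100)
    while True:
        score_norm = float(np.max(np.abs(score))) if score.size else 0.0
        if score_norm <= tol:
            return beta, ll, info, cache, True, n_iter, score_norm
        if n_iter >= max_iter:
            return beta, ll, info, cache, False, n_iter, score_norm
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as e:
            raise SingularInformation(
                "singular information matrix (collinear covariates?)") from e
        if not np.all(np.isfinite(step)):
            raise SingularInformation("non-finite Newton step")
        accepted = False
        for _ in range(_MAX_HALVINGS + 1):
            cand = beta + step
            try:
                ll_new, score_new, info_new, cache_new = _evaluate(sd, cand, ties)
            except FloatingPointError:
                step *= 0.5
                continue
            # concave objective: accept only non-decreasing steps, up to
            # rounding at the scale of the log-likelihood itself
            if ll_new >= ll - 1e-10 * (1.0 + abs(ll)):
                beta, ll, score, info, cache = cand, ll_new, score_new, info_new, cache_new
                accepted = True
                break
            step *= 0.5
        n_iter += 1
        if not accepted:
            raise NonConvergence(
                "step-halving exhausted without improving the partial likelihood")
        if np.max(np.abs(beta)) > _DIVERGE_NORM:
            raise NonConvergence(
                "diverging coefficients: monotone likelihood / separation suspected")


def cox_fit(data: SurvivalDataset, w=None, ties: str = "efron",
            tol: float = 1e-9, max_iter: int = 100,
            weight_placement: str = "case", beta_init=None,
            compute_sandwich: bool = True) -> CoxFit:
    """Solve the weighted partial-likelihood score equation by Newton.

    Newton–Raphson with step-halving on the (concave) weighted log
    partial likelihood; convergence when the max-norm of the score is
    below `tol`. Raises :class:`NonConvergence` on diverging
    coefficients and :class:`SingularInformation` on collinearity.
    """
    require_valid(data)
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie method {ties!r}")
    ew, rw = _resolve_weights(data, w, weight_placement)
    sd = _Sorted(data, ew, rw)
    beta0 = (np.zeros(sd.p) if beta_init is None
             else np.atleast_1d(np.asarray(beta_init, dtype=float)).copy())
    beta, ll, info, cache, converged, n_iter, score_norm = _newton(
        sd, beta0, ties, tol, max_iter)
    if not converged:
        raise NonConvergence(
            f"no convergence in {max_iter} iterations (|score|={score_norm:.3g})")
    n = sd.n
    try:
        model_cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as e:
        raise SingularInformation("information matrix singular at the optimum") from e
    fit = CoxFit(
        beta_hat=beta, loglik=ll, info=info / n, meat=np.full((sd.p, sd.p), np.nan),
        model_cov=model_cov, sandwich_cov=np.full((sd.p, sd.p), np.nan),
        converged=True, n_iter=n_iter, score_norm=score_norm, ties=ties,
        weight_placement=weight_placement, covariate_names=list(data.covariate_names),
    )
    if compute_sandwich:
        fit.sandwich_cov = cox_sandwich(fit, data, w)
    return fit


def _score_residuals(fit: CoxFit, data: SurvivalDataset, w):
    """Per-subject weighted score residuals V_i at beta_hat.

    V_i = w_i delta_i {Z_i - Zbar(X_i)}
          - r_i exp(beta'Z_i) * sum_{events e: X_e <= X_i} w_e {Z_i - Zbar(X_e)} / S0(X_e)

    computed under the Breslow tie convention (tie groups have measure
    zero under continuous event times). The residuals sum to the score,
    which is 0 at beta_hat.
    """
    ew, rw = _resolve_weights(data, w, fit.weight_placement)
    sd = _Sorted(data, ew, rw)
    beta = fit.beta_hat
    _, _, _, cache = _breslow_parts(sd, beta)
    eta, m, S0, S1, Zbar, S0a = cache
    r = sd.rws * np.exp(eta - m)   # risk contribution on the m-shifted scale
    ev = sd.ev
    ew_ev = sd.ews[ev]
    # cumulative event-time functionals (ascending event order)
    q0 = ew_ev / S0a
    q1 = ew_ev[:, None] * Zbar / S0a[:, None]
    c0 = np.concatenate([[0.0], np.cumsum(q0)])
    c1 = np.concatenate([np.zeros((1, sd.p)), np.cumsum(q1, axis=0)])
    # number of event times <= each subject's exit time
    pos = np.searchsorted(sd.ts[ev], sd.ts, side="right")
    term_risk = r[:, None] * (sd.Zs * c0[pos][:, None] - c1[pos])
    V = -term_risk
    V[ev] += ew_ev[:, None] * (sd.Zs[ev] - Zbar)
    out = np.empty_like(V)
    out[sd.order] = V
    return out


def cox_sandwich(fit: CoxFit, data: SurvivalDataset, w=None) -> np.ndarray:
    """Model-robust covariance  A^-1 B A^-1 / n  of beta_hat.

    A-hat is the observed weighted information divided by n; B-hat the
    average outer product of the per-subject score residuals. Valid as
    the variance of the least-false-parameter estimator whether or not
    the proportional-hazards model (or the weighting) is correct.
    """
    V = _score_residuals(fit, data, w)
    n = data.n
    meat = (V.T @ V) / n
    fit.meat = meat
    A = fit.info
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as e:
        raise SingularInformation("information matrix singular") from e
    return Ainv @ meat @ Ainv / n


def breslow_baseline(fit: CoxFit, data: SurvivalDataset, w=None) -> StepFunction:
    """Aalen–Breslow baseline cumulative hazard at beta_hat.

    ``Lambda0(t) = sum_{events e: X_e <= t} w_e / S0(beta_hat, X_e)``;
    reduces to (weighted) Nelson–Aalen at beta_hat = 0.
    """
    ew, rw = _resolve_weights(data, w, fit.weight_placement)
    sd = _Sorted(data, ew, rw)
    eta = sd.Zs @ fit.beta_hat
    m = eta.max()
    r = sd.rws * np.exp(eta - m)
    S0 = _suffix_cumsum(r)
    ev = sd.ev
    S0_ev = S0[sd.a_ev] * np.exp(m)
    if np.any((S0_ev <= 0) & (sd.ews[ev] > 0)):
        raise ZeroDivisionError("empty weighted risk set at an event time")
    jumps = np.where(sd.ews[ev] > 0, sd.ews[ev] / np.where(S0_ev > 0, S0_ev, 1.0), 0.0)
    t_ev = sd.ts[ev]
    uniq, inv = np.unique(t_ev, return_inverse=True)
    agg = np.zeros_like(uniq)
    np.add.at(agg, inv, jumps)
    return StepFunction(uniq, np.cumsum(agg))


# ---------------------------------------------------------------------------
# batched Breslow Newton (used by the perturbation resampler)
# ---------------------------------------------------------------------------

def _batched_breslow_newton(sd: _Sorted, EW, RW, beta0, tol=1e-9, max_iter=50,
                            chunk_floats=2.5e7):
    """Solve B weighted partial-likelihood problems simultaneously.

    EW/RW are (B, n) event/risk weight matrices in *sorted* row order;
    all problems share the design. Breslow ties only. Returns
    (betas (B,p), ok (B,) bool). Non-converged or diverging draws are
    flagged, not raised.
    """
    B, n = EW.shape
    p = sd.p
    Zs = sd.Zs
    ev, a_ev = sd.ev, sd.a_ev
    betas = np.tile(np.atleast_1d(beta0).astype(float), (B, 1))
    tol_b = tol * np.maximum(EW[:, ev].sum(axis=1), 1e-100)   # per-draw scale
    ok = np.ones(B, dtype=bool)
    done = np.zeros(B, dtype=bool)
    chunk = max(1, int(chunk_floats / (n * p * p + n * p + 3 * n)))
    Zev = Zs[ev]

    def parts(idx, bet):
        eta = bet @ Zs.T                        # (b, n)
        m = eta.max(axis=1, keepdims=True)
        r = RW[idx] * np.exp(eta - m)
        S0 = _suffix_cumsum(r, axis=1)
        S1 = _suffix_cumsum(r[:, :, None] * Zs[None], axis=1)
        S2 = _suffix_cumsum(r[:, :, None, None] * (Zs[:, :, None] * Zs[:, None, :])[None], axis=1)
        ewv = EW[idx][:, ev]
        S0a = S0[:, a_ev]
        bad = S0a <= 0
        S0a = np.where(bad, 1.0, S0a)
        Zbar = S1[:, a_ev] / S0a[:, :, None]
        ll = np.sum(np.where(ewv > 0, ewv * (eta[:, ev] - m - np.log(S0a)), 0.0), axis=1)
        sc = np.einsum("be,bej->bj", ewv, Zev[None] - Zbar)
        S2n = S2[:, a_ev] / S0a[:, :, None, None]
        info = np.einsum("be,bejk->bjk", ewv,
                         S2n - Zbar[:, :, :, None] * Zbar[:, :, None, :])
        return ll, sc, info

    for lo in range(0, B, chunk):
        idx = np.arange(lo, min(lo + chunk, B))
        bet = betas[idx].copy()
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            ll, sc, info = parts(idx, bet)
        alive = np.ones(idx.size, dtype=bool)
        for _ in range(max_iter):
            scn = np.max(np.abs(sc), axis=1)
            alive &= ~(scn <= tol_b[idx])
            alive &= np.all(np.isfinite(bet), axis=1)
            if not alive.any():
                break
            try:
                step = np.linalg.solve(info[alive], sc[alive][..., None])[..., 0]
            except np.linalg.LinAlgError:
                # some draw has a singular information matrix: drop those
                cond = np.linalg.cond(info[alive])
                sing = ~np.isfinite(cond) | (cond > 1e14)
                ok[idx[alive][sing]] = False
                alive[np.flatnonzero(alive)[sing]] = False
                if not alive.any():
                    break
                step = np.linalg.solve(info[alive], sc[alive][..., None])[..., 0]
            cand = bet[alive] + step
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                sub = idx[alive]
                llc, scc, infoc = parts(sub, cand)
            # step-halving where the objective decreased or went non-finite
            for _h in range(_MAX_HALVINGS):
                slack = 1e-10 * (1.0 + np.abs(ll[alive]))
                worse = ~(llc >= ll[alive] - slack) | ~np.isfinite(llc)
                if not worse.any():
                    break
                step[worse] *= 0.5
                cand = bet[alive] + step
                with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                    llc, scc, infoc = parts(idx[alive], cand)
            bet[alive] = cand
            ll[alive], sc[alive], info[alive] = llc, scc, infoc
            diverged = np.max(np.abs(bet), axis=1) > _DIVERGE_NORM
            if diverged.any():
                ok[idx[diverged]] = False
                alive &= ~diverged
        scn = np.max(np.abs(sc), axis=1)
        ok[idx] &= (scn <= tol_b[idx]) & np.all(np.isfinite(bet), axis=1)
        betas[idx] = bet
    return betas, ok
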