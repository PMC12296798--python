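"""Independent brute-force reference implementations used as test oracles.

Everything here is written from the defining formulas with explicit
loops and boolean masks — deliberately sharing no code path with the
package — so agreement between the two is informative.
"""

import numpy as np


def naive_cox_loglik(beta, times, events, Z, w, risk_w=None):
    """Weighted log partial likelihood (Breslow, case weights), by loops."""
    beta = np.atleast_1d(beta)
    if risk_w is None:
        risk_w = w
    eta = Z @ beta
    ll = 0.0
    for i in range(len(times)):
        if events[i] != 1 or w[i] == 0:
            continue
        at_risk = times >= times[i]
        ll += w[i] * (eta[i] - np.log(np.sum(risk_w[at_risk] * np.exp(eta[at_risk]))))
    return ll


def naive_cox_score(beta, times, events, Z, w, risk_w=None):
    beta = np.atleast_1d(beta)
    if risk_w is None:
        risk_w = w
    eta = Z @ beta
    p = Z.shape[1]
    score = np.zeros(p)
    for i in range(len(times)):
        if events[i] != 1:
            continue
        at_risk = times >= times[i]
        rr = risk_w[at_risk] * np.exp(eta[at_risk])
        zbar = (rr[:, None] * Z[at_risk]).sum(axis=0) / rr.sum()
        score += w[i] * (Z[i] - zbar)
    return score


def grid_search_cox(times, events, Z, w, lo=-5.0, hi=5.0, step=1e-4):
    """1-d maximizer of the weighted log partial likelihood on a grid."""
    grid = np.arange(lo, hi + step / 2, step)
    eta = np.outer(grid, Z[:, 0])                      # (G, n)
    ll = np.zeros(grid.size)
    for i in range(len(times)):
        if events[i] != 1 or w[i] == 0:
            continue
        at_risk = times >= times[i]
        rr = w[at_risk][None, :] * np.exp(eta[:, at_risk])
        ll += w[i] * (eta[:, i] - np.log(rr.sum(axis=1)))
    return grid[np.argmax(ll)]


def naive_additive_U1(alpha, times, events, Z, w, tau=None):
    """Additive estimating function by direct interval-by-interval sums."""
    alpha = np.atleast_1d(alpha)
    if tau is None:
        tau = times.max()
    p = Z.shape[1]

    def zbar(t):
        at_risk = times >= t
        denom = w[at_risk].sum()
        return (w[at_risk, None] * Z[at_risk]).sum(axis=0) / denom

    U = np.zeros(p)
    for i in range(len(times)):
        if events[i] == 1 and times[i] <= tau:
            U += w[i] * (Z[i] - zbar(times[i]))
    # drift term: piecewise-constant risk sets between sorted exit times
    knots = np.concatenate([[0.0], np.sort(np.unique(np.minimum(times, tau)))])
    for k in range(1, len(knots)):
        t_lo, t_hi = knots[k - 1], knots[k]
        if t_hi <= t_lo:
            continue
        zb = zbar(t_hi)             # value of Zbar on (t_lo, t_hi]
        for i in range(len(times)):
            if times[i] >= t_hi:
                U -= w[i] * (Z[i] - zb) * (alpha @ Z[i]) * (t_hi - t_lo)
    return U


def bisect_additive(times, events, Z, w, lo=-10.0, hi=10.0, tol=1e-10):
    """1-d root of the additive estimating function by bisection."""
    f_lo = naive_additive_U1(lo, times, events, Z, w)[0]
    f_hi = naive_additive_U1(hi, times, events, Z, w)[0]
    assert f_lo * f_hi < 0, "root not bracketed"
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = naive_additive_U1(mid, times, events, Z, w)[0]
        if f_lo * f_mid <= 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def naive_nelson_aalen(times, events, w=None):
    """Weighted Nelson–Aalen estimator as (event_times, cumhaz) arrays."""
    if w is None:
        w = np.ones_like(times, dtype=float)
    ev_times = np.unique(times[events == 1])
    vals = []
    cum = 0.0
    for t in ev_times:
        dN = w[(times == t) & (events == 1)].sum()
        Y = w[times >= t].sum()
        cum += dN / Y
        vals.append(cum)
    return ev_times, np.array(vals)


def random_small_instance(rng, n_max=8, ensure_additive=False):
    """A random tiny survival dataset with positive weights.

    Guarantees at least one event and (optionally) covariate variation
    so the additive dispersion matrix is nonsingular.
    """
    while True:
        n = rng.integers(3, n_max + 1)
        times = np.round(rng.exponential(1.0, n), 3) + 1e-3
        events = rng.integers(0, 2, n)
        z = rng.normal(0, 1, (n, 1)).round(2)
        w = rng.uniform(0.2, 2.0, n).round(2)
        if events.sum() == 0:
            continue
        if ensure_additive and np.unique(z).size < 2:
            continue
        return times, events, z, w
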