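"""Data model for right-censored, per-subject-weighted survival data.

A subject contributes a follow-up time ``X = min(T, C)``, an event
indicator ``delta = I(T <= C)``, a covariate vector ``Z`` and a
non-negative analysis weight ``w`` (default 1, i.e. unweighted).
Estimators in :mod:`survweight.cox` and :mod:`survweight.additive`
consume the array-backed :class:`SurvivalDataset`.

Conventions
-----------
* Times are continuous, non-negative reals in whatever unit the caller
  supplies; no internal rescaling is performed.
* At tied times, events are processed before censorings leave the risk
  set: subject ``j`` is at risk at ``t`` iff ``X_j >= t``.
* Subjects with weight exactly 0 are retained structurally but
  contribute nothing to any estimating-equation sum (a warning is
  logged when such subjects are present).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidDataset

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalRecord",
    "SurvivalDataset",
    "RiskIndex",
    "validate_dataset",
    "risk_index",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject: follow-up time, event indicator, covariates, weight."""

    time: float
    event: int
    covariates: np.ndarray
    weight: float = 1.0

    def __post_init__(self):
        object.__setattr__(
            self, "covariates", np.atleast_1d(np.asarray(self.covariates, dtype=float))
        )


class SurvivalDataset:
    """Array-backed collection of :class:`SurvivalRecord`.

    Parameters
    ----------
    times, events, covariates, weights
        Arrays of shape ``(n,)``, ``(n,)``, ``(n, p)`` and ``(n,)``.
    covariate_names
        Optional labels of length ``p`` (default ``z1..zp``).
    tau
        Analysis horizon; estimating-equation integrals run over
        ``[0, tau]``. Defaults to the largest observed time.
    """

    def __init__(self, times, events, covariates, weights=None,
                 covariate_names=None, tau=None):
        self.times = np.asarray(times, dtype=float)
        self.events = np.asarray(events, dtype=int)
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        self.covariates = Z
        n = self.times.shape[0]
        if weights is None:
            weights = np.ones(n)
        self.weights = np.asarray(weights, dtype=float)
        p = self.covariates.shape[1]
        if covariate_names is None:
            covariate_names = [f"z{k + 1}" for k in range(p)]
        self.covariate_names = list(covariate_names)
        if tau is None:
            tau = float(self.times.max()) if n else 0.0
        self.tau = float(tau)
        if np.any(self.weights == 0):
            logger.warning(
                "%d subject(s) have weight exactly 0; they are retained but "
                "contribute nothing to any estimating-equation sum",
                int(np.sum(self.weights == 0)),
            )

    # -- constructors -------------------------------------------------
    @classmethod
    def from_records(cls, records, covariate_names=None, tau=None):
        records = list(records)
        times = [r.time for r in records]
        events = [r.event for r in records]
        Z = np.array([r.covariates for r in records], dtype=float)
        w = [r.weight for r in records]
        return cls(times, events, Z, w, covariate_names, tau)

    # -- basic protocol ----------------------------------------------
    @property
    def n(self) -> int:
        return self.times.shape[0]

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def __len__(self) -> int:
        return self.n

    def record(self, i: int) -> SurvivalRecord:
        return SurvivalRecord(
            float(self.times[i]), int(self.events[i]),
            self.covariates[i].copy(), float(self.weights[i]),
        )

    def subset(self, idx) -> "SurvivalDataset":
        """Row subset (used by block-jackknife oracles)."""
        return SurvivalDataset(
            self.times[idx], self.events[idx], self.covariates[idx],
            self.weights[idx], self.covariate_names, self.tau,
        )


@dataclass
class FitResult:
    """Common shape of a fitted regression (specialised by each model)."""

    estimate: np.ndarray
    model_cov: np.ndarray
    sandwich_cov: np.ndarray
    converged: bool
    n_iter: int
    score_norm: float


def validate_dataset(data: SurvivalDataset) -> list:
    """Check every structural invariant; return a list of violations.

    Returns an empty list iff the dataset is usable by the estimators:
    n >= 2, at least one event, finite non-negative times, binary event
    indicators, finite covariates, finite non-negative weights not all
    zero, and a positive horizon. Never raises, never mutates.
    """
    v = []
    n = data.n
    if n < 2:
        v.append("fewer than 2 records")
    t, d, Z, w = data.times, data.events, data.covariates, data.weights
    if not (d.shape[0] == n and Z.shape[0] == n and w.shape[0] == n):
        v.append("inconsistent array lengths")
        return v
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        v.append("non-finite or negative time")
    if not np.all(np.isin(d, (0, 1))):
        v.append("event indicator not in {0,1}")
    if d.sum() < 1:
        v.append("no events")
    if np.any(~np.isfinite(Z)):
        v.append("non-finite covariate")
    if np.any(~np.isfinite(w)):
        v.append("non-finite weight")
    if np.any(w < 0):
        v.append("negative weight")
    elif np.all(w == 0):
        v.append("all weights zero")
    if not (np.isfinite(data.tau) and data.tau > 0):
        v.append("non-positive horizon tau")
    return v


def require_valid(data: SurvivalDataset) -> None:
    problems = validate_dataset(data)
    if problems:
        raise InvalidDataset("; ".join(problems))


@dataclass
class RiskIndex:
    """Sorted distinct event times with at-risk and event subject sets.

    ``at_risk[k]`` lists the indices ``i`` with ``times[i] >=
    event_times[k]`` (ascending index order); ``event_subjects[k]``
    lists the subjects with an observed event exactly at
    ``event_times[k]``.
    """

    event_times: np.ndarray
    at_risk: list = field(repr=False)
    event_subjects: list = field(repr=False)


def risk_index(data: SurvivalDataset) -> RiskIndex:
    """Precompute risk sets at each distinct event time.

    Intended for small data and for test oracles; the estimators use
    sorted cumulative sums instead and never materialise risk sets.
    """
    require_valid(data)
    t, d = data.times, data.events
    ev_times = np.unique(t[d == 1])
    at_risk, ev_subj = [], []
    idx = np.arange(data.n)
    for s in ev_times:
        at_risk.append(idx[t >= s])
        ev_subj.append(idx[(t == s) & (d == 1)])
    return RiskIndex(ev_times, at_risk, ev_subj)
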