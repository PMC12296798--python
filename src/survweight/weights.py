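"""Subject-specific weights built from external risk-prediction output.

External information enters the analysis only through per-subject
predictions at a fixed horizon — either a predicted survival
probability ``S(h | Z)`` or a predicted cumulative hazard ``H(h | Z)``
— never as a model object. Two verbatim recipes are provided:

* :func:`weights_from_survival_prob` — use the predicted survival
  probability itself as the weight (the proportional-hazards-based
  recipe, e.g. predicted 5-year survival).
* :func:`weights_from_cumulative_hazard` — map the predicted cumulative
  hazard onto the event-probability scale, ``w = 1 - exp(-H)``, so that
  hazard-based weights (e.g. from a survival forest) live on the same
  [0, 1) scale as probability-based ones. The transform is a package
  choice; raw values can always be supplied with ``source="user"``.

Each constructor accepts ``complement=True`` to flip the direction
(``w -> 1 - w``), switching between up-weighting predicted survivors
and up-weighting predicted high-risk subjects.

Both weighted estimating equations are homogeneous of degree one in the
weights, so rescaling a weight vector by any positive constant (and in
particular :func:`normalize_weights`) leaves every point estimate
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "WeightVector",
    "weights_from_survival_prob",
    "weights_from_cumulative_hazard",
    "user_weights",
    "normalize_weights",
]

_SOURCES = ("survival_prob", "cumulative_hazard", "user")


@dataclass(frozen=True)
class WeightVector:
    """Non-negative per-subject weights with provenance."""

    values: np.ndarray
    source: str
    horizon: Optional[float] = None

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.source not in _SOURCES:
            raise ValueError(f"unknown weight source {self.source!r}")
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("weights must form a non-empty 1-d vector")
        if np.any(~np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError("weights must be finite and non-negative")
        if not np.any(vals > 0):
            raise ValueError("at least one weight must be positive")
        if self.horizon is not None and not self.horizon > 0:
            raise ValueError("horizon must be positive")

    def __len__(self):
        return self.values.size


def weights_from_survival_prob(surv_probs, horizon, complement: bool = False) -> WeightVector:
    """Weights equal to the predicted survival probability at `horizon`.

    With ``complement=True`` the weight is ``1 - S(h|Z)``, i.e. the
    predicted event probability, up-weighting high-risk subjects.
    """
    s = np.asarray(surv_probs, dtype=float)
    if np.any(~np.isfinite(s)) or np.any(s < 0) or np.any(s > 1):
        raise ValueError("survival probabilities must lie in [0, 1]")
    vals = 1.0 - s if complement else s
    return WeightVector(vals, "survival_prob", float(horizon))


def weights_from_cumulative_hazard(cum_haz, horizon, complement: bool = False) -> WeightVector:
    """Weights ``1 - exp(-H(h|Z))`` from a predicted cumulative hazard.

    Monotone increasing in ``H`` and bounded in [0, 1), so hazard-based
    weights are commensurable with survival-probability weights. With
    ``complement=True`` the weight is ``exp(-H)``, the implied survival
    probability.
    """
    h = np.asarray(cum_haz, dtype=float)
    if np.any(~np.isfinite(h)) or np.any(h < 0):
        raise ValueError("cumulative hazards must be finite and non-negative")
    risk = -np.expm1(-h)
    vals = 1.0 - risk if complement else risk
    return WeightVector(vals, "cumulative_hazard", float(horizon))


def user_weights(values, horizon=None) -> WeightVector:
    """Wrap user-supplied weights verbatim (source ``"user"``)."""
    return WeightVector(np.asarray(values, dtype=float), "user", horizon)


def normalize_weights(w: WeightVector) -> WeightVector:
    """Rescale to mean one (``w_i * n / sum(w)``).

    Point estimates are invariant to this rescaling; it only makes
    weight summaries comparable across weighting rules.
    """
    total = float(w.values.sum())
    if total == 0:
        raise ValueError("cannot normalize an all-zero weight vector")
    return WeightVector(w.values * (len(w) / total), w.source, w.horizon)
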