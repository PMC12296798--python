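"""Right-continuous step functions (baseline cumulative hazards)."""

from __future__ import annotations

import numpy as np


class StepFunction:
    """Right-continuous step function with value 0 before the first knot."""

    def __init__(self, x, y):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise ValueError("knots and values must be equal-length 1-d arrays")
        if np.any(np.diff(self.x) < 0):
            raise ValueError("knots must be non-decreasing")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.x, t, side="right") - 1
        out = np.where(idx >= 0, self.y[np.clip(idx, 0, None)], 0.0)
        return out if out.ndim else float(out)
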