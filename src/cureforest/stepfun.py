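"""Right-continuous nondecreasing step functions on [0, inf).

Used for Nelson-Aalen cumulative hazards, plug-in baseline hazards and leaf
cumulative-hazard curves.  Kept deliberately minimal: a sorted knot vector and
the value attained at (and after) each knot, with value 0 before the first knot.
"""

from __future__ import annotations

import numpy as np


class StepFunction:
    """``f(t) = y[k]`` for the largest ``k`` with ``x[k] <= t``; 0 before ``x[0]``.

    Parameters
    ----------
    x : array-like
        Strictly increasing knot locations (typically distinct event times).
    y : array-like
        Function values at the knots.  Must be the same length as ``x``.
    """

    __slots__ = ("x", "y")

    def __init__(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be 1-d arrays of equal length")
        if x.size and np.any(np.diff(x) <= 0):
            raise ValueError("knots must be strictly increasing")
        self.x = x
        self.y = y

    def __call__(self, t):
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("step functions are defined on t >= 0 only")
        idx = np.searchsorted(self.x, t_arr, side="right")
        vals = np.concatenate([[0.0], self.y])[idx]
        if np.isscalar(t) or t_arr.ndim == 0:
            return float(vals)
        return vals

    @property
    def terminal_value(self) -> float:
        return float(self.y[-1]) if self.y.size else 0.0

    def is_nondecreasing(self) -> bool:
        return bool(self.y.size == 0 or (self.y[0] >= 0 and np.all(np.diff(self.y) >= -1e-12)))

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"StepFunction(n_knots={self.x.size}, terminal={self.terminal_value:.4g})"
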