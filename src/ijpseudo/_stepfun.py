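"""Right-continuous step functions with left-limit queries.

All estimated curves in this package (at-risk averages, Nelson--Aalen
hazards, Kaplan--Meier / Aalen--Johansen curves, the entry-time
distribution) are piecewise-constant in time.  A :class:`StepFunction`
stores the jump times and the value attained *at and after* each jump;
evaluation is right-continuous and the left limit is available for the
``G(s-)`` / ``H(s)`` conventions of counting-process formulas.
"""

from __future__ import annotations

import numpy as np

__all__ = ["StepFunction"]


class StepFunction:
    """A right-continuous piecewise-constant function on [0, inf).

    Parameters
    ----------
    jump_times : array-like
        Strictly increasing jump locations.
    values : array-like
        Value at and immediately after each jump; ``values[k]`` is the
        function value on ``[jump_times[k], jump_times[k+1])``.
    initial_value : float, default 0.0
        Value on ``[0, jump_times[0])``.
    """

    __slots__ = ("x", "y", "y0")

    def __init__(self, jump_times, values, initial_value: float = 0.0):
        x = np.asarray(jump_times, dtype=float)
        y = np.asarray(values, dtype=float)
        if x.ndim != 1 or y.shape != x.shape:
            raise ValueError("jump_times and values must be 1-d and equal length")
        if x.size > 1 and not np.all(np.diff(x) > 0):
            raise ValueError("jump_times must be strictly increasing")
        self.x = x
        self.y = y
        self.y0 = float(initial_value)

    def __call__(self, s, side: str = "right"):
        """Evaluate at ``s``; ``side='left'`` returns the left limit."""
        s = np.asarray(s, dtype=float)
        if self.x.size == 0:
            out = np.full(s.shape, self.y0)
            return float(self.y0) if out.ndim == 0 else out
        if side == "right":
            idx = np.searchsorted(self.x, s, side="right") - 1
        elif side == "left":
            idx = np.searchsorted(self.x, s, side="left") - 1
        else:
            raise ValueError("side must be 'right' or 'left'")
        out = np.where(idx >= 0, self.y[np.clip(idx, 0, None)], self.y0)
        return float(out) if out.ndim == 0 else out

    def left(self, s):
        """Left limit ``f(s-)``; convenience alias for ``__call__(s, 'left')``."""
        return self(s, side="left")

    @property
    def jump_times(self):
        return self.x

    @property
    def values(self):
        return self.y

    @property
    def initial_value(self):
        return self.y0

    def to_frame(self):
        """Export as a two-column (time, value) table for plotting."""
        import pandas as pd

        return pd.DataFrame({"time": self.x, "value": self.y})

    def __repr__(self):  # pragma: no cover
        return (
            f"StepFunction({self.x.size} jumps, initial={self.y0:g}, "
            f"final={self.y[-1] if self.y.size else self.y0:g})"
        )
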