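"""Guinier-region linearity objective shared by buffer scaling and SVD-LC.

The Guinier law ln I = ln I(0) - (q R_G)^2 / 3 holds at low q; residual
buffer contamination curves the low-q region, so the straight-line misfit
of ln I vs q^2 over a self-consistent window (q R_G below the validity
limit) is the natural objective for "Guinier-optimized" reconstruction.
"""

from __future__ import annotations

import numpy as np

_PENALTY = 1e3


def guinier_window(
    q: np.ndarray,
    I: np.ndarray,
    srg_limit: float = 1.3,
    n_start: int = 25,
    min_points: int = 8,
) -> int:
    """Self-consistent Guinier window size: the number of leading points
    with q * R_G below ``srg_limit`` for the R_G of the curve itself."""
    n = min(max(n_start, min_points), q.size)
    for _ in range(30):
        qq, II = q[:n], I[:n]
        good = II > 0
        if good.sum() < min_points:
            return n
        slope, _ = np.polyfit(qq[good] ** 2, np.log(II[good]), 1)
        if slope >= 0:
            return n
        rg = np.sqrt(-3.0 * slope)
        n_new = int(np.searchsorted(q, srg_limit / rg, side="right"))
        n_new = min(max(n_new, min_points), q.size)
        if n_new == n:
            return n
        n = n_new
    return n


def guinier_linearity_cost(
    q: np.ndarray,
    I: np.ndarray,
    srg_limit: float = 1.3,
    n_start: int = 25,
    fixed_window: int | None = None,
) -> float:
    """Mean squared residual of a line fit of ln I vs q^2 over the Guinier
    window.

    The window is fixed by the caller (``fixed_window``) or chosen
    self-consistently for the candidate curve.  A fixed window keeps the
    objective comparable across candidate curves during optimization;
    otherwise a candidate could shrink its own window to a handful of
    points and look spuriously linear.  Non-positive intensities inside
    the window and non-negative slopes (no Guinier decay) are penalized.
    """
    n = fixed_window if fixed_window is not None else guinier_window(
        q, I, srg_limit, n_start)
    n = min(max(n, 5), q.size)
    qq, II = q[:n], I[:n]
    n_bad = int(np.sum(II <= 0))
    if n_bad:
        return _PENALTY * (1 + n_bad)
    x = qq**2
    y = np.log(II)
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0:
        return _PENALTY
    resid = y - (slope * x + intercept)
    return float(np.mean(resid**2))
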