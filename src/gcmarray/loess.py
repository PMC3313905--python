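"""Robust local polynomial regression (loess) on a single predictor.

Local weighted least squares with a tricube kernel over the ``span``
fraction of nearest neighbours, optionally re-weighted with bisquare
robustness weights.  A quadratic local model is the default because the
normalization stage removes curvature from M-A scatter-plots; an exact
polynomial of degree <= ``degree`` is reproduced to machine precision.
"""

from __future__ import annotations

import numpy as np

__all__ = ["loess_fit"]


def _window_bounds(x_sorted: np.ndarray, q: int) -> np.ndarray:
    """For each index i, the start of the q nearest neighbours of x[i].

    x_sorted must be ascending; nearest-q windows are contiguous in rank,
    so a single monotone sweep suffices.
    """
    n = x_sorted.size
    lo = np.empty(n, dtype=np.intp)
    cur = 0
    for i in range(n):
        if cur > i:  # window must contain i
            cur = i
        hi = cur + q  # exclusive
        # slide right while the next point is closer than the current leftmost
        while hi < n and cur < i and (
            x_sorted[hi] - x_sorted[i] < x_sorted[i] - x_sorted[cur]
        ):
            cur += 1
            hi += 1
        lo[i] = cur
    return lo


def _fit_pass(
    x: np.ndarray,
    y: np.ndarray,
    lo: np.ndarray,
    q: int,
    degree: int,
    robust_w: np.ndarray,
) -> np.ndarray:
    n = x.size
    fitted = np.empty(n)
    for i in range(n):
        sl = slice(lo[i], lo[i] + q)
        xw = x[sl]
        yw = y[sl]
        d = np.abs(xw - x[i])
        h = d.max()
        if h > 0:
            w = (1.0 - np.clip(d / h, 0.0, 1.0) ** 3) ** 3
        else:
            w = np.ones_like(d)
        w = w * robust_w[sl]
        if w.sum() <= 0:  # all points down-weighted to zero; fall back
            w = np.ones_like(d)
        xc = xw - x[i]  # center for conditioning
        V = np.vander(xc, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(V * sw[:, None], yw * sw, rcond=None)
        fitted[i] = coef[0]
    return fitted


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.3,
    degree: int = 2,
    robust_iterations: int = 4,
) -> np.ndarray:
    """Fitted loess values at every observation, in input order.

    Parameters
    ----------
    x, y
        Predictor and response; NaN pairs are ignored for fitting and
        yield NaN fitted values.
    span
        Fraction of points in each local window, in (0, 1].
    degree
        Local polynomial degree (1 = local linear, 2 = local quadratic).
    robust_iterations
        Number of bisquare re-weighting passes after the initial fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if not (0.0 < span <= 1.0):
        raise ValueError(f"span must be in (0, 1], got {span}")

    valid = np.isfinite(x) & np.isfinite(y)
    out = np.full(x.shape, np.nan)
    n = int(valid.sum())
    min_pts = degree + 1
    q = int(np.ceil(span * n))
    if q < min_pts:
        raise ValueError(
            f"loess window of {q} points is too small for a degree-{degree} "
            f"local fit ({min_pts} required); increase span (got {span})"
        )
    q = min(q, n)

    order = np.argsort(x[valid], kind="stable")
    xs = x[valid][order]
    ys = y[valid][order]
    lo = _window_bounds(xs, q)

    robust_w = np.ones(n)
    fitted = _fit_pass(xs, ys, lo, q, degree, robust_w)
    for _ in range(robust_iterations):
        resid = ys - fitted
        s = np.median(np.abs(resid))
        if s <= 0:
            break  # perfect fit; nothing to robustify
        u = resid / (6.0 * s)
        robust_w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        fitted = _fit_pass(xs, ys, lo, q, degree, robust_w)

    dest = np.flatnonzero(valid)[order]
    out[dest] = fitted
    return out
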