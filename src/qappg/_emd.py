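"""Empirical mode decomposition by classic envelope sifting.

Implements the standard algorithm: cubic-spline upper/lower envelopes through
local extrema (with mirrored end extrema to tame boundary splines), iterative
mean-envelope subtraction with a Cauchy-style stopping criterion, and
extraction of intrinsic mode functions until the residual is monotonic.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import argrelextrema

MAX_IMFS = 12
MAX_SIFTS = 100
SD_STOP = 0.05


def _extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    maxima = argrelextrema(x, np.greater_equal, order=1)[0]
    minima = argrelextrema(x, np.less_equal, order=1)[0]
    # greater_equal flags plateaus at every sample; keep plateau starts only
    if maxima.size:
        maxima = maxima[np.insert(np.diff(maxima) > 1, 0, True)]
    if minima.size:
        minima = minima[np.insert(np.diff(minima) > 1, 0, True)]
    return maxima, minima


def _envelope(idx: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Cubic spline through (idx, x[idx]) with two extrema mirrored per end."""
    n = x.size
    xi = idx.astype(float)
    yi = x[idx]
    k = min(2, xi.size)
    pre_x = -xi[:k][::-1]
    pre_y = yi[:k][::-1]
    post_x = 2 * (n - 1) - xi[-k:][::-1]
    post_y = yi[-k:][::-1]
    if pre_x[-1] >= xi[0]:  # extremum exactly at sample 0
        pre_x = pre_x - 1.0
    if post_x[0] <= xi[-1]:
        post_x = post_x + 1.0
    xs = np.concatenate([pre_x, xi, post_x])
    ys = np.concatenate([pre_y, yi, post_y])
    order = np.argsort(xs)
    xs, ys = xs[order], ys[order]
    keep = np.insert(np.diff(xs) > 0, 0, True)
    return CubicSpline(xs[keep], ys[keep])(np.arange(n))


def emd(x: np.ndarray, max_imfs: int = MAX_IMFS) -> list[np.ndarray]:
    """Decompose ``x`` into IMFs plus a final residual (last list element).

    The components sum exactly to the input.
    """
    x = np.asarray(x, dtype=float)
    residual = x.copy()
    imfs: list[np.ndarray] = []
    for _ in range(max_imfs):
        maxima, minima = _extrema(residual)
        if maxima.size < 2 or minima.size < 2:
            break
        h = residual.copy()
        for _ in range(MAX_SIFTS):
            mx, mn = _extrema(h)
            if mx.size < 2 or mn.size < 2:
                break
            mean_env = 0.5 * (_envelope(mx, h) + _envelope(mn, h))
            h_new = h - mean_env
            denom = np.sum(h ** 2)
            sd = np.sum(mean_env ** 2) / denom if denom > 0 else 0.0
            h = h_new
            if sd < SD_STOP:
                break
        imfs.append(h)
        residual = residual - h
    imfs.append(residual)
    return imfs
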