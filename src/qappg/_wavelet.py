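"""Minimal orthogonal discrete wavelet transform with periodic boundary.

Only what the wavelet-filtering algorithm needs: a multi-level analysis /
synthesis pair for the Daubechies-8 filter bank on dyadic-length signals.
The analysis operator at each level is orthogonal (rows are even circular
shifts of the low/high-pass filters), so synthesis is its transpose and
reconstruction is exact to machine precision.
"""

from __future__ import annotations

import numpy as np

# Daubechies-8 scaling (low-pass synthesis) coefficients; sum = sqrt(2),
# l2-norm = 1, 8 vanishing moments, 16 taps.
DB8_SCALING = np.array([
    0.05441584224308161,
    0.3128715909144659,
    0.6756307362980128,
    0.5853546836548691,
    -0.015829105256023893,
    -0.2840155429624281,
    0.00047248457399797254,
    0.128747426620186,
    -0.01736930100202211,
    -0.04408825393106472,
    0.013981027917015516,
    0.008746094047015655,
    -0.00487035299301066,
    -0.0003917403729959771,
    0.0006754494059985568,
    -0.00011747678400228192,
])


def _filters() -> tuple[np.ndarray, np.ndarray]:
    g = DB8_SCALING
    # quadrature-mirror high-pass: h[k] = (-1)^k g[L-1-k]
    h = ((-1.0) ** np.arange(g.size)) * g[::-1]
    return g, h


def _analysis_step(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One periodized decimating filter-bank step; len(x) must be even."""
    g, h = _filters()
    n = x.size
    L = g.size
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(L)[None, :]) % n
    windows = x[idx]
    return windows @ g, windows @ h


def _synthesis_step(a: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Transpose of :func:`_analysis_step` (exact inverse by orthogonality)."""
    g, h = _filters()
    n = 2 * a.size
    L = g.size
    x = np.zeros(n)
    idx = (2 * np.arange(a.size)[:, None] + np.arange(L)[None, :]) % n
    np.add.at(x, idx, a[:, None] * g[None, :])
    np.add.at(x, idx, d[:, None] * h[None, :])
    return x


def wavedec(x: np.ndarray, levels: int) -> list[np.ndarray]:
    """Multi-level DWT -> [approx, detail_L, detail_{L-1}, ..., detail_1]."""
    x = np.asarray(x, dtype=float)
    if x.size % (2 ** levels):
        raise ValueError(f"signal length {x.size} not divisible by 2^{levels}")
    details = []
    a = x
    for _ in range(levels):
        a, d = _analysis_step(a)
        details.append(d)
    return [a] + details[::-1]


def waverec(coeffs: list[np.ndarray]) -> np.ndarray:
    """Inverse of :func:`wavedec`."""
    a = coeffs[0]
    for d in coeffs[1:]:
        a = _synthesis_step(a, d)
    return a
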