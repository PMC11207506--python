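"""Shared periodogram helpers (mean-removed, one-sided, Parseval-exact)."""

from __future__ import annotations

import numpy as np


def power_spectrum(x: np.ndarray, fs: float, nfft: int | None = None):
    """One-sided power-per-bin spectrum of the mean-removed signal.

    Returns ``(freqs, power)`` scaled so that ``power.sum()`` equals the mean
    square of the mean-removed signal exactly (Parseval) when ``nfft`` is the
    signal length.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if nfft is None:
        nfft = n
    xc = x - x.mean()
    spec = np.fft.rfft(xc, n=nfft)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    power = np.abs(spec) ** 2 / (n * nfft)
    scale = np.full(freqs.size, 2.0)
    scale[0] = 1.0
    if nfft % 2 == 0:
        scale[-1] = 1.0
    return freqs, power * scale


def dominant_frequency(x: np.ndarray, fs: float, nfft: int = 4096) -> float:
    """Frequency of the largest non-DC periodogram bin (zero-padded grid)."""
    x = np.asarray(x, dtype=float)
    nfft = max(nfft, x.size)
    freqs, power = power_spectrum(x, fs, nfft=nfft)
    if power[1:].sum() == 0:
        return 0.0
    return float(freqs[1 + np.argmax(power[1:])])


def band_power(freqs: np.ndarray, power: np.ndarray, lo: float, hi: float) -> float:
    """Sum of bins with ``lo <= f < hi`` (half-open, DC always excluded)."""
    mask = (freqs >= lo) & (freqs < hi) & (freqs > 0)
    return float(power[mask].sum())
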