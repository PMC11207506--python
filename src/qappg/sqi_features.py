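"""The 14 signal-quality indices computed from a raw PPG segment.

Six amplitude statistics (median, range, population std, skewness, excess
kurtosis, 16-bin histogram Shannon entropy) and eight spectral quantities
taken from the mean-removed, un-padded one-sided periodogram: point PSD at
1/3/5/7 Hz (nearest bin), band powers over [0.01, 1) and [1, 3) Hz, their
ratio, and the standard deviation of the magnitude spectrum.

Features are extracted from the RAW segment — quality assessment precedes any
processing.  A constant segment yields an undefined PSD ratio; the sentinel
NaN routes such segments to DISCARD downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._spectral import band_power, power_spectrum
from .core_io import Segment
from .errors import ContractError

__all__ = ["FEATURE_NAMES", "extract_sqi", "feature_matrix"]

#: Fixed column order — part of the trained-model contract.
FEATURE_NAMES = (
    "median",
    "range",
    "std",
    "kurtosis",
    "skewness",
    "entropy",
    "psd_1hz",
    "psd_3hz",
    "psd_5hz",
    "psd_7hz",
    "psd_001_1hz",
    "psd_1_3hz",
    "psd_ratio",
    "std_spectrum",
)

ENTROPY_BINS = 16


def _histogram_entropy(x: np.ndarray, bins: int = ENTROPY_BINS) -> float:
    # Shannon entropy (nats) of an equal-width amplitude histogram;
    # empty bins contribute zero.
    if np.ptp(x) == 0:
        return 0.0
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / x.size
    return float(-(p * np.log(p)).sum())


def extract_sqi(seg: Segment, entropy_bins: int = ENTROPY_BINS) -> dict[str, float]:
    """All 14 quality indices for one segment, keyed by :data:`FEATURE_NAMES`."""
    x = seg.samples
    out: dict[str, float] = {
        "median": float(np.median(x)),
        "range": float(np.ptp(x)),
        "std": float(np.std(x)) if np.ptp(x) > 0 else 0.0,
        "kurtosis": float(stats.kurtosis(x)) if np.ptp(x) > 0 else 0.0,
        "skewness": float(stats.skew(x)) if np.ptp(x) > 0 else 0.0,
        "entropy": _histogram_entropy(x, entropy_bins),
    }
    freqs, power = power_spectrum(x, seg.fs)  # un-padded grid
    for f0 in (1.0, 3.0, 5.0, 7.0):
        k = int(np.argmin(np.abs(freqs - f0)))
        out[f"psd_{int(f0)}hz"] = float(power[k])
    out["psd_001_1hz"] = band_power(freqs, power, 0.01, 1.0)
    out["psd_1_3hz"] = band_power(freqs, power, 1.0, 3.0)
    out["psd_ratio"] = (
        out["psd_1_3hz"] / out["psd_001_1hz"] if out["psd_001_1hz"] > 0 else float("nan")
    )
    mag = np.abs(np.fft.rfft(x - x.mean()))[1:]  # non-DC bins up to Nyquist
    out["std_spectrum"] = float(np.std(mag))
    return out


def feature_matrix(segs) -> pd.DataFrame:
    """Row per segment, columns in :data:`FEATURE_NAMES` order."""
    segs = list(segs)
    if not segs:
        raise ContractError("feature_matrix requires at least one segment")
    rows = [extract_sqi(s) for s in segs]
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES))
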