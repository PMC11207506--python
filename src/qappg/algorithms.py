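"""Pool of nine candidate segment-processing algorithms.

Two families: static filters (band/low/high-pass Butterworth, applied
forward-backward so they are zero-phase) and decomposition methods (cubic
spline baseline removal, db8 wavelet filtering, rank-2 SVD of the STFT,
empirical mode decomposition, singular spectrum analysis), plus a bypass.
Every algorithm maps a segment to a processed segment of identical length.

Per-segment energy costs are declarative configuration (measured on the
reference hardware, not re-measured here) and drive the portfolio budget
logic downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt, find_peaks, istft, stft

from ._emd import emd
from ._spectral import dominant_frequency
from ._wavelet import wavedec, waverec
from .core_io import Segment
from .errors import ConfigurationError, DegenerateInputError

__all__ = ["AlgorithmSpec", "apply", "list_pool", "DEFAULT_ENERGY_MJ", "ALGORITHM_IDS"]

ALGORITHM_IDS = ("BYPASS", "BPF", "LPF", "HPF", "CUB", "WVL", "SVDTFD", "EMD", "SSA")

#: Per-segment energy in mJ as measured on the reference platform.
DEFAULT_ENERGY_MJ = {
    "BYPASS": 0.0,
    "BPF": 10.05,
    "EMD": 2268.50,
    "CUB": 10.85,
    "SSA": 28767.42,
    "WVL": 9.73,
    "SVDTFD": 333.03,
    "HPF": 14.57,
    "LPF": 10.28,
}

_DEFAULT_PARAMS = {
    "BYPASS": {},
    "BPF": {"order": 5, "band_hz": (0.5, 15.0)},
    "LPF": {"order": 5, "cutoff_hz": 2.5},
    "HPF": {"order": 5, "cutoff_hz": 0.5},
    "CUB": {"min_trough_spacing_s": 0.46},
    "WVL": {"levels": 6},
    "SVDTFD": {"window_s": 2.0, "overlap": 0.75, "rank": 2},
    "EMD": {"cutoff_hz": 0.25, "direction": "below", "criterion": "dominant"},
    "SSA": {
        "window": 200,
        "cutoff_hz": 1.0,
        "direction": "below",
        "criterion": "dominant",
        "retain_band_hz": (0.83, 2.16),
    },
}

_CATEGORY = {
    "BYPASS": "bypass",
    "BPF": "filter",
    "LPF": "filter",
    "HPF": "filter",
    "CUB": "decompose",
    "WVL": "decompose",
    "SVDTFD": "decompose",
    "EMD": "decompose",
    "SSA": "decompose",
}


@dataclass(frozen=True)
class AlgorithmSpec:
    """One processing algorithm: identity, parameters and energy cost."""

    id: str
    category: str = ""
    params: dict = field(default_factory=dict)
    energy_mJ: float = 0.0

    def __post_init__(self) -> None:
        if self.id not in ALGORITHM_IDS:
            raise ConfigurationError(f"unknown algorithm id {self.id!r}")
        if self.energy_mJ < 0:
            raise ConfigurationError("energy_mJ must be >= 0")
        if self.id == "BYPASS" and self.energy_mJ != 0:
            raise ConfigurationError("BYPASS must have zero energy")
        if not self.category:
            object.__setattr__(self, "category", _CATEGORY[self.id])
        if not self.params:
            object.__setattr__(self, "params", dict(_DEFAULT_PARAMS[self.id]))


def list_pool(energy_overrides: dict[str, float] | None = None,
              param_overrides: dict[str, dict] | None = None) -> list[AlgorithmSpec]:
    """The nine default algorithm specs, stably ordered by id."""
    energies = dict(DEFAULT_ENERGY_MJ)
    if energy_overrides:
        unknown = set(energy_overrides) - set(ALGORITHM_IDS)
        if unknown:
            raise ConfigurationError(f"energy override for unknown ids: {sorted(unknown)}")
        energies.update(energy_overrides)
    pool = []
    for aid in ALGORITHM_IDS:
        params = dict(_DEFAULT_PARAMS[aid])
        if param_overrides and aid in param_overrides:
            params.update(param_overrides[aid])
        pool.append(AlgorithmSpec(id=aid, params=params, energy_mJ=energies[aid]))
    return pool


def get_spec(aid: str, pool: list[AlgorithmSpec] | None = None) -> AlgorithmSpec:
    for spec in pool if pool is not None else list_pool():
        if spec.id == aid:
            return spec
    raise ConfigurationError(f"algorithm {aid!r} not in pool")


# ---------------------------------------------------------------------------
# individual algorithms; each takes/returns a bare sample array


def _butter_sos(order: int, Wn, btype: str, fs: float):
    return butter(order, Wn, btype=btype, fs=fs, output="ba")


def _zero_phase(x: np.ndarray, b, a) -> np.ndarray:
    padlen = 3 * (max(len(a), len(b)) - 1)
    if x.size <= padlen:
        raise DegenerateInputError(
            f"segment of {x.size} samples too short for filter warm-up ({padlen})"
        )
    return filtfilt(b, a, x)


def _bpf(x: np.ndarray, fs: float, p: dict) -> np.ndarray:
    b, a = _butter_sos(p["order"], p["band_hz"], "bandpass", fs)
    return _zero_phase(x, b, a)


def _lpf(x: np.ndarray, fs: float, p: dict) -> np.ndarray:
    b, a = _butter_sos(p["order"], p["cutoff_hz"], "lowpass", fs)
    return _zero_phase(x, b, a)


def _hpf(x: np.ndarray, fs: float, p: dict) -> np.ndarray:
    b, a = _butter_sos(p["order"], p["cutoff_hz"], "highpass", fs)
    return _zero_phase(x, b, a)


def _cub(x: np.ndarray, fs: float, p: dict) -> np.ndarray:
    """Baseline removal: cubic spline through pulse troughs, subtracted."""
    spacing = int(round(p["min_trough_spacing_s"] * fs))
    troughs, _ = find_peaks(-x, distance=max(spacing, 1))
    if troughs.size < 2:
        return x - np.median(x)
    ti = troughs.astype(float)
    yi = x[troughs]
    xs = np.concatenate([[-1.0 if ti[0] == 0 else -ti[0]], ti,
                         [x.size if ti[-1] == x.size - 1 else 2 * (x.size - 1) - ti[-1]]])
    ys = np.concatenate([[yi[0]], yi, [yi[-1]]])
    baseline = CubicSpline(xs, ys)(np.arange(x.size))
    return x - baseline


def _wvl(x: np.ndarray, fs: float, p: dict) -> np.ndarray:
    """db8 decomposition; drop the approximation (baseline) and the finest
    detail band (high-frequency noise), reconstruct."""
    levels = p["levels"]
    n = x.size
    block = 2 ** levels
    pad = (-n) % block
    if pad:
        x_p = np.concatenate([x, x[-2 : -2 - pad : -1]])  # reflect tail
    else:
        x_p = x
    coeffs = wavedec(x_p, levels)
    coeffs[0] = np.zeros_like(coeffs[0])   # approximation: < fs / 2^(levels+1)
    coeffs[-1] = np.zeros_like(coeffs[-1])  # finest detail: > fs/4
    y = waverec(coeffs)
    return y[:n]


def _svdtfd(x: np.ndarray, fs: float, p: dict) -> np.ndarray:
    """Rank-limited SVD truncation of the complex STFT, inverse by overlap-add."""
    nperseg = int(round(p["window_s"] * fs))
    noverlap = int(round(p["overlap"] * nperseg))
    mean = x.mean()
    f, t, Z = stft(x - mean, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap)
    U, s, Vh = np.linalg.svd(Z, full_matrices=False)
    k = p["rank"]
    Zk = (U[:, :k] * s[:k]) @ Vh[:k, :]
    _, y = istft(Zk, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap)
    if y.size < x.size:
        y = np.pad(y, (0, x.size - y.size), mode="edge")
    return y[: x.size] + mean


def _component_keep(dom_freq: float, p: dict) -> bool:
    cutoff = p["cutoff_hz"]
    removed = dom_freq < cutoff if p.get("direction", "below") == "below" else dom_freq > cutoff
    if removed and "retain_band_hz" in p:
        lo, hi = p["retain_band_hz"]
        if lo <= dom_freq <= hi:
            return True
    return not removed


def _emd_filter(x: np.ndarray, fs: float, p: dict) -> np.ndarray:
    comps = emd(x)
    keep = [c for c in comps if _component_keep(dominant_frequency(c, fs), p)]
    if not keep:
        return np.zeros_like(x)
    return np.sum(keep, axis=0)


def _ssa(x: np.ndarray, fs: float, p: dict) -> np.ndarray:
    """Singular spectrum analysis: embed, SVD, drop low-frequency eigentriples,
    reconstruct by diagonal averaging."""
    L = int(p["window"])
    n = x.size
    if n < 2 * L:
        raise DegenerateInputError(f"SSA needs >= {2 * L} samples, got {n}")
    K = n - L + 1
    mean = x.mean()
    xc = x - mean
    idx = np.arange(L)[:, None] + np.arange(K)[None, :]
    X = xc[idx]  # trajectory matrix, L x K
    U, s, Vh = np.linalg.svd(X, full_matrices=False)
    # keep eigentriples whose temporal pattern is not low-frequency
    keep = np.zeros(s.size, dtype=bool)
    total = np.sum(s ** 2)
    cum = 0.0
    for i in range(s.size):
        if total > 0 and cum / total > 0.9999:
            break  # remaining components are numerically negligible
        cum += s[i] ** 2
        keep[i] = _component_keep(dominant_frequency(U[:, i], fs), p)
    if not keep.any():
        return np.full_like(x, mean)
    Xk = (U[:, keep] * s[keep]) @ Vh[keep, :]
    # diagonal (anti-diagonal) averaging back to a series
    sums = np.zeros(n)
    counts = np.zeros(n)
    anti = idx  # element (i, j) contributes to sample i + j
    np.add.at(sums, anti, Xk)
    np.add.at(counts, anti, 1.0)
    return sums / counts + mean


_IMPL = {
    "BYPASS": lambda x, fs, p: x,
    "BPF": _bpf,
    "LPF": _lpf,
    "HPF": _hpf,
    "CUB": _cub,
    "WVL": _wvl,
    "SVDTFD": _svdtfd,
    "EMD": _emd_filter,
    "SSA": _ssa,
}


def apply(seg: Segment, spec: AlgorithmSpec) -> Segment:
    """Process one segment; output has the same length, rate and identity."""
    if spec.id not in _IMPL:
        raise ConfigurationError(f"unknown algorithm id {spec.id!r}")
    y = _IMPL[spec.id](seg.samples, seg.fs, spec.params)
    if spec.id == "BYPASS":
        return seg
    assert y.size == seg.samples.size
    return replace(seg, samples=y)
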