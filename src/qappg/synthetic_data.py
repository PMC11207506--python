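"""Seeded wrist-PPG session generator with ground truth and graded artifacts.

Emulates the data-collection protocol the pipeline expects — alternating
2 min static / 1 min typing blocks, five repetitions, 15 min per subject —
with a beat-by-beat two-Gaussian pulse model, slow baseline wander, sensor
noise, and typing-only artifact bursts whose severity is graded per subject.

Artifact bursts are narrowband amplitude-modulated tones in three bands:

* drift (< 0.25 Hz): slow lobes and smoothed steps; removable by high-pass /
  band-pass filtering, spline baseline subtraction, or low-frequency
  component removal (EMD/SSA);
* sway (0.55-0.95 Hz): survives the 0.5 Hz filter cutoffs but is removed by
  the sub-1 Hz subspace rule (SSA);
* in-band (1.0-2.5 Hz): overlaps the cardiac band, unfixable by any pool
  algorithm — these segments are what the cascade should discard.

Their relative weights are calibrated so that increasing ``artifact_severity``
breaks plain (bypass) estimation first through drift, then sway, then in-band
power, planting the processability gradient the selection mechanism must
learn.  The ECG channel is synthesized from the *same* beat sequence as the
PPG so reference heart rates are exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core_io import Segment, TimeSeriesRecord, segment_signal
from .errors import ContractError

__all__ = [
    "ProtocolSpec",
    "SubjectParams",
    "SessionTruth",
    "SubjectSession",
    "generate_hr_trace",
    "generate_ppg",
    "generate_ecg",
    "generate_corpus",
    "TRACE_FS",
]

#: Sample rate of heart-rate traces (Hz).
TRACE_FS = 4.0

PPG_FS = 100.0
ECG_FS = 256.0

HR_MIN, HR_MAX = 52.0, 128.0

# artifact band weights relative to unit pulse amplitude (see module docstring)
DRIFT_WEIGHT = 2.0
SWAY_WEIGHT = 0.22
INBAND_WEIGHT = 0.035
BURST_RATE_HZ = 0.5  # Poisson burst arrivals per second of typing
BURST_DURATION_S = (5.0, 10.0)
STEP_PROB = 0.25  # chance a drift burst is a smoothed step transient


@dataclass(frozen=True)
class ProtocolSpec:
    static_s: float = 120.0
    typing_s: float = 60.0
    repetitions: int = 5

    @property
    def block_s(self) -> float:
        return self.static_s + self.typing_s

    @property
    def total_s(self) -> float:
        return self.repetitions * self.block_s

    def typing_windows(self) -> list[tuple[float, float]]:
        return [
            (k * self.block_s + self.static_s, (k + 1) * self.block_s)
            for k in range(self.repetitions)
        ]

    def regime_flags(self, window_s: float = 10.0) -> np.ndarray:
        """'static' / 'typing' flag per consecutive window."""
        n = int(self.total_s // window_s)
        centers = (np.arange(n) + 0.5) * window_s
        flags = np.full(n, "static", dtype=object)
        for lo, hi in self.typing_windows():
            flags[(centers >= lo) & (centers < hi)] = "typing"
        return flags


@dataclass(frozen=True)
class SubjectParams:
    base_hr_bpm: float = 72.0
    hr_walk_std: float = 0.3
    artifact_severity: float = 0.0
    wander_amp: float = 0.2
    noise_std: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not HR_MIN <= self.base_hr_bpm <= HR_MAX:
            raise ContractError(f"base_hr_bpm must lie in [{HR_MIN}, {HR_MAX}]")
        if self.artifact_severity < 0:
            raise ContractError("artifact_severity must be >= 0")


@dataclass(frozen=True)
class SessionTruth:
    true_hr_bpm: np.ndarray  # per-segment mean heart rate
    regime: np.ndarray  # per-segment {'static', 'typing'}
    artifact_energy: np.ndarray  # per-segment mean-square injected artifact


@dataclass(frozen=True)
class SubjectSession:
    subject_id: str
    params: SubjectParams
    ppg: TimeSeriesRecord
    ecg: TimeSeriesRecord
    truth: SessionTruth

    def segments(self, window_s: float = 10.0) -> list[Segment]:
        return segment_signal(self.ppg, window_s)


def generate_hr_trace(sp: SubjectParams, duration_s: float) -> np.ndarray:
    """Smooth bounded-random-walk heart-rate trace at :data:`TRACE_FS` Hz.

    The walk reflects at [52, 128] BPM and is low-pass smoothed so the trace
    varies on a multi-second timescale; zero walk std yields a constant trace.
    """
    if duration_s <= 0:
        raise ContractError("duration must be positive")
    rng = np.random.default_rng(sp.seed)
    n = int(round(duration_s * TRACE_FS))
    steps = rng.normal(0.0, sp.hr_walk_std, size=n)
    walk = sp.base_hr_bpm + np.cumsum(steps)
    # reflect into [HR_MIN, HR_MAX] via triangle-wave folding
    span = HR_MAX - HR_MIN
    folded = np.mod(walk - HR_MIN, 2 * span)
    folded = np.where(folded > span, 2 * span - folded, folded) + HR_MIN
    smooth = gaussian_filter1d(folded, sigma=5.0 * TRACE_FS, mode="nearest")
    return np.clip(smooth, HR_MIN, HR_MAX)


def _beat_times(hr_trace: np.ndarray, duration_s: float) -> np.ndarray:
    """Deterministic beat onsets from an instantaneous-HR trace.

    Shared by the PPG and ECG synthesizers so both channels carry the exact
    same beat sequence.
    """
    times = []
    t = 0.0
    n = hr_trace.size
    while t < duration_s:
        times.append(t)
        hr = hr_trace[min(int(t * TRACE_FS), n - 1)]
        t += 60.0 / hr
    return np.asarray(times)


def _add_gaussian(y: np.ndarray, fs: float, center_s: float, sigma_s: float, amp: float) -> None:
    lo = max(int((center_s - 4 * sigma_s) * fs), 0)
    hi = min(int((center_s + 4 * sigma_s) * fs) + 1, y.size)
    if lo >= hi:
        return
    t = np.arange(lo, hi) / fs
    y[lo:hi] += amp * np.exp(-0.5 * ((t - center_s) / sigma_s) ** 2)


def _pulse_waveform(beats: np.ndarray, duration_s: float, fs: float) -> np.ndarray:
    """Two-Gaussian beats: systolic peak plus a dicrotic bump at 0.45 of the
    cycle with amplitude ratio 0.3."""
    n = int(round(duration_s * fs))
    y = np.zeros(n)
    for i, t0 in enumerate(beats):
        cycle = (beats[i + 1] - t0) if i + 1 < beats.size else (
            beats[i] - beats[i - 1] if i > 0 else 0.8
        )
        _add_gaussian(y, fs, t0 + 0.20 * cycle, 0.09 * cycle, 1.0)
        _add_gaussian(y, fs, t0 + 0.45 * cycle + 0.12 * cycle, 0.12 * cycle, 0.3)
    return y


def _burst(rng: np.random.Generator, n: int, fs: float, start_s: float,
           dur_s: float, freq_hz: float, amp: float, step: bool) -> np.ndarray:
    """One amplitude-modulated artifact burst confined to [start, start+dur]."""
    y = np.zeros(n)
    lo = int(start_s * fs)
    hi = min(int((start_s + dur_s) * fs), n)
    if lo >= hi:
        return y
    m = hi - lo
    t = np.arange(m) / fs
    env = np.hanning(m)
    if step:
        # smoothed rectangular transient (sensor shift during a keystroke run)
        y[lo:hi] = amp * env
    else:
        phase = rng.uniform(0, 2 * np.pi)
        y[lo:hi] = amp * env * np.sin(2 * np.pi * freq_hz * t + phase)
    return y


def _artifact_waveform(rng: np.random.Generator, sp: SubjectParams,
                       ps: ProtocolSpec, n: int, fs: float) -> np.ndarray:
    art = np.zeros(n)
    if sp.artifact_severity == 0:
        return art
    sev = sp.artifact_severity
    for win_lo, win_hi in ps.typing_windows():
        n_bursts = rng.poisson(BURST_RATE_HZ * (win_hi - win_lo))
        # one drift mode per typing bout (a posture/wrist-angle shift) keeps
        # the low-frequency corruption coherent within the window
        drift_freq = rng.uniform(0.04, 0.12)
        for _ in range(n_bursts):
            start = rng.uniform(win_lo, win_hi)
            dur = rng.uniform(*BURST_DURATION_S)
            dur = min(dur, win_hi - start)  # never leak into static regime
            kind = rng.random()
            if kind < 0.5:  # drift band, < 0.25 Hz dominant
                step = rng.random() < STEP_PROB
                art += _burst(rng, n, fs, start, dur, drift_freq,
                              sev * DRIFT_WEIGHT * (1 if rng.random() < 0.5 else -1),
                              step)
            elif kind < 0.85:  # sway band, between the filter and subspace cutoffs
                freq = rng.uniform(0.55, 0.95)
                art += _burst(rng, n, fs, start, dur, freq, sev * SWAY_WEIGHT, False)
            else:  # in-band, unfixable
                freq = rng.uniform(1.0, 2.5)
                art += _burst(rng, n, fs, start, dur, freq, sev * INBAND_WEIGHT, False)
    return art


def generate_ppg(
    hr_trace: np.ndarray,
    sp: SubjectParams,
    ps: ProtocolSpec = ProtocolSpec(),
    subject_id: str = "",
) -> tuple[TimeSeriesRecord, np.ndarray]:
    """Synthesize the PPG channel; returns ``(record, artifact_waveform)``.

    The artifact waveform is returned separately so callers can annotate
    per-segment artifact energy in the session truth.
    """
    duration_s = ps.total_s
    n = int(round(duration_s * PPG_FS))
    rng = np.random.default_rng(np.random.SeedSequence([sp.seed, 1]))
    beats = _beat_times(hr_trace, duration_s)
    y = _pulse_waveform(beats, duration_s, PPG_FS)
    t = np.arange(n) / PPG_FS
    if sp.wander_amp > 0:
        for _ in range(2):
            f = rng.uniform(0.2, 0.4)
            y += 0.5 * sp.wander_amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    if sp.noise_std > 0:
        y += rng.normal(0.0, sp.noise_std, size=n)
    art = _artifact_waveform(rng, sp, ps, n, PPG_FS)
    rec = TimeSeriesRecord(samples=y + art, fs=PPG_FS, channel="PPG", subject_id=subject_id)
    return rec, art


def generate_ecg(
    hr_trace: np.ndarray,
    sp: SubjectParams,
    duration_s: float,
    fs: float = ECG_FS,
    subject_id: str = "",
) -> TimeSeriesRecord:
    """Impulse-like R waves (20 ms Gaussians) at the shared beat times."""
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(np.random.SeedSequence([sp.seed, 2]))
    beats = _beat_times(hr_trace, duration_s)
    y = np.zeros(n)
    for t0 in beats:
        _add_gaussian(y, fs, t0, 0.01, 1.0)
    y += rng.normal(0.0, 0.01, size=n)
    return TimeSeriesRecord(samples=y, fs=fs, channel="ECG", subject_id=subject_id)


def _session_truth(
    hr_trace: np.ndarray, art: np.ndarray, ps: ProtocolSpec, window_s: float = 10.0
) -> SessionTruth:
    n_seg = int(ps.total_s // window_s)
    hr_per_seg = np.empty(n_seg)
    art_energy = np.empty(n_seg)
    trace_win = int(round(window_s * TRACE_FS))
    art_win = int(round(window_s * PPG_FS))
    for i in range(n_seg):
        hr_per_seg[i] = hr_trace[i * trace_win : (i + 1) * trace_win].mean()
        seg_art = art[i * art_win : (i + 1) * art_win]
        art_energy[i] = float(np.mean(seg_art ** 2)) if seg_art.size else 0.0
    return SessionTruth(
        true_hr_bpm=hr_per_seg,
        regime=ps.regime_flags(window_s),
        artifact_energy=art_energy,
    )


def generate_session(
    sp: SubjectParams,
    ps: ProtocolSpec = ProtocolSpec(),
    subject_id: str = "S00",
    window_s: float = 10.0,
) -> SubjectSession:
    """One subject's full session: PPG + ECG records and aligned truth."""
    hr = generate_hr_trace(sp, ps.total_s)
    ppg, art = generate_ppg(hr, sp, ps, subject_id=subject_id)
    ecg = generate_ecg(hr, sp, ps.total_s, subject_id=subject_id)
    truth = _session_truth(hr, art, ps, window_s)
    return SubjectSession(subject_id=subject_id, params=sp, ppg=ppg, ecg=ecg, truth=truth)


@dataclass
class CorpusParams:
    """Parameter ranges swept across subjects of a corpus.

    Typing-burst severity and baseline-wander amplitude both vary per subject:
    severity grades the typing-only corruption while heavy wander corrupts
    whole sessions with exactly the low-frequency interference the filtering
    algorithms remove, so a corpus contains clean, processable and hopeless
    segments in every regime.
    """

    base_hr_range: tuple[float, float] = (60.0, 100.0)
    severity_range: tuple[float, float] = (0.0, 14.0)
    wander_range: tuple[float, float] = (0.1, 6.0)
    hr_walk_std: float = 0.3
    noise_std: float = 0.02


def generate_corpus(
    n_subjects: int = 12,
    ps: ProtocolSpec = ProtocolSpec(),
    params: CorpusParams = CorpusParams(),
    seed: int = 0,
    window_s: float = 10.0,
) -> list[SubjectSession]:
    """A corpus of seeded subject sessions spanning the full quality spectrum.

    Artifact severity is spread evenly across subjects (shuffled by seed) so
    some subjects are mostly clean and others mostly corrupted; per-subject
    seeds derive from the master seed.
    """
    if n_subjects < 1:
        raise ContractError("need at least one subject")
    master = np.random.default_rng(seed)
    severities = np.linspace(*params.severity_range, n_subjects)
    master.shuffle(severities)
    sessions = []
    for i in range(n_subjects):
        sp = SubjectParams(
            base_hr_bpm=float(master.uniform(*params.base_hr_range)),
            hr_walk_std=params.hr_walk_std,
            artifact_severity=float(severities[i]),
            wander_amp=float(master.uniform(*params.wander_range)),
            noise_std=params.noise_std,
            seed=int(master.integers(0, 2**31 - 1)),
        )
        sessions.append(generate_session(sp, ps, subject_id=f"S{i:02d}", window_s=window_s))
    return sessions
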