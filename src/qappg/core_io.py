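"""Record/segment data model, delimited-text I/O and run configuration.

Signals live on disk as plain CSV (``value`` or ``t,value`` columns) next to a
JSON sidecar declaring ``fs_hz``, ``channel`` and ``subject_id``.  Records are
cut into non-overlapping fixed-length windows before any feature extraction or
processing; a trailing remainder shorter than one window is dropped.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError, ParseError

__all__ = [
    "TimeSeriesRecord",
    "Segment",
    "RunConfig",
    "load_record",
    "write_record",
    "segment_signal",
]

#: Conventional sampling rates for each channel type.
DEFAULT_FS = {"PPG": 100.0, "ECG": 256.0}

VALID_CHANNELS = ("PPG", "ECG")


@dataclass(frozen=True)
class TimeSeriesRecord:
    """A uniformly sampled single-channel physiological signal."""

    samples: np.ndarray
    fs: float
    channel: str = "PPG"
    subject_id: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1 or samples.size == 0:
            raise ConfigurationError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ParseError("record contains non-finite samples")
        if self.channel not in VALID_CHANNELS:
            raise ConfigurationError(f"channel must be one of {VALID_CHANNELS}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class Segment:
    """One fixed-length window of a record (default 10 s)."""

    samples: np.ndarray
    fs: float
    window_s: float = 10.0
    index: int = 0
    subject_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        expected = int(round(self.fs * self.window_s))
        if samples.size != expected:
            raise ConfigurationError(
                f"segment length {samples.size} != round(fs*window)={expected}"
            )

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class RunConfig:
    """Resolved pipeline configuration; every default is overridable from file."""

    window_s: float = 10.0
    hr_band_hz: tuple[float, float] = (0.83, 2.16)
    usability_threshold_bpm: float = 5.0
    reject_rate: float = 0.30
    energy_budget_mJ: float = float("inf")
    seed: int = 0
    algorithms: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.hr_band_hz
        if not lo < hi:
            raise ConfigurationError(f"hr_band_hz must satisfy lo < hi, got {self.hr_band_hz}")
        if not 0 <= self.reject_rate < 1:
            raise ConfigurationError(f"reject_rate must be in [0, 1), got {self.reject_rate}")
        if self.window_s <= 0:
            raise ConfigurationError("window_s must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load overrides from a YAML or JSON file."""
        raw = Path(path).read_text()
        data = yaml.safe_load(raw) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "hr_band_hz" in data:
            data["hr_band_hz"] = tuple(data["hr_band_hz"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hr_band_hz"] = list(self.hr_band_hz)
        return d


def _read_sidecar(meta: str | Path) -> dict:
    try:
        data = json.loads(Path(meta).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"sidecar {meta} is not valid JSON: {exc}") from exc
    if "fs_hz" not in data:
        raise ConfigurationError(f"sidecar {meta} missing required key 'fs_hz'")
    return data


def load_record(path: str | Path, meta: str | Path) -> TimeSeriesRecord:
    """Read a delimited-text signal file plus its JSON sidecar.

    The signal file holds one sample per row, either a single ``value`` column
    or ``t,value``; an optional one-line header is detected and skipped.
    Non-numeric rows are rejected (no gap filling) with the row named.
    """
    meta_data = _read_sidecar(meta)
    fs = meta_data["fs_hz"]
    if not isinstance(fs, (int, float)) or fs <= 0:
        raise ConfigurationError(f"sidecar {meta} declares invalid fs_hz={fs!r}")
    channel = meta_data.get("channel", "PPG")
    subject_id = meta_data.get("subject_id", "")
    t0 = float(meta_data.get("t0", 0.0))

    lines = Path(path).read_text().splitlines()
    values: list[float] = []
    start = 0
    if lines:
        first = lines[0].split(",")[-1].strip()
        try:
            float(first)
        except ValueError:
            start = 1  # header row
    for i, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        cell = line.split(",")[-1].strip()
        try:
            v = float(cell)
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric value {cell!r} at row {i}") from exc
        if not np.isfinite(v):
            raise ParseError(f"{path}: non-finite value {cell!r} at row {i}")
        values.append(v)
    if not values:
        raise ParseError(f"{path}: no samples found")
    return TimeSeriesRecord(
        samples=np.asarray(values), fs=float(fs), channel=channel,
        subject_id=subject_id, t0=t0,
    )


def write_record(rec: TimeSeriesRecord, path: str | Path, meta: str | Path) -> None:
    """Write a record as CSV (``value`` column) plus JSON sidecar.

    Uses ``repr`` formatting so that finite decimal inputs round-trip
    bit-identically through :func:`load_record`.
    """
    lines = ["value"] + [repr(v) for v in rec.samples.tolist()]
    Path(path).write_text("\n".join(lines) + "\n")
    sidecar = {
        "fs_hz": rec.fs,
        "channel": rec.channel,
        "subject_id": rec.subject_id,
        "t0": rec.t0,
    }
    Path(meta).write_text(json.dumps(sidecar, indent=2) + "\n")


def segment_signal(
    rec: TimeSeriesRecord, window_s: float = 10.0
) -> list[Segment]:
    """Cut a record into non-overlapping consecutive windows of ``window_s``.

    Returns ``floor(N / (fs * window_s))`` segments; the trailing remainder is
    dropped.  A record shorter than one window yields an empty list with a
    warning rather than an error.
    """
    n_win = int(round(rec.fs * window_s))
    n_seg = rec.samples.size // n_win
    if n_seg == 0:
        warnings.warn(
            f"record of {rec.samples.size} samples shorter than one "
            f"{window_s} s window; no segments produced",
            stacklevel=2,
        )
        return []
    return [
        Segment(
            samples=rec.samples[i * n_win : (i + 1) * n_win],
            fs=rec.fs,
            window_s=window_s,
            index=i,
            subject_id=rec.subject_id,
        )
        for i in range(n_seg)
    ]


def iter_segments(records: Sequence[TimeSeriesRecord], window_s: float = 10.0) -> Iterator[Segment]:
    for rec in records:
        yield from segment_signal(rec, window_s)
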