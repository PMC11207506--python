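import numpy as np
import pytest

from qappg import algorithms as alg
from qappg.core_io import Segment
from qappg.synthetic_data import ProtocolSpec, SubjectParams, generate_session

FS = 100.0
N = 1000


@pytest.fixture(scope="session")
def pool():
    return {spec.id: spec for spec in alg.list_pool()}


@pytest.fixture
def make_tone():
    def _make(freqs, amps=None, fs=FS, n=N, offset=0.0):
        amps = amps if amps is not None else [1.0] * len(freqs)
        t = np.arange(n) / fs
        x = offset + sum(a * np.sin(2 * np.pi * f * t) for f, a in zip(freqs, amps))
        return Segment(samples=x, fs=fs, window_s=n / fs)

    return _make


@pytest.fixture(scope="session")
def clean_session():
    """One artifact-free, noise-free minute of synthetic PPG."""
    sp = SubjectParams(base_hr_bpm=72.0, hr_walk_std=0.0, artifact_severity=0.0,
                       wander_amp=0.0, noise_std=0.0, seed=11)
    return generate_session(sp, ProtocolSpec(static_s=60.0, typing_s=0.0, repetitions=1))


@pytest.fixture(scope="session")
def corrupted_session():
    """Three short static/typing blocks at mid severity."""
    sp = SubjectParams(base_hr_bpm=75.0, hr_walk_std=0.3, artifact_severity=6.0, seed=23)
    return generate_session(sp, ProtocolSpec(static_s=20.0, typing_s=40.0, repetitions=3))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
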