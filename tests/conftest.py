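import numpy as np
import pytest

from msmra.preprocess import EEGRecording


@pytest.fixture
def tone_recording():
    """60 s single-trial recording factory: pure sinusoid at a given Hz."""

    def make(freq_hz: float = 10.0, fs: float = 200.0, seconds: float = 60.0, channels: int = 1):
        t = np.arange(int(seconds * fs)) / fs
        sig = np.tile(np.sin(2 * np.pi * freq_hz * t), (channels, 1))
        return EEGRecording(
            signal=sig,
            fs=fs,
            trial_boundaries=[(0, sig.shape[1])],
            labels=np.array([0]),
        )

    return make


@pytest.fixture
def white_recording():
    """White-noise recording factory with configurable trial structure."""

    def make(
        channels: int = 2,
        fs: float = 200.0,
        trial_s: float = 10.0,
        trials: int = 1,
        sigma: float = 1.0,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        n = int(trial_s * fs)
        sig = rng.normal(0.0, sigma, size=(channels, n * trials))
        return EEGRecording(
            signal=sig,
            fs=fs,
            trial_boundaries=[(i * n, (i + 1) * n) for i in range(trials)],
            labels=np.arange(trials) % 2,
        )

    return make
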