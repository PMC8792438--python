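"""Filtering, differential entropy and normalization of EEG features."""

import numpy as np
import pytest
from scipy import signal as sps

from msmra.exceptions import (
    AlreadyNormalizedError,
    DegenerateWindowError,
    EmptyInputError,
    InvalidBandError,
    TooShortError,
)
from msmra.preprocess import (
    DEFAULT_BANDS,
    BandDefinition,
    EEGRecording,
    FeatureTensor,
    bandpass_filter,
    compute_de_window,
    extract_de_features,
    normalize_features,
)

ALPHA = DEFAULT_BANDS[2]
GAMMA = DEFAULT_BANDS[4]
GAUSS_DE = 0.5 * np.log(2 * np.pi * np.e)  # DE of a unit-variance Gaussian


def rms(x):
    return np.sqrt(np.mean(np.square(x)))


class TestBandpass:
    def test_passband_preserves_tone(self, tone_recording):
        rec = tone_recording(freq_hz=10.0)
        out = bandpass_filter(rec, ALPHA)
        assert rms(out.signal) == pytest.approx(rms(rec.signal), rel=0.05)

    def test_stopband_rejects_tone(self, tone_recording):
        rec = tone_recording(freq_hz=10.0)
        out = bandpass_filter(rec, GAMMA)
        assert rms(out.signal) < 0.02 * rms(rec.signal)

    def test_zero_signal_stays_zero(self):
        rec = EEGRecording(
            signal=np.zeros((3, 1000)), fs=200.0, trial_boundaries=[(0, 1000)], labels=[0]
        )
        out = bandpass_filter(rec, ALPHA)
        assert np.all(out.signal == 0.0)

    def test_metadata_passthrough(self, tone_recording):
        rec = tone_recording()
        out = bandpass_filter(rec, ALPHA)
        assert out.signal.shape == rec.signal.shape
        assert out.fs == rec.fs
        assert out.trial_boundaries == rec.trial_boundaries

    def test_band_above_nyquist_rejected(self, tone_recording):
        rec = tone_recording(fs=80.0)  # Nyquist 40 < gamma upper edge 50
        with pytest.raises(InvalidBandError):
            bandpass_filter(rec, GAMMA)

    def test_too_short_signal_rejected(self):
        rec = EEGRecording(
            signal=np.random.default_rng(0).normal(size=(1, 8)),
            fs=200.0,
            trial_boundaries=[(0, 8)],
            labels=[0],
        )
        with pytest.raises(TooShortError):
            bandpass_filter(rec, ALPHA)


class TestDifferentialEntropy:
    def test_standard_normal_closed_form(self):
        x = np.random.default_rng(42).normal(size=100_000)
        assert compute_de_window(x) == pytest.approx(GAUSS_DE, abs=0.02)
        assert GAUSS_DE == pytest.approx(1.4189, abs=5e-5)

    def test_sigma_three_closed_form(self):
        x = np.random.default_rng(7).normal(0.0, 3.0, size=100_000)
        assert compute_de_window(x) == pytest.approx(GAUSS_DE + np.log(3.0), abs=0.02)

    def test_scaling_shifts_by_log_factor(self):
        x = np.random.default_rng(3).normal(size=500)
        assert compute_de_window(2.0 * x) - compute_de_window(x) == pytest.approx(
            np.log(2.0), abs=1e-9
        )

    @pytest.mark.parametrize("bad", [np.ones(100), np.zeros(50), np.array([1.0])])
    def test_degenerate_windows_rejected(self, bad):
        with pytest.raises(DegenerateWindowError):
            compute_de_window(bad)

    def test_estimator_consistency(self):
        # at n = 1e4 the estimate is within 0.05 nats of the closed form
        # essentially always; allow one failure in 100 seeded replicates
        errs = [
            abs(compute_de_window(np.random.default_rng(s).normal(size=10_000)) - GAUSS_DE)
            for s in range(100)
        ]
        assert sum(e < 0.05 for e in errs) >= 99


class TestExtractFeatures:
    def test_width_is_channels_times_bands(self, white_recording):
        rec = white_recording(channels=62, trial_s=3.0)
        tensor = extract_de_features(rec, DEFAULT_BANDS, window_s=1.0)
        assert tensor.width == 310

    def test_window_count_and_labels(self, white_recording):
        rec = white_recording(channels=2, trial_s=10.0, trials=2)
        tensor = extract_de_features(rec, DEFAULT_BANDS, window_s=1.0)
        assert tensor.n_windows == 20
        assert list(np.unique(tensor.labels[tensor.trial_index == 0])) == [0]
        assert list(np.unique(tensor.labels[tensor.trial_index == 1])) == [1]

    def test_white_noise_matches_passband_power(self, white_recording):
        sigma = 2.0
        rec = white_recording(channels=1, trial_s=120.0, sigma=sigma, seed=5)
        tensor = extract_de_features(rec, DEFAULT_BANDS, window_s=4.0)
        w = np.linspace(0, np.pi, 4096)
        for b, band in enumerate(DEFAULT_BANDS):
            sos = sps.butter(4, [band.low_hz, band.high_hz], "bandpass", fs=rec.fs, output="sos")
            _, h = sps.sosfreqz(sos, worN=w)
            # forward-backward filtering squares the magnitude response
            passband_power = sigma**2 * np.mean(np.abs(h) ** 4)
            expected = 0.5 * np.log(2 * np.pi * np.e * passband_power)
            assert np.mean(tensor.values[:, b]) == pytest.approx(expected, abs=0.1)

    def test_amplitude_scaling_shifts_all_features(self, white_recording):
        rec = white_recording(channels=2, trial_s=5.0)
        scaled = EEGRecording(
            signal=3.0 * rec.signal,
            fs=rec.fs,
            trial_boundaries=rec.trial_boundaries,
            labels=rec.labels,
        )
        t1 = extract_de_features(rec, DEFAULT_BANDS)
        t2 = extract_de_features(scaled, DEFAULT_BANDS)
        assert np.allclose(t2.values - t1.values, np.log(3.0), atol=1e-6)

    def test_short_trial_skipped_with_warning(self, white_recording):
        rec = white_recording(channels=1, trial_s=5.0)
        rec = EEGRecording(
            signal=rec.signal,
            fs=rec.fs,
            trial_boundaries=[(0, 100), (100, 1000)],  # first trial 0.5 s < 1 s window
            labels=[0, 1],
        )
        with pytest.warns(UserWarning, match="skipped"):
            tensor = extract_de_features(rec, DEFAULT_BANDS, window_s=1.0)
        assert set(tensor.trial_index) == {1}

    def test_zero_trials_rejected(self):
        rec = EEGRecording(
            signal=np.random.default_rng(0).normal(size=(1, 1000)),
            fs=200.0,
            trial_boundaries=[],
            labels=[],
        )
        with pytest.raises(EmptyInputError):
            extract_de_features(rec, DEFAULT_BANDS)


class TestNormalize:
    def _tensor(self, seed=0, n=50, d=7):
        rng = np.random.default_rng(seed)
        v = rng.normal(2.0, 5.0, size=(n, d))
        v[:, -1] = 3.14  # constant column
        return FeatureTensor(values=v, labels=np.zeros(n, dtype=int))

    def test_zscore_definition(self):
        out = normalize_features(self._tensor())
        assert out.normalized
        np.testing.assert_allclose(out.values[:, :-1].mean(axis=0), 0.0, atol=1e-6)
        np.testing.assert_allclose(out.values[:, :-1].var(axis=0), 1.0, atol=1e-6)

    def test_constant_column_maps_to_zero(self):
        out = normalize_features(self._tensor())
        assert np.all(out.values[:, -1] == 0.0)

    def test_repeat_normalization_policy(self):
        once = normalize_features(self._tensor())
        with pytest.raises(AlreadyNormalizedError):
            normalize_features(once)
        again = normalize_features(once, on_normalized="noop")
        np.testing.assert_array_equal(again.values, once.values)

    def test_default_band_edges(self):
        edges = [(b.name, b.low_hz, b.high_hz) for b in DEFAULT_BANDS]
        assert edges == [
            ("delta", 1.0, 4.0),
            ("theta", 4.0, 8.0),
            ("alpha", 8.0, 14.0),
            ("beta", 14.0, 31.0),
            ("gamma", 31.0, 50.0),
        ]

    def test_invalid_band_definition(self):
        with pytest.raises(InvalidBandError):
            BandDefinition("bad", 10.0, 5.0)
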