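"""Differential-entropy feature extraction from multichannel EEG.

The preprocessing chain mirrors the standard pipeline for affective EEG
datasets recorded with 62-channel caps: downsample to 200 Hz, band-limit,
then summarise each non-overlapping window of each channel by the
differential entropy (DE) of the five canonical rhythms (Delta, Theta,
Alpha, Beta, Gamma).  Under a Gaussian model of the band-limited signal
the DE of a window reduces to the closed form

    DE = 1/2 * ln(2 * pi * e * sigma^2)   [nats],

i.e. a log-variance band-power feature.  With 62 channels and 5 bands a
window becomes a 310-dimensional vector (channel-major, band-minor).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .exceptions import (
    AlreadyNormalizedError,
    DegenerateWindowError,
    EmptyInputError,
    InvalidBandError,
    TooShortError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "EEGRecording",
    "FeatureTensor",
    "bandpass_filter",
    "compute_de_window",
    "extract_de_features",
    "normalize_features",
    "resample_recording",
]


@dataclass(frozen=True)
class BandDefinition:
    """A half-open frequency band ``[low_hz, high_hz)`` in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise InvalidBandError(
                f"band {self.name!r}: need 0 < low ({self.low_hz}) < high ({self.high_hz})"
            )


#: The five canonical EEG rhythms used throughout.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 14.0),
    BandDefinition("beta", 14.0, 31.0),
    BandDefinition("gamma", 31.0, 50.0),
)


@dataclass
class EEGRecording:
    """One subject-session unit of raw EEG.

    Attributes
    ----------
    signal : ndarray, shape (channels, samples)
        Raw EEG in microvolts.
    fs : float
        Sampling rate in Hz.
    trial_boundaries : list of (start, stop)
        Half-open sample intervals, one per trial, disjoint and in range.
    labels : ndarray of int, shape (n_trials,)
        One emotion label per trial, values in ``0..M-1``.
    """

    signal: np.ndarray
    fs: float
    trial_boundaries: list[tuple[int, int]]
    labels: np.ndarray
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a channels x samples matrix")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if len(self.labels) != len(self.trial_boundaries):
            raise ValueError(
                f"{len(self.labels)} labels for {len(self.trial_boundaries)} trials"
            )
        n = self.signal.shape[1]
        prev_stop = 0
        for start, stop in sorted(self.trial_boundaries):
            if not (0 <= start < stop <= n):
                raise ValueError(f"trial interval ({start}, {stop}) outside signal of length {n}")
            if start < prev_stop:
                raise ValueError("trial intervals overlap")
            prev_stop = stop

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_trials(self) -> int:
        return len(self.trial_boundaries)


@dataclass
class FeatureTensor:
    """DE features of one recording: ``windows x (channels * bands)``.

    The flattening is channel-major, band-minor: column ``c * n_bands + b``
    holds channel ``c``, band ``b``.  With the default 62-channel, 5-band
    layout the width is 310.
    """

    values: np.ndarray
    labels: np.ndarray
    layout: str = "channel-major-band-minor"
    window_s: float = 1.0
    normalized: bool = False
    subject_id: str = ""
    session_id: str = ""
    n_channels: int = 62
    n_bands: int = 5
    trial_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be a windows x features matrix")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("one label per window required")
        if self.trial_index is None:
            self.trial_index = np.zeros(self.values.shape[0], dtype=int)
        else:
            self.trial_index = np.asarray(self.trial_index, dtype=int)

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def key(self) -> tuple[str, str]:
        return (self.subject_id, self.session_id)


def _design_bandpass(band: BandDefinition, fs: float, order: int = 4) -> np.ndarray:
    nyq = fs / 2.0
    if band.high_hz >= nyq:
        raise InvalidBandError(
            f"band {band.name!r} upper edge {band.high_hz} Hz >= Nyquist {nyq} Hz"
        )
    return signal.butter(order, [band.low_hz, band.high_hz], btype="bandpass", fs=fs, output="sos")


def _sosfiltfilt(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    # zero-phase forward-backward filtering; scipy raises when the signal
    # is shorter than its edge padding, which we surface as TooShortError
    try:
        return signal.sosfiltfilt(sos, x, axis=-1)
    except ValueError as exc:
        raise TooShortError(f"signal too short for zero-phase filtering: {exc}") from exc


def bandpass_filter(
    recording: EEGRecording, band: BandDefinition, order: int = 4
) -> EEGRecording:
    """Zero-phase Butterworth band-pass of every channel.

    Returns a new recording with identical sampling rate, trial
    boundaries and labels; only the signal is band-limited.
    """
    sos = _design_bandpass(band, recording.fs, order=order)
    filtered = _sosfiltfilt(sos, recording.signal)
    return replace(recording, signal=filtered)


def compute_de_window(samples: np.ndarray, ddof: int = 1) -> float:
    """Differential entropy of one window under the Gaussian model.

    Uses the unbiased sample variance and natural logarithms, so the
    result is ``0.5 * ln(2 * pi * e * var)`` in nats.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 2:
        raise DegenerateWindowError(f"window of {x.size} sample(s); need >= 2")
    var = float(np.var(x, ddof=ddof))
    if var <= 0.0:
        raise DegenerateWindowError("zero sample variance; differential entropy diverges")
    return 0.5 * float(np.log(2.0 * np.pi * np.e * var))


def _window_variances(x: np.ndarray, win: int, ddof: int = 1) -> np.ndarray:
    """Unbiased variances of consecutive length-``win`` windows, vectorised.

    ``x`` is channels x samples; returns channels x n_windows.
    """
    n_win = x.shape[1] // win
    blocks = x[:, : n_win * win].reshape(x.shape[0], n_win, win)
    return blocks.var(axis=2, ddof=ddof)


def extract_de_features(
    recording: EEGRecording,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    window_s: float = 1.0,
    order: int = 4,
    prefilter: BandDefinition | None = None,
) -> FeatureTensor:
    """Per-window, per-channel, per-band differential entropy features.

    Each trial is cut into non-overlapping windows of ``window_s``
    seconds; every window inherits its trial's label.  Trials shorter
    than one window are skipped with a warning.  An optional broad-band
    ``prefilter`` (e.g. 0-75 Hz) can be applied before the per-band
    filters; by default the per-band filters alone define the analysis
    bands, whose union lies inside any such broad-band filter.
    """
    if recording.n_trials == 0:
        raise EmptyInputError("recording has no trials")
    win = int(round(window_s * recording.fs))
    if win < 2:
        raise InvalidBandError(f"window of {window_s} s is under 2 samples at fs={recording.fs}")

    sig = recording.signal
    if prefilter is not None:
        sig = _sosfiltfilt(_design_bandpass(prefilter, recording.fs, order=order), sig)

    n_ch, n_bands = recording.n_channels, len(bands)
    # filter the whole signal once per band, then window per trial
    per_band = [
        _sosfiltfilt(_design_bandpass(b, recording.fs, order=order), sig) for b in bands
    ]

    rows: list[np.ndarray] = []
    row_labels: list[int] = []
    row_trials: list[int] = []
    for t, (start, stop) in enumerate(recording.trial_boundaries):
        n_win = (stop - start) // win
        if n_win == 0:
            warnings.warn(
                f"trial {t} ({stop - start} samples) shorter than one "
                f"{win}-sample window; skipped",
                stacklevel=2,
            )
            continue
        # variances: bands x channels x windows
        var = np.stack(
            [_window_variances(fb[:, start:stop], win) for fb in per_band], axis=0
        )
        if np.any(var <= 0.0):
            raise DegenerateWindowError(
                f"trial {t}: zero-variance window in band-filtered signal"
            )
        de = 0.5 * np.log(2.0 * np.pi * np.e * var)  # bands x channels x windows
        # channel-major, band-minor flattening
        flat = de.transpose(2, 1, 0).reshape(n_win, n_ch * n_bands)
        rows.append(flat)
        row_labels.extend([int(recording.labels[t])] * n_win)
        row_trials.extend([t] * n_win)

    if not rows:
        raise EmptyInputError("no trial long enough for a single window")
    return FeatureTensor(
        values=np.vstack(rows),
        labels=np.asarray(row_labels, dtype=int),
        window_s=window_s,
        subject_id=recording.subject_id,
        session_id=recording.session_id,
        n_channels=n_ch,
        n_bands=n_bands,
        trial_index=np.asarray(row_trials, dtype=int),
    )


def normalize_features(
    tensor: FeatureTensor, on_normalized: str = "error", eps: float = 1e-12
) -> FeatureTensor:
    """Per-recording z-score of every feature column.

    Statistics come from this recording only, so target statistics never
    leak into the sources.  Constant columns map to zero.  ``on_normalized``
    controls repeat calls: ``"error"`` raises, ``"noop"`` returns the
    input unchanged.
    """
    if tensor.normalized:
        if on_normalized == "noop":
            return tensor
        raise AlreadyNormalizedError("tensor already normalized (pass on_normalized='noop')")
    v = tensor.values
    mean = v.mean(axis=0)
    std = v.std(axis=0)
    out = np.where(std > eps, (v - mean) / np.where(std > eps, std, 1.0), 0.0)
    return replace(tensor, values=out, normalized=True)


def resample_recording(recording: EEGRecording, target_fs: float = 200.0) -> EEGRecording:
    """Polyphase resampling to ``target_fs`` (no-op when rates match)."""
    if recording.fs == target_fs:
        return recording
    from fractions import Fraction

    frac = Fraction(target_fs / recording.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(recording.signal, up, down, axis=-1)
    scale = target_fs / recording.fs
    bounds = [
        (int(np.floor(a * scale)), max(int(np.floor(a * scale)) + 1, int(np.floor(b * scale))))
        for a, b in recording.trial_boundaries
    ]
    bounds = [(a, min(b, out.shape[1])) for a, b in bounds]
    return replace(recording, signal=out, fs=target_fs, trial_boundaries=bounds)
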