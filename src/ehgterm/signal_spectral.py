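"""Signal conditioning and short-time Fourier featurization of EHG traces.

The raw abdominal trace is conditioned by discarding the first minute
(start-up transients), band-pass filtering between 0.05 and 4 Hz with a
fourth-order zero-phase Butterworth filter (applied forward and backward,
so the effective magnitude response is the square of the single-pass
response and the net phase is zero), and decimating to 10 Hz by integer
stride — safe because the 4 Hz band edge sits below the new 5 Hz Nyquist.

The STFT uses 60 s Hamming windows slid with 75% overlap (hop 15 s),
chosen to resolve individual uterine contractions, and keeps the one-sided
magnitude spectrum per frame.  For a 30-minute recording this yields a
301x113 frequency-by-time matrix with 1/60 Hz frequency spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .data_io import EhgRecording

__all__ = [
    "FilterSpec",
    "StftSpec",
    "Spectrogram",
    "condition_signal",
    "frame_count",
    "compute_stft",
]


class TooShortError(ValueError):
    """Input shorter than a single analysis window."""


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass conditioning filter (defaults match the analysis)."""

    order: int = 4
    band_hz: tuple[float, float] = (0.05, 4.0)
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        low, high = self.band_hz
        if not 0 < low < high < fs / 2:
            raise ValueError(f"band {self.band_hz} invalid for fs={fs}")


@dataclass(frozen=True)
class StftSpec:
    fs: float = 10.0
    window_s: float = 60.0
    overlap_fraction: float = 0.75
    window_shape: str = "hamming"
    amplitude_transform: str = "log"  # {"linear", "log"}

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1)")
        hop = self.window_s * self.fs * (1.0 - self.overlap_fraction)
        if abs(hop - round(hop)) > 1e-9:
            raise ValueError("hop must be an integer number of samples")
        if self.amplitude_transform not in {"linear", "log"}:
            raise ValueError("amplitude_transform must be 'linear' or 'log'")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_s * self.fs))

    @property
    def hop_samples(self) -> int:
        return int(round(self.window_samples * (1.0 - self.overlap_fraction)))

    @property
    def n_freqs(self) -> int:
        return self.window_samples // 2 + 1


@dataclass
class Spectrogram:
    """Frequency-by-time STFT matrix with axis metadata."""

    values: np.ndarray
    freqs_hz: np.ndarray
    times_s: np.ndarray
    spec: StftSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.freqs_hz), len(self.times_s)):
            raise ValueError("values shape inconsistent with axes")

    @property
    def n_freqs(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, freqs_hz=None, times_s=None) -> "Spectrogram":
        return Spectrogram(
            values=values,
            freqs_hz=self.freqs_hz if freqs_hz is None else freqs_hz,
            times_s=self.times_s if times_s is None else times_s,
            spec=self.spec,
        )


def condition_signal(
    rec: EhgRecording,
    fspec: FilterSpec = FilterSpec(),
    fs_out: float = 10.0,
    drop_s: float = 60.0,
) -> EhgRecording:
    """Condition a raw recording: drop the first minute, filter, decimate.

    Requires ``rec.fs`` to be an integer multiple of ``fs_out``; returns a
    new recording sampled at ``fs_out`` of length ``(duration - drop_s) *
    fs_out`` samples.
    """
    fspec.validate(rec.fs)
    stride_f = rec.fs / fs_out
    if abs(stride_f - round(stride_f)) > 1e-9:
        raise ValueError(f"fs={rec.fs} is not an integer multiple of {fs_out}")
    stride = int(round(stride_f))
    n_drop = int(round(drop_s * rec.fs))
    if rec.samples.size <= n_drop:
        raise TooShortError("recording shorter than the dropped lead-in")
    trimmed = rec.samples[n_drop:]
    ba = sps.butter(fspec.order, fspec.band_hz, btype="bandpass", fs=rec.fs)
    if fspec.zero_phase:
        filtered = sps.filtfilt(*ba, trimmed)
    else:
        filtered = sps.lfilter(*ba, trimmed)
    decimated = filtered[::stride]
    return replace(rec, fs=fs_out, samples=decimated)


def frame_count(n_samples: int, spec: StftSpec = StftSpec()) -> int:
    """Number of sliding windows: ``floor((n - window) / hop) + 1``."""
    window, hop = spec.window_samples, spec.hop_samples
    if n_samples < window:
        raise TooShortError(
            f"need at least {window} samples for one window, got {n_samples}"
        )
    return (n_samples - window) // hop + 1


def compute_stft(signal: np.ndarray | EhgRecording, spec: StftSpec = StftSpec()) -> Spectrogram:
    """One-sided Hamming-windowed STFT magnitude of a conditioned signal.

    Column ``t`` covers samples ``[t*hop, t*hop + window)``.  With the log
    transform each entry is ``log(1 + |X|)``, which keeps zero signal at
    exactly zero and compresses the dynamic range for training stability.
    """
    x = signal.samples if isinstance(signal, EhgRecording) else np.asarray(signal, float)
    window, hop = spec.window_samples, spec.hop_samples
    n_frames = frame_count(x.size, spec)
    taper = np.hamming(window)
    idx = np.arange(window)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * taper
    mags = np.abs(np.fft.rfft(frames, n=window, axis=1)).T  # freq x time
    if spec.amplitude_transform == "log":
        mags = np.log1p(mags)
    freqs = np.fft.rfftfreq(window, d=1.0 / spec.fs)
    times = (np.arange(n_frames) * hop) / spec.fs
    return Spectrogram(values=mags, freqs_hz=freqs, times_s=times, spec=spec)
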