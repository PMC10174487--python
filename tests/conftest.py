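import numpy as np
import pytest

from ehgterm import CohortSpec, generate_cohort
from ehgterm.signal_spectral import Spectrogram, StftSpec

#: Small STFT configuration for fast model tests (2 s windows at 10 Hz).
SMALL_STFT = StftSpec(fs=10.0, window_s=2.0, overlap_fraction=0.5)


def make_spectrogram(rng, n_times=12, spec=SMALL_STFT, shift=0.0):
    """Random spectrogram whose mean is shifted by ``shift`` (class signal)."""
    values = rng.standard_normal((spec.n_freqs, n_times)) + shift
    freqs = np.fft.rfftfreq(spec.window_samples, d=1.0 / spec.fs)
    times = np.arange(n_times) * spec.hop_samples / spec.fs
    return Spectrogram(values=values, freqs_hz=freqs, times_s=times, spec=spec)


def make_labeled_spectrograms(rng, n=24, shift=1.5, prevalence=0.5):
    """Toy two-class spectrogram set with a mean-shift class signal."""
    labels = (rng.random(n) < prevalence).astype(int)
    sgs = [make_spectrogram(rng, shift=shift * lab) for lab in labels]
    return sgs, labels


@pytest.fixture(scope="session")
def tiny_cohort():
    """12 mothers, moderate spectral effect; shared across fast tests."""
    spec = CohortSpec(n_mothers=12, preterm_prevalence=0.33, spectral_effect=1.0, seed=42)
    mothers, cohort = generate_cohort(spec)
    return mothers, cohort
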