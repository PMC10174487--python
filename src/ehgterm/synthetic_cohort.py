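"""Synthetic EHG cohorts with the statistical structure the analysis assumes.

Each synthetic mother gets a 30-minute single-channel abdominal EHG trace,
a clinical covariate row with realistic missingness, a gestational age at
recording (uniform between 26 and 35 weeks) and a gestational age at
delivery drawn from a left-skewed mixture: a Gaussian term component
(mean 280 d, sd 9 d, truncated at >=259 d) plus a preterm component over
[189, 258] d weighted toward later ages.  Delivery before 259 days (37
completed weeks) defines the preterm label.

The signal model sums four components:

* baseline wander — low-pass-filtered integrated noise with energy below
  0.05 Hz;
* contraction bursts — Poisson arrivals (mean 4 per 30 min) of ~60 s
  Hann-shaped envelopes modulating 0.1–0.7 Hz band-limited noise;
* cardiac-harmonic interference — quasi-periodic tones near 1.3 Hz with
  harmonics at 2.6 and 3.9 Hz (uterine reverberation of maternal cardiac
  activity);
* broadband white noise.

A class-dependent spectral shift multiplies the *power* of the components
between 1.0 and 3.5 Hz by ``1 + spectral_effect`` for preterm mothers,
placing the class signal in the higher spectral bands; ``spectral_effect=0``
makes the signal distribution identical across classes.  A clinical odds
multiplier (``clinical_effect``) links smoking and second-trimester
bleeding to the preterm outcome; ``clinical_effect=1`` makes covariates
independent of the label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import signal as sps

from .data_io import (
    CohortTable,
    ClinicalRecord,
    DegenerateCohortError,
    EhgRecording,
    PRETERM_THRESHOLD_DAYS,
)

__all__ = [
    "CohortSpec",
    "SyntheticMother",
    "sample_delivery_age",
    "sample_clinical",
    "synth_ehg",
    "generate_cohort",
]

#: Base rates for the binary covariates, matched to the real cohort's
#: descriptive statistics (positives among non-missing rows).
BASE_BINARY_RATES: dict[str, float] = {
    "parous": 0.32,
    "prev_abortions": 0.13,
    "hypertension": 0.005,
    "diabetes": 0.007,
    "placental_position": 0.53,
    "bleeding_t1": 0.087,
    "bleeding_t2": 0.022,
    "funneling": 0.036,
    "smoker": 0.07,
}

#: Default per-variable missing fractions, matched to the real cohort.
DEFAULT_MISSING_RATES: dict[str, float] = {
    "age": 23 / 159,
    "weight_kg": 30 / 159,
    "hypertension": 21 / 159,
    "diabetes": 21 / 159,
    "placental_position": 31 / 159,
    "bleeding_t1": 21 / 159,
    "bleeding_t2": 21 / 159,
    "funneling": 21 / 159,
}

#: Covariates whose odds are scaled by ``clinical_effect`` for preterm mothers.
EFFECT_COVARIATES = ("smoker", "bleeding_t2")

_TONE_FREQS_HZ = (1.3, 2.6, 3.9)
_TONE_AMPLITUDES = (3.0, 1.5, 0.75)
#: Components with nominal frequency inside this band receive the
#: class-dependent power scaling.
_EFFECT_BAND_HZ = (1.0, 3.5)


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of a synthetic cohort."""

    n_mothers: int
    preterm_prevalence: float = 30 / 159
    fs_raw: float = 20.0
    duration_s: float = 1800.0
    spectral_effect: float = 0.0
    clinical_effect: float = 1.0
    missing_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.preterm_prevalence <= 1.0:
            raise ValueError("preterm_prevalence must lie in [0, 1]")
        for name, rate in self.missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missing rate for {name!r} must lie in [0, 1]")
        n = self.duration_s * self.fs_raw
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s * fs_raw must be an integer sample count")
        if self.spectral_effect < 0:
            raise ValueError("spectral_effect must be non-negative")
        if self.clinical_effect <= 0:
            raise ValueError("clinical_effect must be a positive odds multiplier")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs_raw))


@dataclass
class SyntheticMother:
    id: str
    clinical: ClinicalRecord
    ga_delivery_days: float
    label: str
    signal: EhgRecording

    def __post_init__(self) -> None:
        expected = "preterm" if self.ga_delivery_days < PRETERM_THRESHOLD_DAYS else "term"
        if self.label != expected:
            raise ValueError("label inconsistent with gestational age at delivery")


# ---------------------------------------------------------------------------
# Outcome and covariates
# ---------------------------------------------------------------------------

def sample_delivery_age(spec: CohortSpec, rng: np.random.Generator) -> float:
    """Draw one gestational age at delivery (days) from the mixture."""
    if rng.random() < spec.preterm_prevalence:
        # Triangular over [189, 258] with mode at the upper edge: preterm
        # births concentrate at later gestational ages.
        return float(rng.triangular(189.0, 258.0, 258.0))
    # Term component: Gaussian truncated at the preterm threshold.
    while True:
        draw = rng.normal(280.0, 9.0)
        if draw >= PRETERM_THRESHOLD_DAYS:
            return float(draw)


def _scaled_rate(base: float, odds_multiplier: float) -> float:
    odds = base / (1.0 - base) * odds_multiplier
    return odds / (1.0 + odds)


def sample_clinical(
    spec: CohortSpec,
    label: str,
    rng: np.random.Generator,
    ga_delivery_days: float | None = None,
) -> ClinicalRecord:
    """Draw one clinical covariate row, then mask entries to missingness.

    For preterm mothers the odds of smoking and second-trimester bleeding
    are multiplied by ``clinical_effect``; all other covariates are drawn
    from their base rates regardless of the label.
    """
    if ga_delivery_days is None:
        if label == "preterm":
            ga_delivery_days = float(rng.triangular(189.0, 258.0, 258.0))
        else:
            ga_delivery_days = float(
                max(PRETERM_THRESHOLD_DAYS, rng.normal(280.0, 9.0))
            )

    age = float(np.clip(np.round(rng.normal(29.0, 5.0)), 18, 45))
    weight = float(np.round(rng.normal(72.0, 9.0), 1))
    # Uniform 26–35 completed weeks, capped below the delivery age.
    hi = min(35 * 7, ga_delivery_days - 1.0)
    ga_recording = float(np.floor(rng.uniform(26 * 7 + 1, hi + 1))) if hi >= 26 * 7 + 1 else float(hi)

    values: dict[str, object] = {
        "age": age,
        "weight_kg": weight,
        "ga_recording_days": ga_recording,
        "ga_delivery_days": ga_delivery_days,
    }
    for name, base in BASE_BINARY_RATES.items():
        rate = base
        if name in EFFECT_COVARIATES and label == "preterm":
            rate = _scaled_rate(base, spec.clinical_effect)
        values[name] = bool(rng.random() < rate)
    for name, rate in spec.missing_rates.items():
        if name in values and rng.random() < rate:
            values[name] = None
    return ClinicalRecord(**values)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _bandpass_noise(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfilt(sos, rng.standard_normal(n))


def _quasi_tone(
    n: int, fs: float, freq: float, rng: np.random.Generator
) -> np.ndarray:
    """Narrow-band tone with slow random phase drift (quasi-periodic)."""
    t = np.arange(n) / fs
    # Phase jitter: integrated noise, low-pass to keep the tone narrow-band.
    jitter = np.cumsum(rng.standard_normal(n)) * 0.002
    phase = 2 * np.pi * freq * t + jitter + rng.uniform(0, 2 * np.pi)
    return np.cos(phase)


def synth_ehg(
    spec: CohortSpec, label: str, rng: np.random.Generator
) -> EhgRecording:
    """Synthesise one raw EHG trace for a mother of the given class."""
    n, fs = spec.n_samples, spec.fs_raw
    effect_gain = np.sqrt(1.0 + spec.spectral_effect) if label == "preterm" else 1.0

    # (i) Baseline wander: integrated noise, energy kept below 0.05 Hz.
    sos_lp = sps.butter(2, 0.05, btype="lowpass", fs=fs, output="sos")
    wander = sps.sosfilt(sos_lp, np.cumsum(rng.standard_normal(n))) * 0.02

    # (ii) Contraction bursts: Poisson arrivals, ~60 s Hann envelopes
    # modulating 0.1–0.7 Hz band-limited noise.
    bursts = np.zeros(n)
    n_bursts = rng.poisson(4.0 * spec.duration_s / 1800.0)
    carrier = _bandpass_noise(n, fs, (0.1, 0.7), rng)
    carrier /= max(carrier.std(), 1e-12)
    for _ in range(n_bursts):
        length = int(round(rng.uniform(45.0, 80.0) * fs))
        start = int(rng.integers(0, max(1, n - length)))
        env = np.hanning(length)
        bursts[start : start + length] += 18.0 * env * carrier[start : start + length]

    # (iii) Cardiac-harmonic interference (power-scaled for preterm in
    # the 1.0–3.5 Hz band).
    tones = np.zeros(n)
    for freq, amp in zip(_TONE_FREQS_HZ, _TONE_AMPLITUDES):
        gain = effect_gain if _EFFECT_BAND_HZ[0] <= freq <= _EFFECT_BAND_HZ[1] else 1.0
        tones += amp * gain * _quasi_tone(n, fs, freq, rng)

    # (iv) White noise floor.
    noise = 0.5 * rng.standard_normal(n)

    samples = wander + bursts + tones + noise
    return EhgRecording(
        record_id="synthetic",
        mother_id="synthetic",
        fs=fs,
        samples=samples,
        channel_name="s1",
        source="synthetic",
    )


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec) -> tuple[list[SyntheticMother], CohortTable]:
    """Generate a full cohort, deterministically for a given seed."""
    if spec.n_mothers == 0:
        raise DegenerateCohortError("cannot generate an empty cohort")
    if spec.n_mothers < 10 and 0.0 < spec.preterm_prevalence < 1.0:
        expected_preterm = spec.n_mothers * spec.preterm_prevalence
        if round(expected_preterm) == 0 or round(expected_preterm) == spec.n_mothers:
            raise DegenerateCohortError(
                "cohort too small to contain both outcome classes at this prevalence"
            )
    rng = np.random.default_rng(spec.seed)
    mothers: list[SyntheticMother] = []
    rows: list[tuple[EhgRecording, ClinicalRecord]] = []
    for i in range(spec.n_mothers):
        ga_delivery = sample_delivery_age(spec, rng)
        label = "preterm" if ga_delivery < PRETERM_THRESHOLD_DAYS else "term"
        clinical = sample_clinical(spec, label, rng, ga_delivery_days=ga_delivery)
        recording = synth_ehg(spec, label, rng)
        mother_id = f"m{i:04d}"
        recording.record_id = mother_id
        recording.mother_id = mother_id
        mothers.append(
            SyntheticMother(
                id=mother_id,
                clinical=clinical,
                ga_delivery_days=ga_delivery,
                label=label,
                signal=recording,
            )
        )
        rows.append((recording, clinical))
    return mothers, CohortTable(rows=rows)
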