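"""Information-loss experiments on STFT representations.

Three perturbations probe where the predictive signal lives:

* band extraction — train and test on the STFT rows of one frequency
  band only (B0 0.05–1.0 Hz: mostly contractile activity; B1 1.0–2.2,
  B2 2.2–3.5, B3 3.5–5.0 Hz: cardiac-harmonic reverberation);
* column shuffling — permute a random subset of STFT columns among
  themselves, destroying temporal patterns while preserving every
  column's spectral content;
* cropping — keep a contiguous block of columns equivalent to a shorter
  recording, with a per-sample random start.

Each perturbation is applied identically to training and test data and
the perturbed cohort is pushed through the repeated cross-validation of
the EHG classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import RepeatPlan, repeated_cv
from .models import EhgRecipe, PreparedCohort, prepare_cohort
from .signal_spectral import Spectrogram, TooShortError, frame_count

__all__ = [
    "BandDef",
    "BANDS",
    "PerturbationSpec",
    "extract_band",
    "shuffle_columns",
    "crop_columns",
    "perturbation_experiment",
]


@dataclass(frozen=True)
class BandDef:
    """A contiguous frequency band; half-open on the right unless ``top``."""

    name: str
    lo_hz: float
    hi_hz: float
    top: bool = False  # include the upper edge (the highest band only)


BANDS: dict[str, BandDef] = {
    "B0": BandDef("B0", 0.05, 1.0),
    "B1": BandDef("B1", 1.0, 2.2),
    "B2": BandDef("B2", 2.2, 3.5),
    "B3": BandDef("B3", 3.5, 5.0, top=True),
}


@dataclass(frozen=True)
class PerturbationSpec:
    kind: str  # {"band", "shuffle", "crop"}
    band: BandDef | None = None
    fraction: float | None = None
    duration_s: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        expected = {"band": self.band, "shuffle": self.fraction, "crop": self.duration_s}
        if self.kind not in expected:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if expected[self.kind] is None:
            raise ValueError(f"{self.kind!r} perturbation needs its parameter")
        others = [v for k, v in expected.items() if k != self.kind]
        if any(v is not None for v in others):
            raise ValueError("exactly the fields for the kind must be populated")
        if self.kind == "shuffle" and not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")

    @property
    def label(self) -> str:
        if self.kind == "band":
            return self.band.name
        if self.kind == "shuffle":
            return f"shuffle_{self.fraction:g}"
        return f"crop_{self.duration_s:g}s"


def extract_band(sg: Spectrogram, band: BandDef) -> Spectrogram:
    """Keep only the rows with ``lo <= f < hi`` (``<= hi`` for the top band)."""
    freqs = sg.freqs_hz
    if band.top:
        mask = (freqs >= band.lo_hz) & (freqs <= band.hi_hz)
    else:
        mask = (freqs >= band.lo_hz) & (freqs < band.hi_hz)
    if not mask.any():
        raise ValueError(f"band {band.name} selects no rows of this spectrogram")
    return sg.with_values(sg.values[mask], freqs_hz=freqs[mask])


def shuffle_columns(
    sg: Spectrogram, fraction: float, rng: np.random.Generator
) -> Spectrogram:
    """Permute ``ceil(fraction * T)`` randomly chosen columns among themselves."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    n_cols = sg.n_times
    n_sel = math.ceil(fraction * n_cols)
    if n_sel < 2:
        return sg.with_values(sg.values.copy())
    selected = rng.choice(n_cols, size=n_sel, replace=False)
    permuted = rng.permutation(selected)
    values = sg.values.copy()
    values[:, selected] = sg.values[:, permuted]
    return sg.with_values(values)


def crop_columns(
    sg: Spectrogram, duration_s: float, rng: np.random.Generator
) -> Spectrogram:
    """Keep a contiguous block of columns matching a shorter recording.

    The block length is the frame count of a ``duration_s`` recording at
    the STFT's sampling configuration; the start column is drawn
    uniformly over the feasible positions.
    """
    if duration_s < sg.spec.window_s:
        raise TooShortError("crop duration shorter than one analysis window")
    n_keep = frame_count(int(round(duration_s * sg.spec.fs)), sg.spec)
    n_keep = min(n_keep, sg.n_times)
    start = int(rng.integers(0, sg.n_times - n_keep + 1))
    values = sg.values[:, start : start + n_keep]
    times = sg.times_s[start : start + n_keep]
    return sg.with_values(values, times_s=times)


def _apply(
    spec: PerturbationSpec, sgs: Sequence[Spectrogram]
) -> list[Spectrogram]:
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "band":
        return [extract_band(sg, spec.band) for sg in sgs]
    if spec.kind == "shuffle":
        return [shuffle_columns(sg, spec.fraction, rng) for sg in sgs]
    # Crop start drawn once per sample per experiment.
    return [crop_columns(sg, spec.duration_s, rng) for sg in sgs]


def perturbation_experiment(
    cohort,
    spec_grid: Sequence[PerturbationSpec],
    plan: RepeatPlan,
    recipe: EhgRecipe | None = None,
) -> pd.DataFrame:
    """Mean AUC with 95% CI per grid point, train and test both perturbed."""
    recipe = recipe or EhgRecipe()
    data = cohort if isinstance(cohort, PreparedCohort) else prepare_cohort(cohort)
    rows = []
    for pspec in spec_grid:
        perturbed = PreparedCohort(
            clinical=data.clinical,
            labels=data.labels,
            ga_delivery=data.ga_delivery,
            spectrograms=_apply(pspec, data.spectrograms),
        )
        run_plan = RepeatPlan(plan.n_repeats, plan.k, plan.master_seed)
        result = repeated_cv(perturbed, recipe, run_plan)
        rows.append(
            {
                "perturbation": pspec.label,
                "kind": pspec.kind,
                "auc_mean": result.auc_mean,
                "auc_lo": result.auc_ci[0],
                "auc_hi": result.auc_ci[1],
            }
        )
    return pd.DataFrame(rows)
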