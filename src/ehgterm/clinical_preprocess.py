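"""Fold-scoped clinical feature construction.

Imputation and normalization statistics are fitted exclusively on the
training rows of a cross-validation fold and then applied unchanged to
both training and test rows, so no information from the test set can leak
into model fitting.  Every predictor — continuous ones included — is
imputed with its training-set mode (ties broken toward the smallest
value); predictors are then z-scored with training means and standard
deviations.  Normalization matters only for the L1-regularized logistic
path, where coefficient penalties must not depend on predictor scale; the
unregularized linear-regression path uses the raw imputed features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import ClinicalRecord

__all__ = [
    "FeatureSpec",
    "PreprocessorState",
    "fit_preprocessor",
    "apply_preprocessor",
]

DEFAULT_PREDICTORS = (
    "age",
    "ga_recording_days",
    "weight_kg",
    "parous",
    "prev_abortions",
    "bleeding_t1",
    "bleeding_t2",
    "smoker",
)

EXCLUDED_PREDICTORS = ("hypertension", "diabetes", "funneling", "placental_position")


class UnimputableVariableError(ValueError):
    """A predictor is missing in every training row."""


@dataclass(frozen=True)
class FeatureSpec:
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    excluded: tuple[str, ...] = EXCLUDED_PREDICTORS

    def __post_init__(self) -> None:
        if set(self.predictors) & set(self.excluded):
            raise ValueError("a predictor cannot also be excluded")


@dataclass
class PreprocessorState:
    """Imputation modes and scaling statistics fitted on one training fold.

    ``scaled`` lists the predictors that are z-scored; predictors whose
    training standard deviation is zero are dropped from the scaled set
    and recorded in ``dropped``.
    """

    spec: FeatureSpec
    modes: dict[str, float]
    means: dict[str, float]
    sds: dict[str, float]
    scaled: tuple[str, ...]
    dropped: tuple[str, ...]
    fitted_on: str = ""


def _as_frame(rows: Sequence[ClinicalRecord] | pd.DataFrame, spec: FeatureSpec) -> pd.DataFrame:
    if isinstance(rows, pd.DataFrame):
        frame = rows.loc[:, list(spec.predictors)].copy()
    else:
        frame = pd.DataFrame(
            [{name: getattr(cl, name) for name in spec.predictors} for cl in rows]
        )
    # Booleans encoded 0/1; pandas object columns with None become NaN.
    for name in spec.predictors:
        frame[name] = pd.to_numeric(
            frame[name].map(lambda v: float(v) if v is not None and not pd.isna(v) else np.nan),
            errors="coerce",
        )
    return frame


def fit_preprocessor(
    train_rows: Sequence[ClinicalRecord] | pd.DataFrame,
    spec: FeatureSpec = FeatureSpec(),
    *,
    scale_binary: bool = True,
    fold_id: str = "",
) -> PreprocessorState:
    """Fit imputation modes and scaling statistics from training rows only.

    Modes ignore missing entries; ties break toward the smallest value.
    Means and standard deviations are computed after imputation.
    """
    frame = _as_frame(train_rows, spec)
    if len(frame) == 0:
        raise ValueError("training rows must be non-empty")

    modes: dict[str, float] = {}
    for name in spec.predictors:
        observed = frame[name].dropna()
        if observed.empty:
            raise UnimputableVariableError(f"{name!r} missing in every training row")
        counts = observed.value_counts()
        top = counts.max()
        modes[name] = float(min(counts[counts == top].index))

    imputed = frame.fillna(pd.Series(modes))
    binary = {
        name
        for name in spec.predictors
        if set(np.unique(imputed[name])) <= {0.0, 1.0}
    }
    candidates = [
        name for name in spec.predictors if scale_binary or name not in binary
    ]
    means, sds = {}, {}
    scaled, dropped = [], []
    for name in candidates:
        mu = float(imputed[name].mean())
        sd = float(imputed[name].std(ddof=0))
        if sd <= 0:
            dropped.append(name)
            continue
        means[name], sds[name] = mu, sd
        scaled.append(name)
    return PreprocessorState(
        spec=spec,
        modes=modes,
        means=means,
        sds=sds,
        scaled=tuple(scaled),
        dropped=tuple(dropped),
        fitted_on=fold_id,
    )


def apply_preprocessor(
    state: PreprocessorState,
    rows: Sequence[ClinicalRecord] | pd.DataFrame,
    *,
    normalize: bool = True,
) -> np.ndarray:
    """Impute and (optionally) z-score rows with the fitted state.

    Columns follow the feature-spec order; variables dropped at fit time
    (zero training variance) are left unscaled but retained so the column
    layout is stable.
    """
    frame = _as_frame(rows, state.spec)
    unknown = set(frame.columns) - set(state.spec.predictors)
    if unknown:
        raise ValueError(f"unknown variables: {sorted(unknown)}")
    imputed = frame.fillna(pd.Series(state.modes))
    out = imputed.loc[:, list(state.spec.predictors)].to_numpy(dtype=float)
    if normalize:
        for j, name in enumerate(state.spec.predictors):
            if name in state.sds:
                out[:, j] = (out[:, j] - state.means[name]) / state.sds[name]
    return out
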