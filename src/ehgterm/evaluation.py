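"""Leakage-safe repeated cross-validation and performance statistics.

Evaluation is a stratified five-fold cross-validation repeated 20 times
with fresh random partitions.  Within a repeat, each fold's preprocessors
and models are fitted on training rows only and the five test folds are
pooled into one score vector, giving one AUC per repeat; the reported
value is the mean over repeats with a Student-t 95% confidence interval
(t with n_repeats - 1 degrees of freedom, the Gaussian-unknown-variance
interval).

Also provided: operating-point metrics (sensitivity, PPV, NPV at fixed
specificity via ROC interpolation and the prevalence identity), a
logit-scale AUC confidence interval (Hanley–McNeil standard error), risk
ratios for binary covariates, descriptive cohort summaries, regression
diagnostics, and the noisy-label AUC ceiling implied by gestational-age
dating error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import CohortTable, PRETERM_THRESHOLD_DAYS
from .models import PreparedCohort, prepare_cohort

__all__ = [
    "RepeatPlan",
    "ExperimentResult",
    "stratified_kfold",
    "auc",
    "repeated_cv",
    "metrics_at_specificity",
    "auc_ci_logit",
    "risk_ratio",
    "label_noise_auc_bound",
    "regression_diagnostics",
    "predictor_summary",
]

SPEC_LEVELS = (0.5, 0.7, 0.9)


# ---------------------------------------------------------------------------
# Fold construction
# ---------------------------------------------------------------------------

def stratified_kfold(
    labels: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Class-wise shuffled round-robin fold assignment.

    Every fold receives the same number of preterm samples up to one, and
    fold sizes differ by at most one.
    """
    labels = np.asarray(labels, int)
    if k == 1:
        warnings.warn("k=1 yields a single degenerate fold containing all rows")
        return np.zeros(labels.size, dtype=int)
    assignment = np.empty(labels.size, dtype=int)
    offset = 0
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ValueError(f"class {cls} has {idx.size} rows, fewer than k={k}")
        perm = rng.permutation(idx)
        assignment[perm] = (np.arange(perm.size) + offset) % k
        # Stagger the round-robin start so totals stay balanced.
        offset += perm.size
    return assignment


@dataclass
class RepeatPlan:
    """Per-repeat stratified fold assignments under one master seed."""

    n_repeats: int = 20
    k: int = 5
    master_seed: int = 0
    assignments: list[np.ndarray] = field(default_factory=list)

    def build(self, labels: np.ndarray) -> "RepeatPlan":
        seeds = np.random.SeedSequence(self.master_seed).spawn(self.n_repeats)
        self.assignments = [
            stratified_kfold(labels, self.k, np.random.default_rng(s)) for s in seeds
        ]
        return self

    def repeat_seed(self, repeat: int, fold: int) -> int:
        return (self.master_seed * 1009 + repeat * 131 + fold) % (2**31 - 1)


# ---------------------------------------------------------------------------
# AUC and confidence intervals
# ---------------------------------------------------------------------------

def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann–Whitney AUC; tied score pairs count one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    values = np.asarray(values, float)
    mean = values.mean()
    if values.size < 2:
        return float(mean), float(mean)
    half = stats.t.ppf(0.5 + level / 2, values.size - 1) * values.std(ddof=1) / np.sqrt(
        values.size
    )
    return float(mean - half), float(mean + half)


def auc_ci_logit(auc_value: float, n_pos: int, n_neg: int) -> tuple[float, float]:
    """Logit-method 95% CI with the Hanley–McNeil standard error.

    The interval is built on the log-odds scale and back-transformed, so
    its limits always stay inside (0, 1).
    """
    a = float(auc_value)
    if a <= 0.0 or a >= 1.0:
        warnings.warn("degenerate AUC; clamping for the logit interval")
        # Pull the estimate in by half a Mann-Whitney step so the
        # interval stays strictly inside (0, 1).
        step = 0.5 / (n_pos * n_neg)
        a = min(max(a, step), 1.0 - step)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a**2 / (1.0 + a)
    var = (
        a * (1 - a) + (n_pos - 1) * (q1 - a**2) + (n_neg - 1) * (q2 - a**2)
    ) / (n_pos * n_neg)
    se = np.sqrt(max(var, 0.0))
    logit = np.log(a / (1 - a))
    half = 1.96 * se / (a * (1 - a))
    lo, hi = logit - half, logit + half
    expit = lambda z: 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))
    tiny = np.finfo(float).tiny
    return (
        float(np.clip(expit(lo), tiny, 1.0 - 1e-12)),
        float(np.clip(expit(hi), tiny, 1.0 - 1e-12)),
    )


def risk_ratio(a: int, b: int, c: int, d: int) -> tuple[float, tuple[float, float]]:
    """Risk ratio of the exposed (a preterm, b term) vs unexposed (c, d) arms.

    No continuity correction: a zero count in either numerator leaves the
    ratio undefined and raises.
    """
    if a == 0 or c == 0:
        raise ZeroDivisionError("risk ratio undefined with a zero event count")
    rr = (a / (a + b)) / (c / (c + d))
    se = np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    lo = rr * np.exp(-1.96 * se)
    hi = rr * np.exp(1.96 * se)
    return float(rr), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# Operating-point metrics
# ---------------------------------------------------------------------------

def _roc_points(scores: np.ndarray, labels: np.ndarray):
    """ROC vertices (fpr, tpr) from score thresholds, tie-grouped."""
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tp = np.cumsum(sorted_labels)
    fp = np.cumsum(1 - sorted_labels)
    # Keep only the last index of each tied-score group.
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tpr = np.r_[0.0, tp[distinct] / max(tp[-1], 1)]
    fpr = np.r_[0.0, fp[distinct] / max(fp[-1], 1)]
    return fpr, tpr


def metrics_at_specificity(
    scores: np.ndarray,
    labels: np.ndarray,
    spec_levels: Sequence[float] = SPEC_LEVELS,
) -> pd.DataFrame:
    """Sensitivity, PPV and NPV at fixed specificities.

    Sensitivity comes from linear interpolation between adjacent ROC
    vertices; PPV and NPV follow from the prevalence identity
    ``PPV = sens*pi / (sens*pi + (1-spec)(1-pi))`` and
    ``NPV = spec(1-pi) / (spec(1-pi) + (1-sens)*pi)`` with the sample
    prevalence ``pi``.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required")
    pi = n_pos / labels.size
    fpr, tpr = _roc_points(scores, labels)
    rows = []
    for level in spec_levels:
        sens = float(np.interp(1.0 - level, fpr, tpr))
        ppv = sens * pi / (sens * pi + (1 - level) * (1 - pi))
        npv = level * (1 - pi) / (level * (1 - pi) + (1 - sens) * pi)
        rows.append(
            {"specificity": level, "sensitivity": sens, "ppv": ppv, "npv": npv}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Repeated cross-validation
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    """Pooled per-repeat scores and the summary statistics over repeats."""

    per_repeat_scores: list[np.ndarray]
    per_repeat_labels: list[np.ndarray]
    aucs: np.ndarray
    auc_mean: float
    auc_ci: tuple[float, float]
    operating_table: pd.DataFrame
    regression: pd.DataFrame | None = None


def repeated_cv(
    cohort: CohortTable | PreparedCohort,
    recipe,
    plan: RepeatPlan,
) -> ExperimentResult:
    """Run the recipe through every fold of every repeat and summarise.

    For each repeat the five test folds are pooled into a single score
    vector yielding one AUC (per-fold preterm counts are too small for
    stable per-fold AUCs); the mean and the t-based 95% CI over repeats
    are reported, along with the mean operating table.  Regression
    recipes additionally report pooled regression diagnostics.
    """
    if isinstance(cohort, PreparedCohort):
        data = cohort
    else:
        data = prepare_cohort(cohort, with_signals=getattr(recipe, "needs_signals", True))
    labels = data.labels
    if not plan.assignments:
        plan.build(labels)
    per_scores, per_labels, aucs = [], [], []
    op_tables = []
    reg_rows = []
    for r, folds in enumerate(plan.assignments):
        scores = np.empty(labels.size, dtype=float)
        pred_days = np.full(labels.size, np.nan)
        for fold in range(plan.k):
            test_idx = np.flatnonzero(folds == fold)
            train_idx = np.flatnonzero(folds != fold)
            out = recipe.fit_score(data, train_idx, test_idx, plan.repeat_seed(r, fold))
            scores[test_idx] = out["scores"]
            if "pred_days" in out:
                pred_days[test_idx] = out["pred_days"]
        per_scores.append(scores)
        per_labels.append(labels.copy())
        aucs.append(auc(scores, labels))
        op_tables.append(metrics_at_specificity(scores, labels))
        if not np.isnan(pred_days).any():
            reg_rows.append(regression_diagnostics(pred_days, data.ga_delivery))
    aucs = np.array(aucs)
    ops = pd.concat(op_tables)
    summary = []
    for level, group in ops.groupby("specificity"):
        row = {"specificity": level}
        for metric in ("sensitivity", "ppv", "npv"):
            lo, hi = _t_ci(group[metric].to_numpy())
            row[metric] = group[metric].mean()
            row[f"{metric}_lo"], row[f"{metric}_hi"] = lo, hi
        summary.append(row)
    regression = pd.DataFrame(reg_rows) if reg_rows else None
    return ExperimentResult(
        per_repeat_scores=per_scores,
        per_repeat_labels=per_labels,
        aucs=aucs,
        auc_mean=float(aucs.mean()),
        auc_ci=_t_ci(aucs),
        operating_table=pd.DataFrame(summary),
        regression=regression,
    )


# ---------------------------------------------------------------------------
# Noisy-label AUC ceiling
# ---------------------------------------------------------------------------

def label_noise_auc_bound(
    ga_delivery_days: Sequence[float],
    sd_days: float = 6.0,
    reps: int = 20,
    rng: np.random.Generator | None = None,
) -> tuple[float, tuple[float, float]]:
    """AUC ceiling implied by gestational-age dating error.

    Each subject is scored by the negated noisy delivery age,
    ``-(ga + eps)`` with ``eps ~ N(0, sd_days^2)``, against the true
    259-day label; the mean AUC over ``reps`` draws with its t-based 95%
    CI estimates the best any classifier could do given that the labels
    themselves carry this dating uncertainty.
    """
    ga = np.asarray(ga_delivery_days, float)
    labels = (ga < PRETERM_THRESHOLD_DAYS).astype(int)
    if labels.sum() in (0, labels.size):
        raise ValueError("both classes required under the 259-day rule")
    rng = np.random.default_rng() if rng is None else rng
    values = [
        auc(-(ga + rng.normal(0.0, sd_days, size=ga.size)), labels)
        for _ in range(reps)
    ]
    values = np.array(values)
    return float(values.mean()), _t_ci(values)


# ---------------------------------------------------------------------------
# Regression diagnostics and cohort summaries
# ---------------------------------------------------------------------------

def regression_diagnostics(
    predicted_days: np.ndarray, true_days: np.ndarray
) -> dict[str, float]:
    """RMSE, R^2, least-squares slope and Bland–Altman agreement limits."""
    pred = np.asarray(predicted_days, float)
    true = np.asarray(true_days, float)
    if pred.shape != true.shape:
        raise ValueError("length mismatch")
    if pred.size < 3:
        raise ValueError("need at least three pairs")
    resid = pred - true
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((true - true.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    var_true = float(np.var(true))
    slope = (
        float(np.cov(true, pred, bias=True)[0, 1] / var_true) if var_true > 0 else np.nan
    )
    diff_mean = float(resid.mean())
    diff_sd = float(resid.std(ddof=1)) if pred.size > 1 else 0.0
    return {
        "rmse": rmse,
        "r2": r2,
        "slope": slope,
        "bland_altman_mean": diff_mean,
        "bland_altman_lo": diff_mean - 1.96 * diff_sd,
        "bland_altman_hi": diff_mean + 1.96 * diff_sd,
    }


CONTINUOUS_SUMMARY_VARS = ("age", "ga_recording_days", "weight_kg")
BINARY_SUMMARY_VARS = (
    "parous",
    "prev_abortions",
    "hypertension",
    "diabetes",
    "placental_position",
    "bleeding_t1",
    "bleeding_t2",
    "funneling",
    "smoker",
)


def predictor_summary(
    clinical: pd.DataFrame, labels: np.ndarray
) -> dict[str, pd.DataFrame]:
    """Descriptive cohort report: distributions and univariate predictive power.

    Continuous predictors get median, IQR, missing count, and the AUC
    (value used directly as a preterm score) with a logit-method CI.
    Binary predictors get the positive count, the percent positive among
    non-missing rows, the missing count, and the risk ratio with CI
    (``NaN`` where a zero cell leaves it undefined).
    """
    labels = np.asarray(labels, int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    cont_rows = []
    for name in CONTINUOUS_SUMMARY_VARS:
        if name not in clinical.columns:
            continue
        col = pd.to_numeric(clinical[name], errors="coerce")
        observed = col.dropna()
        n_missing = int(col.isna().sum())
        row = {
            "variable": name,
            "median": float(observed.median()),
            "iqr_lo": float(observed.quantile(0.25)),
            "iqr_hi": float(observed.quantile(0.75)),
            "n_missing": n_missing,
        }
        mask = ~col.isna().to_numpy()
        sub_labels = labels[mask]
        if 0 < sub_labels.sum() < sub_labels.size:
            a = auc(col.to_numpy()[mask], sub_labels)
            lo, hi = auc_ci_logit(a, int(sub_labels.sum()), int(sub_labels.size - sub_labels.sum()))
            row.update({"auc": a, "auc_lo": lo, "auc_hi": hi})
        else:
            row.update({"auc": np.nan, "auc_lo": np.nan, "auc_hi": np.nan})
        cont_rows.append(row)

    bin_rows = []
    for name in BINARY_SUMMARY_VARS:
        if name not in clinical.columns:
            continue
        col = clinical[name]
        missing = col.isna()
        observed = col[~missing].astype(bool)
        positives = int(observed.sum())
        denom = int((~missing).sum())
        row = {
            "variable": name,
            "n_positive": positives,
            "pct_positive": 100.0 * positives / denom if denom else np.nan,
            "n_missing": int(missing.sum()),
        }
        obs_labels = labels[~missing.to_numpy()]
        a = int(((observed.to_numpy()) & (obs_labels == 1)).sum())
        b = int(((observed.to_numpy()) & (obs_labels == 0)).sum())
        c = int(((~observed.to_numpy()) & (obs_labels == 1)).sum())
        d = int(((~observed.to_numpy()) & (obs_labels == 0)).sum())
        try:
            rr, (lo, hi) = risk_ratio(a, b, c, d)
        except ZeroDivisionError:
            rr, lo, hi = np.nan, np.nan, np.nan
        row.update({"risk_ratio": rr, "rr_lo": lo, "rr_hi": hi})
        bin_rows.append(row)

    overview = pd.DataFrame(
        [
            {
                "n_participants": labels.size,
                "n_preterm": n_pos,
                "pct_preterm": 100.0 * n_pos / labels.size,
            }
        ]
    )
    return {
        "overview": overview,
        "continuous": pd.DataFrame(cont_rows),
        "binary": pd.DataFrame(bin_rows),
    }
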