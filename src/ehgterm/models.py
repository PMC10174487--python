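"""The three predictor families for preterm-birth prediction.

* Clinical-only models: an L1-regularized (lasso) logistic regression for
  the categorical outcome and an unregularized ordinary-least-squares
  regression for the gestational age at delivery (classified afterwards
  with the 259-day threshold).
* The EHG sequence model: a bidirectional LSTM reading STFT columns as
  time steps, a two-unit fully connected layer on the final step, and
  either a softmax head trained with a class-weighted cross-entropy or a
  linear head trained with mean squared error.  The class weights
  ``w_i = 2 * S_{1-i} / (S_0 + S_1)`` upweight errors on the minority
  (preterm) class in proportion to the imbalance; they always sum to 2
  and reduce to unit weights for balanced classes.
* Combined models: the two fully-connected activations of a sequence
  network trained on the training fold are concatenated with the clinical
  features and fed to the clinical-model fits.

The recurrent network is implemented directly on numpy with manual
backpropagation through time and an Adam optimizer; gradients are
verified against finite differences in the test suite.  Training is fully
deterministic given the configured seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .clinical_preprocess import FeatureSpec, apply_preprocessor, fit_preprocessor
from .data_io import CohortTable, PRETERM_THRESHOLD_DAYS
from .signal_spectral import FilterSpec, Spectrogram, StftSpec, compute_stft, condition_signal

__all__ = [
    "ClassWeights",
    "NetworkSpec",
    "TrainConfig",
    "class_weights",
    "weighted_cross_entropy",
    "weighted_cross_entropy_grad",
    "SequenceModel",
    "train_sequence_model",
    "extract_fc_activations",
    "fit_logistic_lasso",
    "fit_linear_regression",
    "fit_combined",
    "PreparedCohort",
    "prepare_cohort",
    "ClinicalRecipe",
    "EhgRecipe",
    "CombinedRecipe",
]

SCORE_EPS = 1e-12
#: Internal centering of the regression target (days); typical term delivery.
TARGET_CENTER_DAYS = 280.0
TARGET_SCALE_DAYS = 20.0


# ---------------------------------------------------------------------------
# Class weights and weighted cross-entropy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassWeights:
    """Penalization weights derived from training class counts.

    ``w0`` applies to term (label 0), ``w1`` to preterm (label 1);
    ``s0``/``s1`` are the training counts they were derived from.
    """

    w0: float
    w1: float
    s0: int
    s1: int


def class_weights(s0: int, s1: int) -> ClassWeights:
    """``w_i = 2 * S_{1-i} / (S_0 + S_1)`` — upweights the rarer class."""
    if s0 < 1 or s1 < 1:
        raise ValueError("both classes need at least one training sample")
    total = s0 + s1
    return ClassWeights(w0=2.0 * s1 / total, w1=2.0 * s0 / total, s0=s0, s1=s1)


def weighted_cross_entropy(
    scores: np.ndarray, labels: np.ndarray, w: ClassWeights
) -> float:
    """Mean class-weighted cross-entropy of preterm probabilities.

    ``-(1/N) * sum[w1*T*ln(y) + w0*(1-T)*ln(1-y)]`` with scores clamped
    away from {0, 1}.
    """
    y = np.clip(np.asarray(scores, float), SCORE_EPS, 1.0 - SCORE_EPS)
    t = np.asarray(labels, float)
    if y.shape != t.shape:
        raise ValueError("scores and labels must align")
    terms = w.w1 * t * np.log(y) + w.w0 * (1.0 - t) * np.log(1.0 - y)
    return float(-np.mean(terms))


def weighted_cross_entropy_grad(
    scores: np.ndarray, labels: np.ndarray, w: ClassWeights
) -> np.ndarray:
    """Analytic gradient of the weighted cross-entropy w.r.t. the scores."""
    y = np.clip(np.asarray(scores, float), SCORE_EPS, 1.0 - SCORE_EPS)
    t = np.asarray(labels, float)
    return -(w.w1 * t / y - w.w0 * (1.0 - t) / (1.0 - y)) / y.size


# ---------------------------------------------------------------------------
# Sequence network (numpy BiLSTM)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkSpec:
    input_size: int = 301
    bilstm_hidden: int = 100
    fc_units: int = 2
    head: str = "softmax_classifier"  # or "regression"

    def __post_init__(self) -> None:
        if self.fc_units != 2:
            raise ValueError("the fully connected layer has two units")
        if self.head not in {"softmax_classifier", "regression"}:
            raise ValueError(f"unknown head {self.head!r}")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 16
    epochs: int = 60
    learning_rate: float = 1e-3
    l2_penalty: float = 1e-4
    grad_clip: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.epochs) < 1 or self.learning_rate <= 0:
            raise ValueError("batch size, epochs and learning rate must be positive")
        if self.l2_penalty < 0 or self.grad_clip <= 0:
            raise ValueError("l2_penalty must be >= 0 and grad_clip > 0")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _init_lstm(rng: np.random.Generator, d: int, h: int) -> dict[str, np.ndarray]:
    sx = np.sqrt(6.0 / (d + 4 * h))
    sh = np.sqrt(6.0 / (h + 4 * h))
    params = {
        "Wx": rng.uniform(-sx, sx, size=(d, 4 * h)),
        "Wh": rng.uniform(-sh, sh, size=(h, 4 * h)),
        "b": np.zeros(4 * h),
    }
    params["b"][h : 2 * h] = 1.0  # forget-gate bias
    return params


def _lstm_forward(params: dict[str, np.ndarray], x: np.ndarray, reverse: bool):
    """Run one LSTM direction over x (B, T, D); returns final h and caches."""
    B, T, _ = x.shape
    h_dim = params["Wh"].shape[0]
    order = range(T - 1, -1, -1) if reverse else range(T)
    h = np.zeros((B, h_dim))
    c = np.zeros((B, h_dim))
    caches = []
    for t in order:
        z = x[:, t, :] @ params["Wx"] + h @ params["Wh"] + params["b"]
        i = _sigmoid(z[:, :h_dim])
        f = _sigmoid(z[:, h_dim : 2 * h_dim])
        g = np.tanh(z[:, 2 * h_dim : 3 * h_dim])
        o = _sigmoid(z[:, 3 * h_dim :])
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        caches.append((t, h, c, i, f, g, o, tanh_c))
        h, c = h_new, c_new
    return h, caches


def _lstm_backward(
    params: dict[str, np.ndarray],
    x: np.ndarray,
    caches: list,
    dh_last: np.ndarray,
) -> tuple[dict[str, np.ndarray], None]:
    """Backprop through time; gradient enters only at the final state."""
    h_dim = params["Wh"].shape[0]
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    dh = dh_last.copy()
    dc = np.zeros_like(dh)
    for t, h_prev, c_prev, i, f, g, o, tanh_c in reversed(caches):
        do = dh * tanh_c
        dc = dc + dh * o * (1.0 - tanh_c**2)
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g**2),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        grads["Wx"] += x[:, t, :].T @ dz
        grads["Wh"] += h_prev.T @ dz
        grads["b"] += dz.sum(axis=0)
        dh = dz @ params["Wh"].T
        dc = dc * f
    return grads, None


class SequenceModel:
    """BiLSTM sequence classifier/regressor over STFT column sequences.

    Holds the fold-scoped per-frequency standardization statistics, the
    network parameters, and (for classification) the training-fold class
    weights, so that prediction on new spectrograms is self-contained.
    """

    def __init__(self, spec: NetworkSpec, cfg: TrainConfig):
        self.spec = spec
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        h = spec.bilstm_hidden
        self.fwd = _init_lstm(rng, spec.input_size, h)
        self.bwd = _init_lstm(rng, spec.input_size, h)
        s_fc = np.sqrt(6.0 / (2 * h + 2))
        self.fc_W = rng.uniform(-s_fc, s_fc, size=(2 * h, 2))
        self.fc_b = np.zeros(2)
        if spec.head == "regression":
            self.out_W = rng.uniform(-1.0, 1.0, size=(2, 1))
            self.out_b = np.zeros(1)
        self.row_mean: np.ndarray | None = None
        self.row_sd: np.ndarray | None = None
        self.weights: ClassWeights | None = None
        self._rng = rng

    # -- parameter bookkeeping ------------------------------------------------

    def _params(self) -> dict[str, np.ndarray]:
        params = {
            "f_Wx": self.fwd["Wx"],
            "f_Wh": self.fwd["Wh"],
            "f_b": self.fwd["b"],
            "b_Wx": self.bwd["Wx"],
            "b_Wh": self.bwd["Wh"],
            "b_b": self.bwd["b"],
            "fc_W": self.fc_W,
            "fc_b": self.fc_b,
        }
        if self.spec.head == "regression":
            params["out_W"] = self.out_W
            params["out_b"] = self.out_b
        return params

    # -- featurization --------------------------------------------------------

    def _to_batch(self, sgs: Sequence[Spectrogram]) -> np.ndarray:
        shapes = {sg.values.shape for sg in sgs}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent spectrogram shapes: {sorted(shapes)}")
        (rows, _), = shapes
        if rows != self.spec.input_size:
            raise ValueError(
                f"spectrogram rows {rows} != network input size {self.spec.input_size}"
            )
        x = np.stack([sg.values.T for sg in sgs])  # (B, T, F)
        if self.row_mean is not None:
            x = (x - self.row_mean) / self.row_sd
        return x

    def fit_scaler(self, sgs: Sequence[Spectrogram]) -> None:
        """Per-frequency-row standardization statistics from training data."""
        stacked = np.concatenate([sg.values for sg in sgs], axis=1)
        self.row_mean = stacked.mean(axis=1)
        sd = stacked.std(axis=1)
        self.row_sd = np.where(sd > 0, sd, 1.0)

    # -- forward/backward -----------------------------------------------------

    def _forward(self, x: np.ndarray):
        h_f, cache_f = _lstm_forward(self.fwd, x, reverse=False)
        h_b, cache_b = _lstm_forward(self.bwd, x, reverse=True)
        h_cat = np.concatenate([h_f, h_b], axis=1)
        acts = h_cat @ self.fc_W + self.fc_b
        return acts, (x, h_cat, cache_f, cache_b)

    def _backward(self, dacts: np.ndarray, cache) -> dict[str, np.ndarray]:
        x, h_cat, cache_f, cache_b = cache
        h = self.spec.bilstm_hidden
        grads = {
            "fc_W": h_cat.T @ dacts,
            "fc_b": dacts.sum(axis=0),
        }
        dh_cat = dacts @ self.fc_W.T
        gf, _ = _lstm_backward(self.fwd, x, cache_f, dh_cat[:, :h])
        gb, _ = _lstm_backward(self.bwd, x, cache_b, dh_cat[:, h:])
        grads.update({"f_" + k: v for k, v in gf.items()})
        grads.update({"b_" + k: v for k, v in gb.items()})
        return grads

    def _loss_and_grads(self, x: np.ndarray, targets: np.ndarray):
        acts, cache = self._forward(x)
        if self.spec.head == "softmax_classifier":
            shifted = acts - acts.max(axis=1, keepdims=True)
            expd = np.exp(shifted)
            probs = expd / expd.sum(axis=1, keepdims=True)
            y = np.clip(probs[:, 1], SCORE_EPS, 1 - SCORE_EPS)
            w = self.weights
            loss = weighted_cross_entropy(y, targets, w)
            n = targets.size
            da1 = (-w.w1 * targets * (1 - y) + w.w0 * (1 - targets) * y) / n
            dacts = np.stack([-da1, da1], axis=1)
            grads = self._backward(dacts, cache)
        else:
            out = (acts @ self.out_W + self.out_b)[:, 0]
            resid = out - targets
            loss = float(np.mean(resid**2))
            dout = (2.0 / targets.size) * resid[:, None]
            grads = self._backward(dout @ self.out_W.T, cache)
            grads["out_W"] = acts.T @ dout
            grads["out_b"] = dout.sum(axis=0)
        return loss, grads

    # -- training -------------------------------------------------------------

    def fit(self, sgs: Sequence[Spectrogram], targets: np.ndarray) -> "SequenceModel":
        targets = np.asarray(targets, dtype=float)
        if len(sgs) == 0:
            raise ValueError("empty training set")
        if self.spec.head == "softmax_classifier":
            s1 = int(targets.sum())
            s0 = targets.size - s1
            if s0 == 0 or s1 == 0:
                raise ValueError("classification needs both classes in training")
            self.weights = class_weights(s0, s1)
            y_train = targets
        else:
            y_train = (targets - TARGET_CENTER_DAYS) / TARGET_SCALE_DAYS
        self.fit_scaler(sgs)
        x_all = self._to_batch(sgs)

        params = self._params()
        adam_m = {k: np.zeros_like(v) for k, v in params.items()}
        adam_v = {k: np.zeros_like(v) for k, v in params.items()}
        step = 0
        n = len(sgs)
        rng = np.random.default_rng(self.cfg.seed + 1)
        for _ in range(self.cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.cfg.batch_size):
                idx = order[start : start + self.cfg.batch_size]
                _, grads = self._loss_and_grads(x_all[idx], y_train[idx])
                # L2 on weight matrices (not biases).
                for k in grads:
                    if not k.endswith("b"):
                        grads[k] = grads[k] + self.cfg.l2_penalty * params[k]
                norm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
                if norm > self.cfg.grad_clip:
                    scale = self.cfg.grad_clip / norm
                    grads = {k: g * scale for k, g in grads.items()}
                step += 1
                for k, g in grads.items():
                    adam_m[k] = 0.9 * adam_m[k] + 0.1 * g
                    adam_v[k] = 0.999 * adam_v[k] + 0.001 * g**2
                    m_hat = adam_m[k] / (1 - 0.9**step)
                    v_hat = adam_v[k] / (1 - 0.999**step)
                    params[k] -= self.cfg.learning_rate * m_hat / (np.sqrt(v_hat) + 1e-8)
        return self

    # -- inference ------------------------------------------------------------

    def activations(self, sgs: Sequence[Spectrogram]) -> np.ndarray:
        """Pre-softmax two-unit fully-connected activations, one row per input."""
        acts, _ = self._forward(self._to_batch(sgs))
        return acts

    def predict_proba(self, sgs: Sequence[Spectrogram]) -> np.ndarray:
        """Preterm-class probability per input (classification head)."""
        if self.spec.head != "softmax_classifier":
            raise ValueError("probabilities require the classification head")
        acts = self.activations(sgs)
        shifted = acts - acts.max(axis=1, keepdims=True)
        expd = np.exp(shifted)
        return (expd / expd.sum(axis=1, keepdims=True))[:, 1]

    def predict_days(self, sgs: Sequence[Spectrogram]) -> np.ndarray:
        """Predicted gestational age at delivery in days (regression head)."""
        if self.spec.head != "regression":
            raise ValueError("day predictions require the regression head")
        acts = self.activations(sgs)
        out = (acts @ self.out_W + self.out_b)[:, 0]
        return out * TARGET_SCALE_DAYS + TARGET_CENTER_DAYS


def train_sequence_model(
    train: Sequence[tuple[Spectrogram, float]],
    spec: NetworkSpec,
    cfg: TrainConfig,
) -> SequenceModel:
    """Fit a sequence network on (spectrogram, target) pairs.

    Targets are 0/1 labels for the classification head and gestational
    ages at delivery (days) for the regression head.
    """
    sgs = [sg for sg, _ in train]
    targets = np.array([t for _, t in train], dtype=float)
    return SequenceModel(spec, cfg).fit(sgs, targets)


def extract_fc_activations(model: SequenceModel, sg: Spectrogram) -> np.ndarray:
    """The deterministic two-unit pre-softmax activation vector for one input."""
    return model.activations([sg])[0]


# ---------------------------------------------------------------------------
# Clinical models
# ---------------------------------------------------------------------------

class LogisticLassoModel:
    """L1-penalized logistic regression with inner-CV penalty selection."""

    def __init__(self, coef: np.ndarray, intercept: float, lam: float):
        self.coef_ = np.asarray(coef, float)
        self.intercept_ = float(intercept)
        self.lambda_ = lam

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(np.asarray(X, float) @ self.coef_ + self.intercept_)


DEFAULT_LAMBDA_GRID = tuple(np.logspace(-2.0, 2.0, 13))


def _soft_threshold(x: float, t: float) -> float:
    return np.sign(x) * max(abs(x) - t, 0.0)


def _cd_lasso_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    w: np.ndarray | None = None,
    b: float | None = None,
    max_irls: int = 100,
    tol: float = 1e-9,
) -> tuple[np.ndarray, float]:
    """Minimize ``sum_i logloss_i + lam * ||w||_1`` (intercept unpenalized).

    Outer loop: iteratively reweighted least squares.  Inner loop: cyclic
    coordinate descent with soft thresholding on the weighted quadratic
    surrogate — this solver drives coefficients exactly to zero, so fully
    redundant columns keep at most one nonzero weight and an infinite
    penalty recovers the intercept-only (prevalence) model.
    """
    n, p = X.shape
    w = np.zeros(p) if w is None else w.astype(float).copy()
    ybar = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
    b = float(np.log(ybar / (1 - ybar))) if b is None else float(b)
    for _ in range(max_irls):
        eta = X @ w + b
        mu = _sigmoid(eta)
        v = np.clip(mu * (1 - mu), 1e-6, None)
        z = eta + (y - mu) / v
        w_prev, b_prev = w.copy(), b
        r = z - X @ w - b
        for _ in range(100):
            max_delta = 0.0
            for j in range(p):
                r += X[:, j] * w[j]
                rho = float(np.dot(v * X[:, j], r))
                denom = float(np.dot(v, X[:, j] ** 2))
                new = _soft_threshold(rho, lam) / denom if denom > 0 else 0.0
                max_delta = max(max_delta, abs(new - w[j]))
                r -= X[:, j] * new
                w[j] = new
            db = float(np.dot(v, r) / v.sum())
            b += db
            r -= db
            if max(max_delta, abs(db)) < tol:
                break
        if max(float(np.max(np.abs(w - w_prev), initial=0.0)), abs(b - b_prev)) < tol:
            break
    return w, b


def fit_logistic_lasso(
    X: np.ndarray,
    y: np.ndarray,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    seed: int = 0,
) -> LogisticLassoModel:
    """Sparse logistic fit; the penalty is picked by inner 5-fold deviance.

    ``lambda_grid`` holds inverse-C penalties; a single value skips the
    inner cross-validation, and 0 fits an unpenalized model.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    if X.size == 0:
        raise ValueError("empty feature matrix")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present")

    def fit_one(X_fit, y_fit, lam):
        if lam == 0.0:
            est = LogisticRegression(C=np.inf, max_iter=20000, tol=1e-8)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(X_fit, y_fit)
            return est.coef_.ravel(), float(est.intercept_[0])
        return _cd_lasso_logistic(X_fit, y_fit, lam)

    lams = sorted({float(l) for l in lambda_grid}, reverse=True)
    if len(lams) == 1:
        coef, intercept = fit_one(X, y, lams[0])
        return LogisticLassoModel(coef, intercept, lams[0])

    min_class = int(np.bincount(y).min())
    n_splits = min(5, max(2, min_class))
    inner = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    deviance = np.zeros(len(lams))
    for train_idx, val_idx in inner.split(X, y):
        for i, lam in enumerate(lams):
            coef, intercept = fit_one(X[train_idx], y[train_idx], lam)
            prob = np.clip(
                _sigmoid(X[val_idx] @ coef + intercept), SCORE_EPS, 1 - SCORE_EPS
            )
            y_val = y[val_idx]
            deviance[i] -= float(
                np.sum(y_val * np.log(prob) + (1 - y_val) * np.log(1 - prob))
            )
    best = lams[int(np.argmin(deviance))]
    coef, intercept = fit_one(X, y, best)
    return LogisticLassoModel(coef, intercept, best)


class LinearRegressionModel:
    """Ordinary least squares on gestational age at delivery (days)."""

    def __init__(self, beta: np.ndarray, rank_deficient: bool):
        self.beta = beta
        self.rank_deficient = rank_deficient

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        return X @ self.beta[1:] + self.beta[0]

    def predict_label(self, X: np.ndarray) -> np.ndarray:
        """1 = preterm, via the 259-day threshold on predicted days."""
        return (self.predict(X) < PRETERM_THRESHOLD_DAYS).astype(int)


def fit_linear_regression(X: np.ndarray, t: np.ndarray) -> LinearRegressionModel:
    """Unregularized OLS of delivery age (days) on the feature matrix."""
    X = np.asarray(X, float)
    t = np.asarray(t, float)
    design = np.column_stack([np.ones(len(X)), X])
    beta, _, rank, _ = np.linalg.lstsq(design, t, rcond=None)
    deficient = rank < design.shape[1]
    if deficient:
        warnings.warn("rank-deficient design; pseudo-inverse solution used")
    return LinearRegressionModel(beta=beta, rank_deficient=deficient)


def fit_combined(
    clinical_features: np.ndarray,
    activations: np.ndarray,
    y_or_t: np.ndarray,
    head: str = "cls",
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    seed: int = 0,
):
    """Fit the combined model on clinical features ++ network activations."""
    clinical_features = np.asarray(clinical_features, float)
    activations = np.asarray(activations, float)
    if clinical_features.shape[0] != activations.shape[0]:
        raise ValueError("misaligned rows between clinical features and activations")
    X = np.column_stack([clinical_features, activations])
    if head == "cls":
        return fit_logistic_lasso(X, y_or_t, lambda_grid=lambda_grid, seed=seed)
    return fit_linear_regression(X, y_or_t)


# ---------------------------------------------------------------------------
# Fold-scoped model recipes for cross-validated evaluation
# ---------------------------------------------------------------------------

@dataclass
class PreparedCohort:
    """Featurized cohort shared across folds (no fold-scoped statistics).

    Spectrogram computation and the clinical table are label-free
    transforms of each sample individually, so computing them once for the
    whole cohort introduces no leakage; imputation, scaling, and model
    fits remain strictly fold-scoped inside the recipes.
    """

    clinical: pd.DataFrame
    labels: np.ndarray
    ga_delivery: np.ndarray
    spectrograms: list[Spectrogram] | None = None

    def __len__(self) -> int:
        return len(self.labels)


def prepare_cohort(
    cohort: CohortTable,
    *,
    with_signals: bool = True,
    filter_spec: FilterSpec = FilterSpec(),
    stft_spec: StftSpec = StftSpec(),
) -> PreparedCohort:
    """Condition and featurize every recording once; gather the tables."""
    frame = cohort.clinical_frame()
    labels = cohort.labels
    ga = np.array([cl.ga_delivery_days for cl in cohort.clinical])
    sgs = None
    if with_signals:
        sgs = [
            compute_stft(condition_signal(rec, filter_spec, fs_out=stft_spec.fs), stft_spec)
            for rec in cohort.signals
        ]
    return PreparedCohort(clinical=frame, labels=labels, ga_delivery=ga, spectrograms=sgs)


def _zscore_train_apply(train: np.ndarray, other: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (other - mu) / sd


@dataclass
class ClinicalRecipe:
    """Clinical-only predictor: lasso-logistic (cls) or OLS (reg)."""

    head: str = "cls"
    feature_spec: FeatureSpec = field(default_factory=FeatureSpec)
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID
    needs_signals = False

    def fit_score(
        self, data: PreparedCohort, train_idx: np.ndarray, test_idx: np.ndarray, seed: int
    ) -> dict[str, np.ndarray]:
        train_rows = data.clinical.iloc[train_idx]
        test_rows = data.clinical.iloc[test_idx]
        state = fit_preprocessor(train_rows, self.feature_spec)
        if self.head == "cls":
            X_train = apply_preprocessor(state, train_rows, normalize=True)
            X_test = apply_preprocessor(state, test_rows, normalize=True)
            model = fit_logistic_lasso(
                X_train, data.labels[train_idx], lambda_grid=self.lambda_grid, seed=seed
            )
            return {"scores": model.predict_proba(X_test)}
        X_train = apply_preprocessor(state, train_rows, normalize=False)
        X_test = apply_preprocessor(state, test_rows, normalize=False)
        model = fit_linear_regression(X_train, data.ga_delivery[train_idx])
        pred = model.predict(X_test)
        return {"scores": -pred, "pred_days": pred}


@dataclass
class EhgRecipe:
    """EHG-only predictor: the BiLSTM sequence network."""

    head: str = "cls"
    net_spec: NetworkSpec | None = None
    train_cfg: TrainConfig = field(default_factory=TrainConfig)
    needs_signals = True

    def _network_spec(self, data: PreparedCohort) -> NetworkSpec:
        rows = data.spectrograms[0].n_freqs
        base = self.net_spec or NetworkSpec()
        head = "softmax_classifier" if self.head == "cls" else "regression"
        return NetworkSpec(
            input_size=rows, bilstm_hidden=base.bilstm_hidden, head=head
        )

    def _fit_network(
        self, data: PreparedCohort, train_idx: np.ndarray, seed: int
    ) -> SequenceModel:
        spec = self._network_spec(data)
        cfg = TrainConfig(
            batch_size=self.train_cfg.batch_size,
            epochs=self.train_cfg.epochs,
            learning_rate=self.train_cfg.learning_rate,
            l2_penalty=self.train_cfg.l2_penalty,
            grad_clip=self.train_cfg.grad_clip,
            seed=seed,
        )
        sgs = [data.spectrograms[i] for i in train_idx]
        targets = (
            data.labels[train_idx]
            if self.head == "cls"
            else data.ga_delivery[train_idx]
        )
        return SequenceModel(spec, cfg).fit(sgs, np.asarray(targets, float))

    def fit_score(
        self, data: PreparedCohort, train_idx: np.ndarray, test_idx: np.ndarray, seed: int
    ) -> dict[str, np.ndarray]:
        model = self._fit_network(data, train_idx, seed)
        test_sgs = [data.spectrograms[i] for i in test_idx]
        if self.head == "cls":
            return {"scores": model.predict_proba(test_sgs)}
        pred = model.predict_days(test_sgs)
        return {"scores": -pred, "pred_days": pred}


@dataclass
class CombinedRecipe:
    """Clinical features concatenated with fold-trained network activations."""

    head: str = "cls"
    feature_spec: FeatureSpec = field(default_factory=FeatureSpec)
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID
    net_spec: NetworkSpec | None = None
    train_cfg: TrainConfig = field(default_factory=TrainConfig)
    needs_signals = True

    def fit_score(
        self, data: PreparedCohort, train_idx: np.ndarray, test_idx: np.ndarray, seed: int
    ) -> dict[str, np.ndarray]:
        ehg = EhgRecipe(head=self.head, net_spec=self.net_spec, train_cfg=self.train_cfg)
        network = ehg._fit_network(data, train_idx, seed)
        acts_train = network.activations([data.spectrograms[i] for i in train_idx])
        acts_test = network.activations([data.spectrograms[i] for i in test_idx])

        state = fit_preprocessor(data.clinical.iloc[train_idx], self.feature_spec)
        if self.head == "cls":
            X_train = apply_preprocessor(state, data.clinical.iloc[train_idx], normalize=True)
            X_test = apply_preprocessor(state, data.clinical.iloc[test_idx], normalize=True)
            a_train, a_test = _zscore_train_apply(acts_train, acts_test)
            model = fit_combined(
                X_train, a_train, data.labels[train_idx],
                head="cls", lambda_grid=self.lambda_grid, seed=seed,
            )
            return {"scores": model.predict_proba(np.column_stack([X_test, a_test]))}
        X_train = apply_preprocessor(state, data.clinical.iloc[train_idx], normalize=False)
        X_test = apply_preprocessor(state, data.clinical.iloc[test_idx], normalize=False)
        model = fit_combined(
            X_train, acts_train, data.ga_delivery[train_idx], head="reg"
        )
        pred = model.predict(np.column_stack([X_test, acts_test]))
        return {"scores": -pred, "pred_days": pred}
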