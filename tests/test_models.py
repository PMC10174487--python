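"""Loss arithmetic, network gradients, and the three predictor families."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import SMALL_STFT, make_labeled_spectrograms, make_spectrogram
from ehgterm.evaluation import auc
from ehgterm.models import (
    ClassWeights,
    NetworkSpec,
    SequenceModel,
    TrainConfig,
    class_weights,
    extract_fc_activations,
    fit_combined,
    fit_linear_regression,
    fit_logistic_lasso,
    train_sequence_model,
    weighted_cross_entropy,
    weighted_cross_entropy_grad,
)

TINY_NET = NetworkSpec(input_size=SMALL_STFT.n_freqs, bilstm_hidden=6)
TINY_REG = NetworkSpec(
    input_size=SMALL_STFT.n_freqs, bilstm_hidden=6, head="regression"
)


class TestClassWeights:
    def test_balanced_counts_give_unit_weights(self):
        w = class_weights(40, 40)
        assert w.w0 == w.w1 == 1.0

    def test_study_counts(self):
        # 30 preterm among 159 mothers
        w = class_weights(129, 30)
        assert w.w1 == pytest.approx(258 / 159)
        assert w.w0 == pytest.approx(60 / 159)

    @given(st.integers(1, 10_000), st.integers(1, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_weights_always_sum_to_two(self, s0, s1):
        w = class_weights(s0, s1)
        assert w.w0 + w.w1 == pytest.approx(2.0)
        assert w.w0 > 0 and w.w1 > 0

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            class_weights(0, 5)


class TestWeightedCrossEntropy:
    def test_single_sample_values(self):
        w = ClassWeights(w0=1.0, w1=1.0, s0=1, s1=1)
        assert weighted_cross_entropy([0.5], [1], w) == pytest.approx(np.log(2))
        w15 = ClassWeights(w0=0.5, w1=1.5, s0=3, s1=1)
        assert weighted_cross_entropy([0.7], [1], w15) == pytest.approx(
            -1.5 * np.log(0.7)
        )

    def test_perfect_prediction_gives_zero_loss(self):
        w = class_weights(2, 2)
        loss = weighted_cross_entropy([1.0, 0.0], [1, 0], w)
        assert loss == pytest.approx(0.0, abs=1e-10)

    def test_unit_weights_match_unweighted_oracle(self):
        rng = np.random.default_rng(0)
        w = ClassWeights(w0=1.0, w1=1.0, s0=1, s1=1)
        for _ in range(20):
            y = rng.uniform(0.01, 0.99, 16)
            t = rng.integers(0, 2, 16)
            oracle = -np.mean(t * np.log(y) + (1 - t) * np.log(1 - y))
            assert abs(weighted_cross_entropy(y, t, w) - oracle) < 1e-10

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        w = class_weights(12, 4)
        y = rng.uniform(0.05, 0.95, 10)
        t = rng.integers(0, 2, 10)
        grad = weighted_cross_entropy_grad(y, t, w)
        eps = 1e-7
        for j in range(10):
            up, dn = y.copy(), y.copy()
            up[j] += eps
            dn[j] -= eps
            fd = (
                weighted_cross_entropy(up, t, w) - weighted_cross_entropy(dn, t, w)
            ) / (2 * eps)
            assert abs(fd - grad[j]) < 1e-5


def _network_grad_max_error(spec, targets):
    rng = np.random.default_rng(2)
    model = SequenceModel(spec, TrainConfig(seed=3))
    if spec.head == "softmax_classifier":
        model.weights = class_weights(1, 1)
    x = rng.standard_normal((2, 4, spec.input_size))
    _, grads = model._loss_and_grads(x, targets)
    params = model._params()
    max_err = 0.0
    sampler = np.random.default_rng(4)
    for name, p in params.items():
        flat = p.reshape(-1)
        for j in sampler.choice(flat.size, size=min(5, flat.size), replace=False):
            eps = 1e-6
            orig = flat[j]
            flat[j] = orig + eps
            lp, _ = model._loss_and_grads(x, targets)
            flat[j] = orig - eps
            lm, _ = model._loss_and_grads(x, targets)
            flat[j] = orig
            max_err = max(max_err, abs((lp - lm) / (2 * eps) - grads[name].reshape(-1)[j]))
    return max_err


class TestSequenceNetwork:
    def test_backprop_matches_finite_differences_classifier(self):
        spec = NetworkSpec(input_size=5, bilstm_hidden=3)
        assert _network_grad_max_error(spec, np.array([1.0, 0.0])) < 1e-6

    def test_backprop_matches_finite_differences_regressor(self):
        spec = NetworkSpec(input_size=5, bilstm_hidden=3, head="regression")
        assert _network_grad_max_error(spec, np.array([0.4, -0.3])) < 1e-6

    def test_training_is_reproducible(self):
        rng = np.random.default_rng(5)
        sgs, labels = make_labeled_spectrograms(rng, n=20)
        cfg = TrainConfig(batch_size=4, epochs=4, seed=7)
        a = train_sequence_model(list(zip(sgs, labels)), TINY_NET, cfg)
        b = train_sequence_model(list(zip(sgs, labels)), TINY_NET, cfg)
        np.testing.assert_array_equal(a.predict_proba(sgs), b.predict_proba(sgs))

    def test_learns_strong_mean_shift(self):
        rng = np.random.default_rng(6)
        sgs, labels = make_labeled_spectrograms(rng, n=60, shift=2.0)
        test_sgs, test_labels = make_labeled_spectrograms(rng, n=40, shift=2.0)
        cfg = TrainConfig(batch_size=8, epochs=25, seed=8)
        model = train_sequence_model(list(zip(sgs, labels)), TINY_NET, cfg)
        assert auc(model.predict_proba(test_sgs), test_labels) > 0.9

    def test_no_signal_stays_near_chance(self):
        rng = np.random.default_rng(7)
        aucs = []
        for seed in range(6):
            sgs, labels = make_labeled_spectrograms(rng, n=40, shift=0.0)
            test_sgs, test_labels = make_labeled_spectrograms(rng, n=40, shift=0.0)
            cfg = TrainConfig(batch_size=8, epochs=6, seed=seed)
            model = train_sequence_model(list(zip(sgs, labels)), TINY_NET, cfg)
            aucs.append(auc(model.predict_proba(test_sgs), test_labels))
        assert abs(np.mean(aucs) - 0.5) < 0.15

    def test_regression_head_fits_constant_target(self):
        rng = np.random.default_rng(8)
        sgs = [make_spectrogram(rng) for _ in range(16)]
        targets = np.full(16, 270.0)
        cfg = TrainConfig(batch_size=8, epochs=200, learning_rate=5e-3, seed=9)
        model = train_sequence_model(list(zip(sgs, targets)), TINY_REG, cfg)
        np.testing.assert_allclose(model.predict_days(sgs), 270.0, atol=3.0)

    def test_single_class_training_rejected(self):
        rng = np.random.default_rng(9)
        sgs = [make_spectrogram(rng) for _ in range(6)]
        with pytest.raises(ValueError):
            train_sequence_model(
                list(zip(sgs, np.ones(6))), TINY_NET, TrainConfig(epochs=1)
            )

    def test_inconsistent_input_sizes_rejected(self):
        rng = np.random.default_rng(10)
        sgs = [make_spectrogram(rng, n_times=8), make_spectrogram(rng, n_times=9)]
        with pytest.raises(ValueError):
            train_sequence_model(
                list(zip(sgs, [0, 1])), TINY_NET, TrainConfig(epochs=1)
            )


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(11)
    sgs, labels = make_labeled_spectrograms(rng, n=24, shift=1.0)
    cfg = TrainConfig(batch_size=8, epochs=5, seed=12)
    model = train_sequence_model(list(zip(sgs, labels)), TINY_NET, cfg)
    return model, sgs


class TestActivations:

    def test_deterministic_two_vector(self, fitted):
        model, sgs = fitted
        a = extract_fc_activations(model, sgs[0])
        b = extract_fc_activations(model, sgs[0])
        assert a.shape == (2,)
        np.testing.assert_array_equal(a, b)

    def test_softmax_of_activations_equals_probability(self, fitted):
        model, sgs = fitted
        acts = extract_fc_activations(model, sgs[0])
        softmax = np.exp(acts - acts.max())
        softmax /= softmax.sum()
        prob = model.predict_proba([sgs[0]])[0]
        assert abs(softmax[1] - prob) < 1e-8


class TestLogisticLasso:
    def test_infinite_penalty_predicts_prevalence(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((80, 4))
        y = (rng.random(80) < 0.25).astype(int)
        model = fit_logistic_lasso(X, y, lambda_grid=[1e6])
        np.testing.assert_allclose(model.coef_, 0.0, atol=1e-6)
        np.testing.assert_allclose(model.predict_proba(X), y.mean(), atol=0.01)

    def test_unpenalized_separates_toy_design(self):
        X = np.array([[0.0], [0.2], [0.4], [0.6], [1.4], [1.6], [1.8], [2.0]])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        model = fit_logistic_lasso(X, y, lambda_grid=[0.0])
        assert np.mean((model.predict_proba(X) > 0.5) == y) == 1.0

    def test_duplicated_column_stays_sparse(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal(200)
        X = np.column_stack([x, x, rng.standard_normal(200)])
        y = (x + 0.3 * rng.standard_normal(200) > 0).astype(int)
        model = fit_logistic_lasso(X, y, lambda_grid=[0.5])
        assert min(abs(model.coef_[0]), abs(model.coef_[1])) < 1e-6

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic_lasso(np.ones((5, 2)), np.ones(5))


class TestLinearRegression:
    def test_exact_linear_function_recovered(self):
        rng = np.random.default_rng(15)
        X = rng.standard_normal((30, 3))
        t = 260.0 + X @ np.array([3.0, -2.0, 1.0])
        model = fit_linear_regression(X, t)
        np.testing.assert_allclose(model.predict(X), t, atol=1e-8)

    def test_intercept_only_predicts_mean(self):
        t = np.array([250.0, 270.0, 290.0])
        model = fit_linear_regression(np.empty((3, 0)), t)
        np.testing.assert_allclose(model.predict(np.empty((3, 0))), 270.0)

    def test_preterm_threshold_at_259_days(self):
        model = fit_linear_regression(
            np.array([[0.0], [1.0], [2.0]]), np.array([258.9, 259.0, 259.1])
        )
        X = np.array([[0.0], [1.0]])
        assert list(model.predict_label(X)) == [1, 0]

    def test_rank_deficiency_flagged(self):
        X = np.column_stack([np.ones(5), np.ones(5)])
        with pytest.warns(UserWarning):
            model = fit_linear_regression(X, np.arange(5.0))
        assert model.rank_deficient


class TestCombined:
    def test_feature_count_is_clinical_plus_two(self):
        rng = np.random.default_rng(16)
        clinical = rng.standard_normal((40, 8))
        acts = rng.standard_normal((40, 2))
        y = (rng.random(40) < 0.5).astype(int)
        model = fit_combined(clinical, acts, y, head="cls", lambda_grid=[0.1])
        assert model.coef_.size == 10

    def test_label_leaking_activations_reach_perfect_auc(self):
        rng = np.random.default_rng(17)
        y = (rng.random(60) < 0.4).astype(int)
        clinical = rng.standard_normal((60, 5))
        acts = np.column_stack([1.0 - y, y]).astype(float)  # one-hot oracle
        model = fit_combined(clinical, acts, y, head="cls", lambda_grid=[0.1])
        assert auc(model.predict_proba(np.column_stack([clinical, acts])), y) == 1.0

    def test_zeroed_activations_match_clinical_only(self):
        rng = np.random.default_rng(18)
        X = rng.standard_normal((100, 5))
        y = (X[:, 0] + 0.5 * rng.standard_normal(100) > 0).astype(int)
        zeros = np.zeros((100, 2))
        combined = fit_combined(X, zeros, y, head="cls", lambda_grid=[0.2])
        clinical_only = fit_logistic_lasso(X, y, lambda_grid=[0.2])
        np.testing.assert_allclose(
            combined.predict_proba(np.column_stack([X, zeros])),
            clinical_only.predict_proba(X),
            atol=0.02,
        )

    def test_misaligned_rows_rejected(self):
        with pytest.raises(ValueError):
            fit_combined(np.ones((4, 2)), np.ones((5, 2)), np.ones(4))
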