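"""Loss arithmetic, the step learning-rate schedule and the SGD
training loop."""

import numpy as np
import pytest

from ecgresnet.dataset import LabeledDataset, encode_labels
from ecgresnet.model import ModelSpec, build_model
from ecgresnet.record_io import AamiClass
from ecgresnet.trainer import TrainConfig, evaluate_accuracy, loss, lr_at, train


class TestLoss:
    def test_perfect_prediction_zero_loss(self):
        y = np.eye(5)[:3]
        assert loss(y, y) == pytest.approx(0.0, abs=1e-9)

    def test_half_probability_ln2(self):
        p = np.array([[0.5, 0.5, 0, 0, 0]])
        y = np.array([[1.0, 0, 0, 0, 0]])
        assert loss(p, y) == pytest.approx(np.log(2), rel=1e-12)

    def test_l2_penalty_arithmetic(self):
        p = y = np.eye(5)[:1]
        w = [np.array([0.0, 2.0, 0.0])]
        assert loss(p, y, w, alpha=0.01) == pytest.approx(0.04)

    def test_zero_probability_clamped_finite(self):
        p = np.array([[0.0, 1.0, 0, 0, 0]])
        y = np.array([[1.0, 0, 0, 0, 0]])
        assert np.isfinite(loss(p, y))

    def test_penalty_shrinks_with_weights(self):
        p = y = np.eye(5)[:1]
        w = [np.ones(10)]
        big = loss(p, y, w, alpha=0.1)
        small = loss(p, y, [0.5 * w[0]], alpha=0.1)
        assert small < big


class TestLrSchedule:
    def test_initial_value(self):
        assert lr_at(1, TrainConfig()) == 0.1

    def test_default_steps(self):
        cfg = TrainConfig()
        assert lr_at(50, cfg) == pytest.approx(0.1)
        assert lr_at(51, cfg) == pytest.approx(0.01)
        assert lr_at(76, cfg) == pytest.approx(0.001)

    def test_non_increasing_over_100_epochs(self):
        cfg = TrainConfig()
        values = [lr_at(e, cfg) for e in range(1, 101)]
        assert all(b <= a for a, b in zip(values, values[1:]))

    def test_empty_schedule_constant(self):
        cfg = TrainConfig(lr_schedule=())
        assert {lr_at(e, cfg) for e in range(1, 101)} == {0.1}


def _toy_model(n_classes=2, input_length=64):
    spec = ModelSpec(
        input_length=input_length, n_classes=n_classes, initial_filters=4,
        initial_kernel=8, initial_stride=2, residual_kernel=4,
        n_improved_stages=1, filter_schedule=(8,), dropout_rate=0.0,
    )
    return build_model(spec, seed=0)


def _separable_toy(n=64, length=64, seed=0):
    """Two classes distinguished by the sign of a low-frequency bump."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, length)
    X, labels = [], []
    for i in range(n):
        sign = 1 if i % 2 == 0 else -1
        X.append(sign * np.sin(2 * np.pi * t) + 0.05 * rng.standard_normal(length))
        labels.append(0 if sign > 0 else 1)
    y = np.zeros((n, 2))
    y[np.arange(n), labels] = 1.0
    return LabeledDataset(np.array(X), y)


class TestTrain:
    def test_overfits_separable_toy(self):
        ds = _separable_toy()
        model = _toy_model()
        cfg = TrainConfig(initial_lr=0.01, lr_schedule=(), epochs=30,
                          batch_size=16, seed=0)
        model, history = train(model, ds, ds, cfg)
        acc, _ = evaluate_accuracy(model, ds)
        assert acc == 1.0

    def test_same_seed_reproduces_history(self):
        ds = _separable_toy()
        cfg = TrainConfig(initial_lr=0.01, lr_schedule=(), epochs=5,
                          batch_size=16, seed=3)
        _, h1 = train(_toy_model(), ds, ds, cfg)
        _, h2 = train(_toy_model(), ds, ds, cfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_accuracy == h2.val_accuracy
        assert h1.best_epoch == h2.best_epoch

    def test_loss_non_increasing_at_tiny_lr(self):
        ds = _separable_toy(n=16)
        cfg = TrainConfig(initial_lr=0.001, lr_schedule=(), momentum=0.0,
                          epochs=10, batch_size=16, seed=0, l2_alpha=0.0)
        _, history = train(_toy_model(), ds, ds, cfg)
        diffs = np.diff(history.train_loss)
        assert (diffs <= 1e-6).all()

    def test_best_epoch_has_max_val_accuracy(self):
        ds = _separable_toy()
        cfg = TrainConfig(initial_lr=0.01, lr_schedule=(), epochs=8,
                          batch_size=16, seed=1)
        _, history = train(_toy_model(), ds, ds, cfg)
        best = history.val_accuracy[history.best_epoch - 1]
        assert best == max(history.val_accuracy)
        # ties broken toward the earliest epoch
        first_max = 1 + history.val_accuracy.index(best)
        assert history.best_epoch == first_max

    def test_returned_model_matches_best_snapshot(self):
        ds = _separable_toy()
        cfg = TrainConfig(initial_lr=0.01, lr_schedule=(), epochs=10,
                          batch_size=16, seed=2)
        model, history = train(_toy_model(), ds, ds, cfg)
        acc, _ = evaluate_accuracy(model, ds)
        assert acc == pytest.approx(max(history.val_accuracy))

    def test_empty_dataset_rejected(self):
        ds = _separable_toy()
        empty = LabeledDataset(np.zeros((0, 64)), np.zeros((0, 2)))
        with pytest.raises(ValueError):
            train(_toy_model(), empty, ds, TrainConfig(epochs=1))

    def test_divergence_aborts_with_diagnostic(self):
        ds = _separable_toy()
        model = _toy_model()
        for p in model.parameters():
            p.value *= 1e6  # force an immediate blow-up
        with pytest.raises(RuntimeError, match="diverged|finite"):
            train(model, ds, ds, TrainConfig(initial_lr=10.0, epochs=2,
                                             batch_size=16, seed=0))


class TestConfigValidation:
    def test_bad_lr_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(initial_lr=0.0)

    def test_bad_epochs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
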