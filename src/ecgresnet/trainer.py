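"""Mini-batch SGD training with cross-entropy + L2 loss, a step
learning-rate schedule and best-on-validation model selection.

The loss is the mean categorical cross-entropy
``-sum_i y_i ln p_i`` plus ``alpha * sum ||W||^2`` over every
regularized layer (all convolutions and the fully connected head).
The learning rate starts at 0.1 and is multiplied by 0.1 at epochs
51 and 76 by default — the model is observed to converge gradually
after roughly 50 epochs, so the schedule anneals in the second half
of the default 100-epoch run.  After each epoch the validation
accuracy is measured and the weight snapshot with the highest value
(earliest epoch on ties) is the returned model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dataset import LabeledDataset
from .model import Model, softmax

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainHistory", "loss", "lr_at", "train", "evaluate_accuracy"]

_LOG_EPS = 1e-12  # clamp for ln p at the true class


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    ``lr_schedule`` is a sequence of ``(epoch, multiplier)`` pairs:
    from the given epoch (1-based) onward the learning rate is
    multiplied by the factor.  Momentum 0.9, batch size 128 and
    ``l2_alpha`` 1e-4 are conventional defaults for SGD on residual
    networks.
    """

    optimizer: str = "sgd"
    initial_lr: float = 0.1
    lr_schedule: tuple[tuple[int, float], ...] = ((51, 0.1), (76, 0.1))
    momentum: float = 0.9
    batch_size: int = 128
    epochs: int = 100
    l2_alpha: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer != "sgd":
            raise ValueError("only the SGD optimizer is supported")
        if self.initial_lr <= 0:
            raise ValueError("initial learning rate must be positive")
        if self.epochs < 1:
            raise ValueError("at least one epoch is required")


@dataclass
class TrainHistory:
    """Per-epoch training loss, validation loss and validation
    accuracy, plus the index (1-based) of the selected best epoch."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = 0

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch,train_loss,val_loss,val_accuracy\n")
            for i, (tl, vl, va) in enumerate(
                zip(self.train_loss, self.val_loss, self.val_accuracy), start=1
            ):
                fh.write(f"{i},{tl:.6f},{vl:.6f},{va:.6f}\n")


def loss(
    probabilities: np.ndarray,
    onehot: np.ndarray,
    weights: list[np.ndarray] | None = None,
    alpha: float = 0.0,
) -> float:
    """Mean cross-entropy plus ``alpha * sum ||W||^2``.

    Probabilities at the true class are clamped at 1e-12 so that a
    confident wrong prediction yields a large finite loss rather than
    an infinity.
    """
    p = np.clip(np.asarray(probabilities, dtype=float), _LOG_EPS, 1.0)
    y = np.asarray(onehot, dtype=float)
    ce = float(-(y * np.log(p)).sum(axis=1).mean())
    penalty = 0.0
    if weights and alpha:
        penalty = alpha * float(sum(np.sum(w**2) for w in weights))
    return ce + penalty


def lr_at(epoch: int, config: TrainConfig) -> float:
    """Piecewise-constant, non-increasing step schedule (1-based
    epochs)."""
    if epoch < 1:
        raise ValueError("epochs are 1-based")
    lr = config.initial_lr
    for step_epoch, mult in config.lr_schedule:
        if epoch >= step_epoch:
            lr *= mult
    return lr


def evaluate_accuracy(model: Model, dataset: LabeledDataset,
                      batch_size: int = 256) -> tuple[float, float]:
    """(accuracy in [0,1], mean cross-entropy loss) on a dataset."""
    if len(dataset) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    correct = 0
    total_ce = 0.0
    for i in range(0, len(dataset), batch_size):
        Xb, yb = dataset.X[i : i + batch_size], dataset.y[i : i + batch_size]
        p = model.forward(Xb, training=False)
        correct += int((p.argmax(axis=1) == yb.argmax(axis=1)).sum())
        total_ce += loss(p, yb) * len(Xb)
    return correct / len(dataset), total_ce / len(dataset)


def train(
    model: Model,
    train_set: LabeledDataset,
    val_set: LabeledDataset,
    config: TrainConfig = TrainConfig(),
) -> tuple[Model, TrainHistory]:
    """Train in place and return the best-on-validation weights.

    Each epoch shuffles the training set (seeded), runs mini-batch
    SGD with momentum, adds the L2 gradient ``2 * alpha * W`` to every
    regularized parameter, then scores validation accuracy.  The
    snapshot with the highest validation accuracy (ties broken toward
    the earliest epoch) is restored into the model before returning.
    Given the same model seed, data and config, the run is exactly
    reproducible.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    params = model.parameters()
    velocity = [np.zeros_like(p.value) for p in params]
    history = TrainHistory()
    best_acc, best_state = -1.0, None
    alpha = config.l2_alpha

    for epoch in range(1, config.epochs + 1):
        lr = lr_at(epoch, config)
        order = rng.permutation(len(train_set))
        epoch_ce = 0.0
        for i in range(0, len(order), config.batch_size):
            sel = order[i : i + config.batch_size]
            Xb, yb = train_set.X[sel], train_set.y[sel]
            model.zero_grad()
            logits = model.forward_logits(Xb, training=True)
            p = softmax(logits)
            batch_ce = loss(p, yb)
            if not np.isfinite(batch_ce):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss is not finite"
                )
            epoch_ce += batch_ce * len(sel)
            model.backward((p - yb) / len(sel))
            for param, v in zip(params, velocity):
                g = param.grad
                if alpha and param.regularized:
                    g = g + 2.0 * alpha * param.value
                v *= config.momentum
                v -= lr * g
                param.value += v
        penalty = alpha * float(
            sum(np.sum(p.value**2) for p in params if p.regularized)
        )
        history.train_loss.append(epoch_ce / len(train_set) + penalty)

        val_acc, val_ce = evaluate_accuracy(model, val_set)
        history.val_loss.append(val_ce)
        history.val_accuracy.append(val_acc)
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = model.state()
            history.best_epoch = epoch
        logger.info(
            "epoch %3d lr %.4g train loss %.4f val loss %.4f val acc %.4f",
            epoch, lr, history.train_loss[-1], val_ce, val_acc,
        )

    if best_state is not None:
        model.load_state(best_state)
    return model, history
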