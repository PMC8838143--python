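"""SGDM training with weighted cross-entropy and early stopping.

The optimizer is stochastic gradient descent with classical momentum
and L2 regularization folded into the gradient::

    v' = momentum * v - lr * (g + weight_decay * theta)
    theta' = theta + v'

with the canonical hyperparameters lr = 0.001, momentum = 0.99,
weight_decay = 0.0005, batch size 32.  The loss is class-weighted
cross-entropy, with inverse-frequency weights w_k = N / (K * n_k) so a
balanced set gets unit weights.

Training monitors validation loss each epoch and stops once it has not
improved for ``early_stop_patience`` epochs, restoring the weights of
the best epoch.  Class index 0 is MEL (the positive class), 1 is BEN,
matching the evaluation module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .augment import AugmentPolicy, random_augment
from .dataio import ImageRecord, Label
from .layers import softmax_cross_entropy
from .network import LCNetModel

__all__ = [
    "CLASS_ORDER",
    "TrainConfig",
    "TrainHistory",
    "class_weights",
    "weighted_cross_entropy",
    "sgdm_step",
    "SGDM",
    "train",
    "records_to_arrays",
]

#: fixed class/column order of the network head: column 0 = P(MEL)
CLASS_ORDER: tuple[Label, Label] = (Label.MEL, Label.BEN)

_LOG_EPS = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    momentum: float = 0.99
    weight_decay: float = 0.0005
    batch_size: int = 32
    max_epochs: int = 100
    early_stop_patience: int = 10
    seed: int = 0
    augment: bool = True
    augment_policy: AugmentPolicy = field(default_factory=AugmentPolicy)

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


def class_weights(train_counts: dict[Label, int]) -> np.ndarray:
    """Inverse-frequency class weights w_k = N / (K * n_k), in CLASS_ORDER.

    Balanced counts give unit weights; a class that is half as frequent
    gets twice the weight, keeping the expected weight at 1.
    """
    if len(train_counts) < 2:
        raise ValueError("need counts for both classes")
    for label, n in train_counts.items():
        if n < 1:
            raise ValueError(f"class {label} has zero samples")
    total = sum(train_counts.values())
    k = len(train_counts)
    return np.array([total / (k * train_counts[lab]) for lab in CLASS_ORDER])


def weighted_cross_entropy(
    predictions: np.ndarray,
    targets: np.ndarray,
    weights: np.ndarray,
) -> float:
    """Mean class-weighted cross-entropy of probability rows.

    ``Loss = -(1/N) sum_i sum_j w_j T_ij log P_ij`` with P clamped to
    [1e-12, 1] before the log.  T rows must be one-hot; P rows must lie
    in the simplex.
    """
    p = np.asarray(predictions, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    if p.shape != t.shape or p.ndim != 2 or w.shape != (p.shape[1],):
        raise ValueError(
            f"shape mismatch: P {p.shape}, T {t.shape}, w {w.shape}"
        )
    logp = np.log(np.clip(p, _LOG_EPS, 1.0))
    return float(-(w * t * logp).sum() / p.shape[0])


def sgdm_step(
    theta: np.ndarray,
    grad: np.ndarray,
    velocity: np.ndarray,
    config: TrainConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """One SGDM update; returns (theta', v').

    Classical momentum with the L2 term added to the gradient:
    v' = momentum * v - lr * (g + weight_decay * theta).
    """
    if not (theta.shape == grad.shape == velocity.shape):
        raise ValueError("theta, grad and velocity must have matching shapes")
    if not np.all(np.isfinite(grad)):
        raise FloatingPointError("non-finite gradient; training aborted")
    v_new = config.momentum * velocity - config.learning_rate * (
        grad + config.weight_decay * theta
    )
    return theta + v_new, v_new


class SGDM:
    """Stateful optimizer holding one velocity buffer per parameter."""

    def __init__(self, params, config: TrainConfig):
        self.params = list(params)
        self.config = config
        self.velocity = [np.zeros_like(p.value) for _, p in self.params]

    def step(self) -> None:
        for (name, p), v in zip(self.params, self.velocity):
            p.value, v_new = sgdm_step(p.value, p.grad, v, self.config)
            v[...] = v_new


def records_to_arrays(records: list[ImageRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Stack records into (N, 3, S, S) float32 in [0,1] and class indices."""
    x = np.stack([r.pixels for r in records]).astype(np.float32) / 255.0
    x = np.ascontiguousarray(x.transpose(0, 3, 1, 2))
    y = np.array([CLASS_ORDER.index(r.label) for r in records], dtype=np.intp)
    return x, y


def _evaluate_epoch(model, x, y, weights, batch_size=64):
    """(loss, accuracy) on a held-out set, batch-norm in inference mode."""
    n = len(y)
    correct = 0
    total_loss = 0.0
    eye = np.eye(2, dtype=np.float64)
    for start in range(0, n, batch_size):
        sl = slice(start, min(start + batch_size, n))
        probs = model.forward(x[sl])
        total_loss += weighted_cross_entropy(probs, eye[y[sl]], weights) * (sl.stop - sl.start)
        # tie at 0.5 resolves to BEN (index 1): strict > for MEL
        pred = np.where(probs[:, 0] > 0.5, 0, 1)
        correct += int((pred == y[sl]).sum())
    return total_loss / n, correct / n


def train(
    model: LCNetModel,
    train_records: list[ImageRecord],
    val_records: list[ImageRecord],
    config: TrainConfig = TrainConfig(),
    *,
    loss_weights: np.ndarray | None = None,
) -> tuple[LCNetModel, TrainHistory]:
    """Epoch loop with seeded shuffling, optional per-batch augmentation,
    validation monitoring and best-epoch weight restoration.

    Train and validation records must be disjoint; when augmentation is
    on, the training records are expected to be pre-balanced by
    oversampling.
    """
    if not train_records or not val_records:
        raise ValueError("train and validation sets must be non-empty")
    overlap = {r.id for r in train_records} & {r.id for r in val_records}
    if overlap:
        raise ValueError(f"train/val overlap: {sorted(overlap)[:3]}...")

    counts = {lab: sum(1 for r in train_records if r.label == lab) for lab in CLASS_ORDER}
    if loss_weights is None:
        loss_weights = class_weights(counts)
    loss_weights = np.asarray(loss_weights, dtype=np.float64)

    x_val, y_val = records_to_arrays(val_records)
    y_train = np.array(
        [CLASS_ORDER.index(r.label) for r in train_records], dtype=np.intp
    )
    x_train_raw = None
    if not config.augment:
        x_train_raw, _ = records_to_arrays(train_records)

    optimizer = SGDM(model.params(), config)
    history = TrainHistory()
    eye = np.eye(2, dtype=np.float32)
    best_loss = np.inf
    best_state = None
    since_best = 0

    for epoch in range(1, config.max_epochs + 1):
        rng = np.random.default_rng([config.seed % (2**31), epoch])
        order = rng.permutation(len(train_records))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            if config.augment:
                imgs = [
                    random_augment(train_records[i].pixels, config.augment_policy, rng)
                    for i in idx
                ]
                xb = np.stack(imgs).astype(np.float32) / 255.0
                xb = np.ascontiguousarray(xb.transpose(0, 3, 1, 2))
            else:
                xb = x_train_raw[idx]
            tb = eye[y_train[idx]]
            model.zero_grad()
            logits = model.forward_logits(xb, training=True)
            loss, grad = softmax_cross_entropy(
                logits, tb, loss_weights.astype(np.float32)
            )
            model.backward(grad)
            optimizer.step()
            epoch_loss += loss * len(idx)
        history.train_loss.append(epoch_loss / len(order))

        val_loss, val_acc = _evaluate_epoch(model, x_val, y_val, loss_weights)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        history.stopped_epoch = epoch

        if val_loss < best_loss:
            best_loss = val_loss
            history.best_epoch = epoch
            best_state = model.state_dict()
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.early_stop_patience:
                break

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def plot_history(history: TrainHistory, path) -> None:
    """Write accuracy/loss-vs-epoch curves as a PNG (convenience output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    epochs = range(1, history.stopped_epoch + 1)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.plot(epochs, history.val_accuracy, marker="o")
    ax1.set_xlabel("epoch")
    ax1.set_ylabel("validation accuracy")
    ax1.set_ylim(0, 1.02)
    ax2.plot(epochs, history.train_loss, label="train")
    ax2.plot(epochs, history.val_loss, label="validation")
    ax2.set_xlabel("epoch")
    ax2.set_ylabel("loss")
    ax2.legend()
    ax1.axvline(history.best_epoch, ls="--", c="gray", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
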