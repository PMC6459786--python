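"""Dataset splitting, supervised training, and transfer learning.

Training minimizes cross-entropy plus the model's L2 penalty with Adam,
evaluating validation loss after every epoch.  Training stops when the
validation loss has not improved for ``early_stop_patience`` epochs or
when ``max_epochs`` (default 25) is reached, and the weights from the
best validation epoch are restored.

Transfer learning adapts a trained model to a new site / class set: the
softmax head is replaced by a freshly normal-initialized layer sized to
the new classes, and the transferred feature layers are retrained at
10% of the head's learning rate (per-layer learning-rate scaling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cnn_model import CNNModel, predict_proba_batch
from .core import ClassLabel, SegmentRecord
from .preprocess import build_feature_matrix

__all__ = [
    "TrainConfig",
    "SplitSpec",
    "TrainingHistory",
    "split_dataset",
    "features_and_labels",
    "train_model",
    "transfer_retrain",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    ``early_stop_patience`` counts epochs without a new best validation
    loss, where an improvement smaller than ``early_stop_min_delta``
    does not count as a new best; ``transfer_lr_fraction`` is the
    learning-rate multiplier of transferred (non-head) layers during
    transfer retraining.
    """

    max_epochs: int = 25
    base_learning_rate: float = 1e-3
    batch_size: int = 32
    early_stop_patience: int = 1
    early_stop_min_delta: float = 0.0
    transfer_lr_fraction: float = 0.10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not 0 < self.transfer_lr_fraction <= 1:
            raise ValueError("transfer_lr_fraction must be in (0, 1]")
        if self.base_learning_rate <= 0:
            raise ValueError("base_learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")
        if self.early_stop_min_delta < 0:
            raise ValueError("early_stop_min_delta must be non-negative")


@dataclass(frozen=True)
class SplitSpec:
    """Per-class split fractions; stratification is always per class."""

    fractions: dict[str, float] = field(
        default_factory=lambda: {"train": 0.7, "validation": 0.3, "test": 0.0}
    )

    def __post_init__(self) -> None:
        keys = set(self.fractions)
        if keys != {"train", "validation", "test"}:
            raise ValueError("fractions must have exactly train/validation/test keys")
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("fractions must be non-negative")
        if abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def split_dataset(
    segments: Sequence[SegmentRecord],
    spec: SplitSpec,
    rng_seed: int,
) -> tuple[list[SegmentRecord], list[SegmentRecord], list[SegmentRecord]]:
    """Stratified train/validation/test split.

    Within each class the segments are shuffled with the seeded
    generator, validation and test take ``floor(fraction * n)`` items,
    and the remainder goes to train — so the three parts are disjoint
    and cover the input exactly.
    """
    if any(seg.label is None for seg in segments):
        raise ValueError("every segment must be labeled for splitting")
    rng = np.random.default_rng(rng_seed)
    by_class: dict[ClassLabel, list[int]] = {}
    for i, seg in enumerate(segments):
        by_class.setdefault(seg.label, []).append(i)

    parts: dict[str, list[int]] = {"train": [], "validation": [], "test": []}
    for label in sorted(by_class, key=lambda lb: lb.name):
        idx = np.array(by_class[label])
        rng.shuffle(idx)
        n = len(idx)
        n_val = int(np.floor(spec.fractions["validation"] * n))
        n_test = int(np.floor(spec.fractions["test"] * n))
        for part, need in (("validation", n_val), ("test", n_test)):
            if spec.fractions[part] > 0 and need == 0:
                raise ValueError(
                    f"class {label} has too few segments ({n}) for the "
                    f"requested {part} fraction"
                )
        if spec.fractions["train"] > 0 and n - n_val - n_test == 0:
            raise ValueError(f"class {label} has too few segments ({n}) for training")
        parts["validation"].extend(idx[:n_val].tolist())
        parts["test"].extend(idx[n_val : n_val + n_test].tolist())
        parts["train"].extend(idx[n_val + n_test :].tolist())

    return (
        [segments[i] for i in parts["train"]],
        [segments[i] for i in parts["validation"]],
        [segments[i] for i in parts["test"]],
    )


def features_and_labels(
    segments: Sequence[SegmentRecord],
    class_order: Sequence[ClassLabel],
) -> tuple[np.ndarray, np.ndarray]:
    """Build the (N, 5, 15000) float32 feature stack and integer labels."""
    class_index = {label: i for i, label in enumerate(class_order)}
    xs = np.empty((len(segments), 5, 15000), dtype=np.float32)
    ys = np.empty(len(segments), dtype=np.int64)
    for i, seg in enumerate(segments):
        if seg.label not in class_index:
            raise ValueError(f"segment label {seg.label} not in class order")
        xs[i] = build_feature_matrix(seg).values.astype(np.float32)
        ys[i] = class_index[seg.label]
    return xs, ys


@dataclass
class TrainingHistory:
    """Per-epoch losses plus stopping metadata."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


class _Adam:
    """Adam with per-layer learning-rate scaling (for transfer learning)."""

    def __init__(self, model: CNNModel, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}
        for li, layer in enumerate(model.layers):
            for name, arr in layer.params.items():
                self.m[(li, name)] = np.zeros_like(arr)
                self.v[(li, name)] = np.zeros_like(arr)

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for li, layer in enumerate(self.model.layers):
            lr = self.lr * layer.lr_scale
            for name, arr in layer.params.items():
                g = layer.grads[name].astype(np.float32)
                m = self.m[(li, name)]
                v = self.v[(li, name)]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                arr -= lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def _as_arrays(
    data, class_order: Sequence[ClassLabel]
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, tuple) and len(data) == 2:
        x, y = data
        return np.asarray(x, dtype=np.float32), np.asarray(y, dtype=np.int64)
    return features_and_labels(data, class_order)


def train_model(
    model: CNNModel,
    train_data,
    validation_data,
    cfg: TrainConfig,
) -> tuple[CNNModel, TrainingHistory]:
    """Train in place; return the model with best-validation weights.

    ``train_data`` / ``validation_data`` are either ``(X, y)`` array
    pairs (features stacked as (N, 5, 15000), integer labels indexing
    the model's class order) or sequences of labeled
    :class:`SegmentRecord`, which are featurized here.

    Validation is a forward-only pass: model weights and batch-norm
    statistics are not updated by it.
    """
    x_train, y_train = _as_arrays(train_data, model.class_order)
    x_val, y_val = _as_arrays(validation_data, model.class_order)
    if len(x_train) == 0:
        raise ValueError("training set is empty")
    if len(x_val) == 0:
        raise ValueError("validation set is empty")

    rng = np.random.default_rng(cfg.rng_seed)
    optimizer = _Adam(model, cfg.base_learning_rate)
    history = TrainingHistory()
    best_val = np.inf
    best_state = model.state_dict()
    best_state = {k: v.copy() for k, v in best_state.items()}
    epochs_since_best = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_train))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            loss = model.loss_and_backward(x_train[batch], y_train[batch], rng=rng)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch + 1}"
                )
            optimizer.step()
            epoch_loss += loss
            n_batches += 1
        train_loss = epoch_loss / n_batches
        val_loss = model.loss(x_val, y_val)
        if not np.isfinite(val_loss):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch + 1}")
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        logger.info(
            "epoch %d: train loss %.4f, validation loss %.4f", epoch + 1, train_loss, val_loss
        )
        if val_loss < best_val - cfg.early_stop_min_delta:
            best_val = val_loss
            history.best_epoch = epoch + 1
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= cfg.early_stop_patience:
                history.stopped_epoch = epoch + 1
                break
    if history.stopped_epoch < 0:
        history.stopped_epoch = len(history.train_loss)
    model.load_state_dict(best_state)
    return model, history


def transfer_retrain(
    gm_model: CNNModel,
    new_train,
    new_validation,
    new_class_set: Sequence[ClassLabel],
    cfg: TrainConfig,
) -> tuple[CNNModel, TrainingHistory]:
    """Adapt a trained model to a new class set / acquisition site.

    The source model is left untouched; a copy has its softmax head
    replaced (normal init, mean 0, std 0.01) and resized to
    ``new_class_set``.  During retraining the transferred layers use
    ``transfer_lr_fraction`` (default 10%) of the head's learning rate.
    """
    model = gm_model.copy()
    rng = np.random.default_rng(cfg.rng_seed)
    model.reset_output_layer(new_class_set, rng)
    for layer in model.layers[:-1]:
        layer.lr_scale = cfg.transfer_lr_fraction
    model.output_layer.lr_scale = 1.0
    model, history = train_model(model, new_train, new_validation, cfg)
    return model, history
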