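"""1-D convolutional network for segment classification, in pure numpy.

The classifier maps the 5 x 15000 feature matrix (low-passed raw row +
four band-power envelograms) to class probabilities.  Architecture:
stacked blocks of [1-D convolution over time -> batch normalization ->
ReLU -> max pooling], with the five feature rows entering as input
channels of the first convolution, followed by dropout and fully
connected layers ending in a softmax.  Overfitting is controlled by
dropout and an L2 weight penalty.

Both the forward pass and analytic back-propagation are implemented
here (the test suite checks every layer's gradient against finite
differences).  All parameters live in float32; convolutions are
evaluated as windowed tensor contractions so the heavy lifting is a
single BLAS matrix product per layer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .core import (
    ClassLabel,
    GENERALIZED_CLASSES,
    SPECIALIZED_CLASSES,
)
from .preprocess import FeatureMatrix

__all__ = [
    "ModelConfig",
    "ClassProbabilities",
    "CNNModel",
    "build_model",
    "predict_proba",
    "predict_proba_batch",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the convolutional classifier.

    ``conv_blocks`` lists (filters, kernel_length, pool_length) per
    block; ``input_stride`` is the stride of the first convolution
    (1 ms at 5 kHz with the default 5).  Defaults are sized for
    single-CPU training on 3-s segments: a stride-5 entry convolution
    and four blocks of 8/16/32/32 filters with kernel 9 and pool 4
    reduce the 15,000 time steps to 11 before the dense head.
    """

    n_classes: int = 4
    conv_blocks: tuple[tuple[int, int, int], ...] = (
        (8, 9, 4),
        (16, 9, 4),
        (32, 9, 4),
        (32, 9, 4),
    )
    input_stride: int = 5
    dense_units: int = 64
    dropout_rate: float = 0.5
    l2_lambda: float = 1e-4
    input_rows: int = 5
    input_samples: int = 15000

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        for filters, kernel, pool in self.conv_blocks:
            if filters < 1 or kernel < 1 or pool < 1:
                raise ValueError("conv block sizes must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be non-negative")
        if self.dense_units < 1:
            raise ValueError("dense_units must be >= 1")
        if self.input_stride < 1:
            raise ValueError("input_stride must be >= 1")


@dataclass
class ClassProbabilities:
    """Softmax output for one segment, in the model's class order."""

    probs: np.ndarray
    class_order: tuple[ClassLabel, ...]

    @property
    def predicted(self) -> ClassLabel:
        return self.class_order[int(np.argmax(self.probs))]


class _Layer:
    """Base layer: parameter dict, gradient dict, per-layer LR scale."""

    has_weights = False

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.lr_scale: float = 1.0

    def forward(self, x: np.ndarray, training: bool, rng) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def l2_param_names(self) -> tuple[str, ...]:
        return ()

    def extra_state(self) -> dict[str, np.ndarray]:
        return {}

    def load_extra_state(self, state: dict[str, np.ndarray]) -> None:
        pass


class _Conv1d(_Layer):
    """Same-padded 1-D convolution along time; rows are input channels.

    Output position ``t`` sees input positions ``stride*t - pl .. + pr``;
    the output length is ``ceil(T / stride)``.
    """

    has_weights = True

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
    ):
        super().__init__()
        self.in_ch, self.out_ch, self.kernel, self.stride = in_ch, out_ch, kernel, stride
        std = np.sqrt(2.0 / (in_ch * kernel))
        self.params["W"] = rng.normal(0.0, std, size=(out_ch, in_ch, kernel)).astype(
            np.float32
        )
        self.params["b"] = np.zeros(out_ch, dtype=np.float32)
        self._pl = (kernel - 1) // 2
        self._pr = kernel - 1 - self._pl

    def out_len(self, t_in: int) -> int:
        return -(-t_in // self.stride)

    def forward(self, x, training, rng):
        if x.shape[1] != self.in_ch:
            raise ValueError(
                f"expected {self.in_ch} input channels, got {x.shape[1]}"
            )
        # y[b,f,t] = sum_{c,k} W[f,c,k] * xp[b,c,stride*t+k]: GEMM per tap
        s = self.stride
        t_in = x.shape[2]
        t_out = self.out_len(t_in)
        pad_r = self._pr + (s * t_out - t_in)  # cover the last strided window
        xp = np.pad(x, ((0, 0), (0, 0), (self._pl, pad_r)))
        W = self.params["W"]
        y = np.empty((x.shape[0], self.out_ch, t_out), dtype=x.dtype)
        y[:] = self.params["b"][None, :, None]
        tmp = np.empty_like(y)
        for k in range(self.kernel):
            np.matmul(W[:, :, k], xp[:, :, k : k + s * t_out : s], out=tmp)
            y += tmp
        self._xp = xp
        self._t_in = t_in
        return y

    def backward(self, dy):
        W = self.params["W"]
        xp, s = self._xp, self.stride
        t_out = dy.shape[2]
        self.grads["b"] = dy.sum(axis=(0, 2))
        dW = np.empty_like(W)
        dxp = np.zeros_like(xp)
        for k in range(self.kernel):
            sl = slice(k, k + s * t_out, s)
            xk = xp[:, :, sl]
            # (B,F,T) @ (B,T,C) summed over batch -> (F,C)
            dW[:, :, k] = np.matmul(dy, xk.transpose(0, 2, 1)).sum(axis=0)
            dxp[:, :, sl] += np.matmul(W[:, :, k].T, dy)
        self.grads["W"] = dW
        self._xp = None
        return np.ascontiguousarray(dxp[:, :, self._pl : self._pl + self._t_in])

    def l2_param_names(self):
        return ("W",)


class _BatchNorm1d(_Layer):
    """Per-channel batch normalization over (batch, time)."""

    has_weights = True

    def __init__(self, n_ch: int):
        super().__init__()
        self.params["gamma"] = np.ones(n_ch, dtype=np.float32)
        self.params["beta"] = np.zeros(n_ch, dtype=np.float32)
        self.running_mean = np.zeros(n_ch, dtype=np.float32)
        self.running_var = np.ones(n_ch, dtype=np.float32)

    def forward(self, x, training, rng):
        n = x.shape[0] * x.shape[2]
        if training:
            # single-pass sufficient statistics (einsum avoids strided reductions)
            s1 = np.einsum("bct->c", x, optimize=True)
            s2 = np.einsum("bct,bct->c", x, x, optimize=True)
            mu = s1 / n
            var = np.maximum(s2 / n - mu * mu, 0.0)
            self.running_mean = (
                (1 - _BN_MOMENTUM) * self.running_mean + _BN_MOMENTUM * mu
            ).astype(np.float32)
            self.running_var = (
                (1 - _BN_MOMENTUM) * self.running_var + _BN_MOMENTUM * var
            ).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        ivar = (1.0 / np.sqrt(var + _BN_EPS)).astype(x.dtype)
        xhat = x - mu[None, :, None].astype(x.dtype)
        xhat *= ivar[None, :, None]
        if training:
            self._xhat, self._ivar = xhat, ivar
        y = xhat * self.params["gamma"][None, :, None]
        y += self.params["beta"][None, :, None]
        return y

    def backward(self, dy):
        xhat, ivar = self._xhat, self._ivar
        n = dy.shape[0] * dy.shape[2]
        self.grads["gamma"] = np.einsum("bct,bct->c", dy, xhat, optimize=True)
        self.grads["beta"] = np.einsum("bct->c", dy, optimize=True)
        gamma = self.params["gamma"]
        s1 = (self.grads["beta"] * gamma) / n
        s2 = (self.grads["gamma"] * gamma) / n
        # dx = ivar * (dxhat - mean(dxhat) - xhat * mean(dxhat * xhat))
        dx = dy * gamma[None, :, None]
        dx -= s1[None, :, None].astype(dy.dtype)
        dx -= xhat * s2[None, :, None].astype(dy.dtype)
        dx *= ivar[None, :, None]
        self._xhat = self._ivar = None
        return dx

    def extra_state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def load_extra_state(self, state):
        self.running_mean = state["running_mean"].astype(np.float32)
        self.running_var = state["running_var"].astype(np.float32)


class _ReLU(_Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class _MaxPool1d(_Layer):
    """Non-overlapping max pooling; a trailing remainder is dropped."""

    def __init__(self, pool: int):
        super().__init__()
        self.pool = pool

    def forward(self, x, training, rng):
        b, c, t = x.shape
        t_out = t // self.pool
        self._t_in = t
        xr = x[:, :, : t_out * self.pool].reshape(b, c, t_out, self.pool)
        y = xr.max(axis=3)
        self._xr, self._y = xr, y
        return y

    def backward(self, dy):
        b, c, t_out = dy.shape
        # route gradient to every maximal sample (ties are measure-zero for
        # continuous inputs, so this matches argmax routing in practice)
        mask = self._xr == self._y[..., None]
        dxr = mask * dy[..., None]
        dx = np.zeros((b, c, self._t_in), dtype=dy.dtype)
        dx[:, :, : t_out * self.pool] = dxr.reshape(b, c, t_out * self.pool)
        self._xr = self._y = None
        return dx


class _Flatten(_Layer):
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class _Dropout(_Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate
        self._mask = None

    def forward(self, x, training, rng):
        if not training or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode requires an RNG")
        self._mask = (rng.random(x.shape) >= self.rate).astype(np.float32) / (
            1.0 - self.rate
        )
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx


class _Dense(_Layer):
    has_weights = True

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, std: float | None = None):
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        if std is None:
            std = np.sqrt(2.0 / n_in)
        self.params["W"] = rng.normal(0.0, std, size=(n_in, n_out)).astype(np.float32)
        self.params["b"] = np.zeros(n_out, dtype=np.float32)

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        dx = dy @ self.params["W"].T
        self._x = None
        return dx

    def l2_param_names(self):
        return ("W",)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class CNNModel:
    """The assembled classifier: layer stack + class-label ordering."""

    def __init__(
        self,
        config: ModelConfig,
        class_order: tuple[ClassLabel, ...],
        rng_seed: int,
    ):
        if len(class_order) != config.n_classes:
            raise ValueError("class_order length must equal n_classes")
        self.config = config
        self.class_order = tuple(class_order)
        self.rng_seed = rng_seed
        rng = np.random.default_rng(rng_seed)
        layers: list[_Layer] = []
        in_ch = config.input_rows
        t = config.input_samples
        for i, (filters, kernel, pool) in enumerate(config.conv_blocks):
            stride = config.input_stride if i == 0 else 1
            conv = _Conv1d(in_ch, filters, kernel, rng, stride=stride)
            layers.append(conv)
            layers.append(_BatchNorm1d(filters))
            layers.append(_ReLU())
            layers.append(_MaxPool1d(pool))
            in_ch = filters
            t = conv.out_len(t) // pool
            if t < 1:
                raise ValueError("pooling collapsed the time axis to zero length")
        layers.append(_Flatten())
        layers.append(_Dropout(config.dropout_rate))
        layers.append(_Dense(in_ch * t, config.dense_units, rng))
        layers.append(_ReLU())
        layers.append(_Dropout(config.dropout_rate))
        layers.append(_Dense(config.dense_units, config.n_classes, rng))
        self.layers = layers
        self._flat_dim = in_ch * t

    # ----- forward / loss -------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        if x.dtype != np.float64:  # keep float64 inputs (gradient checks), else float32
            x = x.astype(np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1:] != (self.config.input_rows, self.config.input_samples):
            raise ValueError(
                f"input shape {x.shape} incompatible with model input "
                f"({self.config.input_rows}, {self.config.input_samples})"
            )
        return x

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Return logits of shape (batch, n_classes)."""
        out = self._check_input(x)
        for layer in self.layers:
            out = layer.forward(out, training, rng)
        return out

    def loss_and_backward(
        self,
        x: np.ndarray,
        y: np.ndarray,
        rng: np.random.Generator | None = None,
    ) -> float:
        """Cross-entropy + L2 loss; fills every layer's gradient dict.

        ``y`` holds integer class indices into ``class_order``.
        """
        y = np.asarray(y)
        logits = self.forward(x, training=True, rng=rng)
        probs = _softmax(logits.astype(np.float64))
        b = probs.shape[0]
        ce = -np.mean(np.log(np.clip(probs[np.arange(b), y], 1e-12, None)))
        l2 = 0.0
        lam = self.config.l2_lambda
        if lam > 0:
            for layer in self.layers:
                for name in layer.l2_param_names():
                    w = layer.params[name]
                    l2 += 0.5 * lam * float(np.sum(w.astype(np.float64) ** 2))
        dlogits = probs.copy()
        dlogits[np.arange(b), y] -= 1.0
        grad = (dlogits / b).astype(logits.dtype)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        if lam > 0:
            for layer in self.layers:
                for name in layer.l2_param_names():
                    layer.grads[name] = layer.grads[name] + lam * layer.params[name]
        return float(ce + l2)

    def loss(self, x: np.ndarray, y: np.ndarray) -> float:
        """Evaluation-mode cross-entropy + L2 (no gradients, no dropout)."""
        y = np.asarray(y)
        probs = _softmax(self.forward(x, training=False).astype(np.float64))
        ce = -np.mean(np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None)))
        l2 = 0.0
        lam = self.config.l2_lambda
        if lam > 0:
            for layer in self.layers:
                for name in layer.l2_param_names():
                    l2 += 0.5 * lam * float(
                        np.sum(layer.params[name].astype(np.float64) ** 2)
                    )
        return float(ce + l2)

    # ----- bookkeeping ----------------------------------------------------

    def parameters(self) -> Iterator[tuple[_Layer, str, np.ndarray]]:
        for layer in self.layers:
            for name, arr in layer.params.items():
                yield layer, name, arr

    @property
    def n_parameters(self) -> int:
        return sum(arr.size for _, _, arr in self.parameters())

    @property
    def output_layer(self) -> _Dense:
        layer = self.layers[-1]
        assert isinstance(layer, _Dense)
        return layer

    def reset_output_layer(
        self,
        new_class_order: Sequence[ClassLabel],
        rng: np.random.Generator,
        init_std: float = 0.01,
    ) -> None:
        """Replace the softmax head with a fresh normal-initialized layer.

        Used by transfer learning: the transferred feature layers keep
        their weights while the classification head is re-randomized
        (normal, mean 0) and resized to the new class set.
        """
        new_class_order = tuple(new_class_order)
        head = _Dense(
            self.config.dense_units,
            len(new_class_order),
            rng,
            std=init_std,
        )
        self.layers[-1] = head
        self.class_order = new_class_order
        self.config = dataclasses.replace(self.config, n_classes=len(new_class_order))

    # ----- serialization --------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                state[f"layer{i}.{name}"] = arr
            for name, arr in layer.extra_state().items():
                state[f"layer{i}.{name}"] = arr
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = state[f"layer{i}.{name}"].astype(np.float32).copy()
            extra = {
                name: state[f"layer{i}.{name}"] for name in layer.extra_state()
            }
            layer.load_extra_state(extra)

    def copy(self) -> "CNNModel":
        clone = CNNModel(self.config, self.class_order, self.rng_seed)
        clone.load_state_dict(self.state_dict())
        return clone


def build_model(
    cfg: ModelConfig,
    rng_seed: int,
    class_order: Sequence[ClassLabel] | None = None,
) -> CNNModel:
    """Construct a seeded classifier.

    ``class_order`` defaults to the 3-class generalized or 4-class
    specialized ordering when ``n_classes`` is 3 or 4; otherwise it must
    be given explicitly.
    """
    if class_order is None:
        if cfg.n_classes == 3:
            class_order = GENERALIZED_CLASSES
        elif cfg.n_classes == 4:
            class_order = SPECIALIZED_CLASSES
        else:
            raise ValueError(
                "class_order must be given explicitly for n_classes not in {3, 4}"
            )
    return CNNModel(cfg, tuple(class_order), rng_seed)


def predict_proba_batch(model: CNNModel, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Evaluation-mode class probabilities for a stack of feature matrices."""
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    out = np.empty((x.shape[0], model.config.n_classes), dtype=np.float64)
    for start in range(0, x.shape[0], batch_size):
        logits = model.forward(x[start : start + batch_size], training=False)
        out[start : start + logits.shape[0]] = _softmax(logits.astype(np.float64))
    return out


def predict_proba(model: CNNModel, matrix: FeatureMatrix | np.ndarray) -> ClassProbabilities:
    """Class probabilities for a single feature matrix."""
    values = matrix.values if isinstance(matrix, FeatureMatrix) else np.asarray(matrix)
    probs = predict_proba_batch(model, values)[0]
    return ClassProbabilities(probs, model.class_order)
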