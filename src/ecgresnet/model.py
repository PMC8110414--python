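"""A 1D residual convolutional network for heartbeat-slice
classification, implemented directly on numpy.

The architecture follows the "improved ResNet-18" design for
single-lead ECG slices:

* an initial length-32 convolution (large kernels suit low-frequency,
  low-sampling-rate signals better than the 3-wide kernels of image
  ResNets) with ReLU and dropout 0.5 on the convolutional path;
* one *classic* residual stage: two convolutions with a ReLU between
  them, added to a max-pooling shortcut of the stage input;
* seven *improved* residual stages, each prefixed by a batch
  normalization; the kernel count starts at 12 and doubles at stages
  3, 5 and 7 (12 -> 24 -> 48 -> 96) with stride-2 downsampling and a
  1x1 projection shortcut at each width change, identity shortcuts
  elsewhere;
* flatten and a fully connected softmax head with 5 outputs.

Residual blocks compute ``y = F(x) + shortcut(x)`` with
``F = W2 * relu(W1 * x)``; a ReLU follows the addition.  L2
regularization applies to every convolution kernel and the fully
connected weights.  All forward and backward passes are plain numpy,
so evaluation is deterministic and training is reproducible from a
seed.

Tensors are laid out ``(batch, channels, length)``; convolutions use
"same" zero padding so the output length is ``ceil(L / stride)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ModelSpec",
    "ResidualBlock",
    "Model",
    "build_model",
    "softmax",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, stabilized by max subtraction (invariant to
    adding a constant to all logits)."""
    z = np.asarray(logits, dtype=float)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("name", "value", "grad", "regularized")

    def __init__(self, name: str, value: np.ndarray, regularized: bool = False):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)
        self.regularized = regularized


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _same_pad(L: int, k: int, stride: int) -> tuple[int, int, int]:
    L_out = -(-L // stride)
    pad = max((L_out - 1) * stride + k - L, 0)
    return L_out, pad // 2, pad - pad // 2


class Conv1d(Layer):
    """Cross-correlation with "same" padding; He fan-in init."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (in_channels * kernel))
        self.w = Param(
            f"{name}.w",
            rng.standard_normal((out_channels, in_channels, kernel)) * std,
            regularized=True,
        )
        self.b = Param(f"{name}.b", np.zeros(out_channels))
        self.k, self.s = kernel, stride
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def _windows(self, xp: np.ndarray) -> np.ndarray:
        return sliding_window_view(xp, self.k, axis=2)[:, :, :: self.s, :]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, C, L = x.shape
        L_out, pl, pr = _same_pad(L, self.k, self.s)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        win = self._windows(xp)[:, :, :L_out, :]
        y = np.tensordot(win, self.w.value, axes=([1, 3], [1, 2]))
        y = np.ascontiguousarray(y.transpose(0, 2, 1)) + self.b.value[None, :, None]
        self._cache = (xp, L, pl, L_out) if training else None
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp, L, pl, L_out = self._cache
        win = self._windows(xp)[:, :, :L_out, :]
        self.w.grad += np.tensordot(grad, win, axes=([0, 2], [0, 2]))
        self.b.grad += grad.sum(axis=(0, 2))
        contrib = np.einsum("bfl,fck->bclk", grad, self.w.value)
        dxp = np.zeros_like(xp)
        for t in range(self.k):
            dxp[:, :, t : t + L_out * self.s : self.s] += contrib[:, :, :, t]
        return dxp[:, :, pl : pl + L]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length); running
    statistics are used in evaluation mode."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 name: str = "bn"):
        self.gamma = Param(f"{name}.gamma", np.ones(channels))
        self.beta = Param(f"{name}.beta", np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * invstd[None, :, None]
        if training:
            self._cache = (xhat, invstd, x.shape[0] * x.shape[2])
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, invstd, n = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        dxhat = grad * self.gamma.value[None, :, None]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (invstd[None, :, None] / n) * (n * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool1d(Layer):
    """Max pooling with "same" padding (pad value -inf)."""

    def __init__(self, kernel: int, stride: int = 1):
        self.k, self.s = kernel, stride
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, C, L = x.shape
        L_out, pl, pr = _same_pad(L, self.k, self.s)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)), constant_values=-np.inf)
        win = sliding_window_view(xp, self.k, axis=2)[:, :, :: self.s, :][:, :, :L_out, :]
        idx = win.argmax(axis=-1)
        y = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, xp.shape, L, pl, L_out) if training else None
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        idx, xp_shape, L, pl, L_out = self._cache
        B, C, Lp = xp_shape
        pos = np.arange(L_out)[None, None, :] * self.s + idx
        dxp = np.zeros((B * C, Lp))
        np.add.at(
            dxp,
            (np.repeat(np.arange(B * C)[:, None], L_out, axis=1),
             pos.reshape(B * C, L_out)),
            grad.reshape(B * C, L_out),
        )
        return dxp.reshape(B, C, Lp)[:, :, pl : pl + L]


class Dropout(Layer):
    """Inverted dropout on the convolutional path."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, name: str = "fc"):
        std = np.sqrt(2.0 / in_features)
        self.w = Param(f"{name}.w", rng.standard_normal((in_features, out_features)) * std,
                       regularized=True)
        self.b = Param(f"{name}.b", np.zeros(out_features))

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x if training else None
        return x @ self.w.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class ResidualBlock(Layer):
    """``y = F(x) + shortcut(x)``.

    ``branch`` realizes the residual mapping F (two convolutions with
    a ReLU between them); ``shortcut`` is ``None`` for identity, a
    max-pool for the classic stage, or a 1x1 strided projection when
    the channel count or length changes.  With the branch weights
    zeroed and an identity shortcut the block is exactly the
    identity.
    """

    def __init__(self, branch: Sequential, shortcut: Layer | None = None):
        self.branch = branch
        self.shortcut = shortcut

    def params(self) -> list[Param]:
        out = self.branch.params()
        if self.shortcut is not None:
            out += self.shortcut.params()
        return out

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        f = self.branch.forward(x, training)
        s = x if self.shortcut is None else self.shortcut.forward(x, training)
        if f.shape != s.shape:
            raise ValueError(
                f"residual branch output {f.shape} does not match shortcut "
                f"{s.shape}; a projection shortcut is required"
            )
        return f + s

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dx = self.branch.backward(grad)
        if self.shortcut is None:
            return dx + grad
        return dx + self.shortcut.backward(grad)


@dataclass(frozen=True)
class ModelSpec:
    """Complete architecture description.

    The defaults are the full-size network: 1080-sample input, 12
    initial kernels of length 32, seven improved residual stages with
    the filter schedule (12, 12, 24, 24, 48, 48, 96) — doubling, with
    stride-2 downsampling and projection shortcuts, at stages 3, 5
    and 7 — kernel length 16 inside residual stages, dropout 0.5.
    ``scaled_down`` returns a reduced variant for CPU-scale
    experiments on synthetic data.
    """

    input_length: int = 1080
    n_classes: int = 5
    initial_filters: int = 12
    initial_kernel: int = 32
    initial_stride: int = 1
    residual_kernel: int = 16
    n_improved_stages: int = 7
    filter_schedule: tuple[int, ...] = (12, 12, 24, 24, 48, 48, 96)
    shortcut_pool: int = 3
    dropout_rate: float = 0.5
    l2_alpha: float = 1e-4

    def __post_init__(self) -> None:
        if len(self.filter_schedule) != self.n_improved_stages:
            raise ValueError(
                f"filter schedule of length {len(self.filter_schedule)} does not "
                f"match {self.n_improved_stages} improved stages"
            )
        if any(b < a for a, b in zip(self.filter_schedule, self.filter_schedule[1:])):
            raise ValueError("filter counts must be non-decreasing across stages")
        if self.filter_schedule and self.filter_schedule[0] < self.initial_filters:
            raise ValueError("filter counts must not shrink below the initial count")

    @classmethod
    def scaled_down(cls) -> "ModelSpec":
        """A small variant for single-CPU experiments: 8 initial
        kernels with stride 4, two improved stages (8 -> 16 -> 32).

        The length-16 residual kernels keep a receptive field of
        roughly two seconds at the reduced resolution — wide enough
        to sense RR-interval irregularities, the only cue for
        supraventricular premature beats.  Dropout is lowered to 0.2:
        rate 0.5 on an 8-channel feature map starves the small model
        (observed as majority-class collapse).
        """
        return cls(
            initial_filters=8,
            initial_stride=4,
            residual_kernel=16,
            n_improved_stages=2,
            filter_schedule=(16, 32),
            dropout_rate=0.2,
        )


class Model:
    """The assembled network; holds layers, the dropout RNG and the
    architecture spec."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        self.rng = np.random.default_rng(seed)
        init = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        s = spec
        layers: list[Layer] = [
            Conv1d(1, s.initial_filters, s.initial_kernel, stride=s.initial_stride,
                   rng=init, name="conv0"),
            ReLU(),
            Dropout(s.dropout_rate, self.rng),
        ]
        f = s.initial_filters
        # classic residual stage: conv-relu-conv branch, max-pool shortcut
        branch = Sequential([
            Conv1d(f, f, s.residual_kernel, rng=init, name="classic.conv1"),
            ReLU(),
            Conv1d(f, f, s.residual_kernel, rng=init, name="classic.conv2"),
        ])
        layers += [
            ResidualBlock(branch, MaxPool1d(s.shortcut_pool, stride=1)),
            ReLU(),
        ]
        # improved stages: batch norm first, then the classic pattern
        prev = f
        for i, nf in enumerate(s.filter_schedule, start=1):
            stride = 2 if nf != prev else 1
            branch = Sequential([
                Conv1d(prev, nf, s.residual_kernel, stride=stride, rng=init,
                       name=f"stage{i}.conv1"),
                ReLU(),
                Conv1d(nf, nf, s.residual_kernel, rng=init, name=f"stage{i}.conv2"),
            ])
            shortcut = (
                Conv1d(prev, nf, 1, stride=stride, rng=init, name=f"stage{i}.proj")
                if (nf != prev or stride > 1)
                else None
            )
            layers += [
                BatchNorm1d(prev, name=f"stage{i}.bn"),
                ResidualBlock(branch, shortcut),
                ReLU(),
            ]
            prev = nf
        layers.append(Flatten())
        flat = prev * self._final_length()
        layers.append(Dense(flat, s.n_classes, rng=init, name="fc"))
        self.net = Sequential(layers)

    def _final_length(self) -> int:
        L = -(-self.spec.input_length // self.spec.initial_stride)
        prev = self.spec.initial_filters
        for nf in self.spec.filter_schedule:
            if nf != prev:
                L = -(-L // 2)
            prev = nf
        return L

    # -- inference ---------------------------------------------------------

    def _as_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, None, :]
        if X.shape[2] != self.spec.input_length:
            raise ValueError(
                f"input length {X.shape[2]} does not match the model's "
                f"{self.spec.input_length}"
            )
        return X

    def forward_logits(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        return self.net.forward(self._as_input(X), training)

    def forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        """Class probabilities, shape (batch, n_classes)."""
        return softmax(self.forward_logits(X, training))

    def predict(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Argmax class indices, evaluated in batches."""
        X = np.asarray(X, dtype=float)
        out = []
        for i in range(0, len(X), batch_size):
            out.append(self.forward_logits(X[i : i + batch_size]).argmax(axis=1))
        return np.concatenate(out) if out else np.zeros(0, dtype=int)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.net.backward(dlogits)

    # -- parameter management ---------------------------------------------

    def parameters(self) -> list[Param]:
        return self.net.params()

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def state(self) -> list[np.ndarray]:
        """Snapshot of all weights and batch-norm running statistics."""
        arrays = [p.value.copy() for p in self.parameters()]
        for l in self.net.layers:
            if isinstance(l, BatchNorm1d):
                arrays += [l.running_mean.copy(), l.running_var.copy()]
        return arrays

    def load_state(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, a in zip(params, arrays[: len(params)]):
            p.value[...] = a
        rest = iter(arrays[len(params) :])
        for l in self.net.layers:
            if isinstance(l, BatchNorm1d):
                l.running_mean[...] = next(rest)
                l.running_var[...] = next(rest)

    def summary(self) -> str:
        lines = [f"input (1, {self.spec.input_length})"]
        for p in self.parameters():
            lines.append(f"  {p.name}: {p.value.shape}")
        lines.append(f"total parameters: {self.n_parameters()}")
        return "\n".join(lines)


def build_model(spec: ModelSpec = ModelSpec(), seed: int = 0) -> Model:
    """Build the network with seeded He initialization; two builds
    from the same spec and seed have identical weights."""
    return Model(spec, seed=seed)
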