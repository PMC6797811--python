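"""A small convolutional network for pulse-image classification, in numpy.

The classifier is a 10-layer CNN: three convolution layers, three max-pooling
layers, a dropout layer between the third pool and the first fully connected
layer, two fully connected layers, and a softmax output.  It is trained with
mini-batch Adam on categorical cross-entropy, and the best weights as
measured by test error are checkpointed each epoch.

Everything is implemented directly on numpy arrays: convolution as an
im2col/GEMM pair, non-overlapping max pooling via an argmax scatter, inverted
dropout, and the standard Adam moment recursions.  All randomness (weight
initialisation, shuffling, dropout masks) flows from explicit generators, so
a run is bit-reproducible given its seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ConvSpec",
    "PoolSpec",
    "ArchitectureConfig",
    "TrainingConfig",
    "TrainingHistory",
    "PulseCNN",
    "proposed_architecture",
    "lenet_architecture",
    "build_model",
    "train",
    "predict",
    "evaluate_error",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConvSpec:
    out_channels: int
    kernel: tuple[int, int] = (5, 5)
    stride: int = 1
    padding: str = "same"  # "same" or "valid"


@dataclass(frozen=True)
class PoolSpec:
    window: int = 2
    stride: int = 2

    def __post_init__(self) -> None:
        if self.window != self.stride:
            raise ValueError("only non-overlapping pooling (window == stride) is supported")


@dataclass(frozen=True)
class ArchitectureConfig:
    """Schema for the 10-layer family: 3 conv + 3 pool + dropout + 2 FC + softmax."""

    convs: tuple[ConvSpec, ConvSpec, ConvSpec]
    pools: tuple[PoolSpec, PoolSpec, PoolSpec]
    dropout_rate: float = 0.5
    fc_hidden: int = 128
    n_classes: int = 6
    input_shape: tuple[int, int, int] = (1, 200, 200)

    def __post_init__(self) -> None:
        if len(self.convs) != 3 or len(self.pools) != 3:
            raise ValueError("architecture requires exactly 3 conv and 3 pool stages")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.fc_hidden < 1 or self.n_classes < 2:
            raise ValueError("fc sizes must be positive (n_classes >= 2)")

    @property
    def named_layer_count(self) -> int:
        """Conv x3 + pool x3 + dropout + FC x2 + softmax = 10 named layers."""
        return len(self.convs) + len(self.pools) + 1 + 2 + 1


def proposed_architecture(
    n_classes: int = 6,
    input_shape: tuple[int, int, int] = (1, 200, 200),
    channels: tuple[int, int, int] = (16, 32, 64),
    kernel: tuple[int, int] = (5, 5),
    first_stride: int = 1,
    fc_hidden: int = 128,
    dropout_rate: float = 0.5,
) -> ArchitectureConfig:
    """The proposed 10-layer configuration (kernel/channel sizes are tunable)."""
    return ArchitectureConfig(
        convs=(
            ConvSpec(channels[0], kernel, first_stride, "same"),
            ConvSpec(channels[1], kernel, 1, "same"),
            ConvSpec(channels[2], kernel, 1, "same"),
        ),
        pools=(PoolSpec(), PoolSpec(), PoolSpec()),
        dropout_rate=dropout_rate,
        fc_hidden=fc_hidden,
        n_classes=n_classes,
        input_shape=input_shape,
    )


def lenet_architecture(
    n_classes: int = 6,
    input_shape: tuple[int, int, int] = (1, 200, 200),
) -> ArchitectureConfig:
    """A LeNet-style baseline expressed in the same schema (no dropout)."""
    return ArchitectureConfig(
        convs=(
            ConvSpec(6, (5, 5), 1, "same"),
            ConvSpec(16, (5, 5), 1, "same"),
            ConvSpec(32, (5, 5), 1, "same"),
        ),
        pools=(PoolSpec(), PoolSpec(), PoolSpec()),
        dropout_rate=0.0,
        fc_hidden=84,
        n_classes=n_classes,
        input_shape=input_shape,
    )


@dataclass(frozen=True)
class TrainingConfig:
    """Adam + loop hyperparameters.

    ``delta`` is Adam's numerical-stability constant; ``epsilon_reported``
    is stored verbatim alongside it for provenance (some tool chains print a
    separate epsilon) but plays no role in the update.
    """

    learning_rate: float = 0.001
    rho1: float = 0.9
    rho2: float = 0.999
    delta: float = 1e-8
    epsilon_reported: float = 0.001
    batch_size: int = 64
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 <= self.rho1 < 1 and 0 <= self.rho2 < 1):
            raise ValueError("rho1, rho2 must lie in [0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


@dataclass
class TrainingHistory:
    cost: list[float] = field(default_factory=list)          # mean training loss
    train_error: list[float] = field(default_factory=list)   # 1 - train accuracy
    test_error: list[float] = field(default_factory=list)    # 1 - test accuracy
    best_epoch: int = -1
    best_state: dict[str, np.ndarray] | None = None

    def validate(self) -> None:
        if self.best_epoch >= 0 and self.test_error:
            assert self.test_error[self.best_epoch] == min(self.test_error)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


def _same_pad(size: int, kernel: int, stride: int) -> tuple[int, int]:
    out = -(-size // stride)  # ceil
    total = max(0, (out - 1) * stride + kernel - size)
    return total // 2, total - total // 2


class _Conv2d:
    def __init__(self, cin: int, cout: int, kernel: tuple[int, int], stride: int,
                 padding: str, rng: np.random.Generator) -> None:
        kh, kw = kernel
        fan_in = cin * kh * kw
        self.W = (rng.standard_normal((cout, cin, kh, kw)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.stride = stride
        self.padding = padding
        self.kernel = kernel
        self._cache = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def set_params(self, p):
        self.W, self.b = p["W"], p["b"]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        kh, kw = self.kernel
        s = self.stride
        if self.padding == "same":
            pt, pb = _same_pad(x.shape[2], kh, s)
            pl, pr = _same_pad(x.shape[3], kw, s)
        else:
            pt = pb = pl = pr = 0
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr))) if (pt or pb or pl or pr) else x
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
        n, cin, ho, wo = win.shape[:4]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * ho * wo, cin * kh * kw)
        wmat = self.W.reshape(self.W.shape[0], -1)
        out = cols @ wmat.T + self.b
        self._cache = (cols, xp.shape, (pt, pl), (n, ho, wo))
        return np.ascontiguousarray(out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xp_shape, (pt, pl), (n, ho, wo) = self._cache
        kh, kw = self.kernel
        s = self.stride
        cout = self.W.shape[0]
        cin = self.W.shape[1]
        dflat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, cout)
        self.dW = (dflat.T @ cols).reshape(self.W.shape)
        self.db = dflat.sum(axis=0)
        dcols = (dflat @ self.W.reshape(cout, -1)).reshape(n, ho, wo, cin, kh, kw)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # n, cin, ho, wo, kh, kw
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[:, :, :, :, i, j]
        h0, w0 = self._orig_hw  # unpad to the original input size
        return dxp[:, :, pt : pt + h0, pl : pl + w0]

    def grads(self):
        return {"W": self.dW, "b": self.db}


class _MaxPool2d:
    def __init__(self, window: int) -> None:
        self.w = window
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        w = self.w
        n, c, h, wd = x.shape
        ho, wo = h // w, wd // w
        xc = x[:, :, : ho * w, : wo * w]
        patches = xc.reshape(n, c, ho, w, wo, w).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, w * w)
        idx = patches.argmax(axis=-1)
        out = np.take_along_axis(patches, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape, (ho, wo))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, x_shape, (ho, wo) = self._cache
        w = self.w
        n, c, h, wd = x_shape
        dpatches = np.zeros((n, c, ho, wo, w * w), dtype=np.float32)
        np.put_along_axis(dpatches, idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros(x_shape, dtype=np.float32)
        dx[:, :, : ho * w, : wo * w] = (
            dpatches.reshape(n, c, ho, wo, w, w).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho * w, wo * w)
        )
        return dx


class _ReLU:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _Dropout:
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float) -> None:
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if self.rng is None:
            self.rng = np.random.default_rng(0)
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class _Flatten:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class _Linear:
    def __init__(self, din: int, dout: int, rng: np.random.Generator) -> None:
        self.W = (rng.standard_normal((dout, din)) * np.sqrt(2.0 / din)).astype(np.float32)
        self.b = np.zeros(dout, dtype=np.float32)

    def params(self):
        return {"W": self.W, "b": self.b}

    def set_params(self, p):
        self.W, self.b = p["W"], p["b"]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = dout.T @ self._x
        self.db = dout.sum(axis=0)
        return dout @ self.W

    def grads(self):
        return {"W": self.dW, "b": self.db}


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    p = _softmax(logits)
    n = len(y)
    loss = float(-np.mean(np.log(np.clip(p[np.arange(n), y], 1e-12, None))))
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class ShapeError(ValueError):
    pass


class PulseCNN:
    """The 10-layer pulse classifier assembled from an :class:`ArchitectureConfig`."""

    def __init__(self, cfg: ArchitectureConfig, rng: np.random.Generator | None = None) -> None:
        if rng is None:
            rng = np.random.default_rng(0)
        self.cfg = cfg
        cin, h, w = cfg.input_shape
        self.layers: list = []
        for conv, pool in zip(cfg.convs, cfg.pools):
            cl = _Conv2d(cin, conv.out_channels, conv.kernel, conv.stride, conv.padding, rng)
            self.layers += [cl, _ReLU(), _MaxPool2d(pool.window)]
            if conv.padding == "same":
                h = -(-h // conv.stride)
                w = -(-w // conv.stride)
            else:
                h = (h - conv.kernel[0]) // conv.stride + 1
                w = (w - conv.kernel[1]) // conv.stride + 1
            cl._orig_hw = None  # filled per forward below
            h //= pool.window
            w //= pool.window
            cin = conv.out_channels
        if h < 1 or w < 1:
            raise ShapeError("conv/pool stack collapses the spatial dimensions to zero")
        flat = cin * h * w
        self.dropout = _Dropout(cfg.dropout_rate)
        self.layers.append(self.dropout)
        self.layers.append(_Flatten())
        self.layers.append(_Linear(flat, cfg.fc_hidden, rng))
        self.layers.append(_ReLU())
        self.layers.append(_Linear(cfg.fc_hidden, cfg.n_classes, rng))
        self._flat_dim = flat

    # -- plumbing ----------------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None, :, :]
        cin, h, w = self.cfg.input_shape
        if x.ndim != 4 or x.shape[1:] != (cin, h, w):
            raise ShapeError(f"expected input (N, {cin}, {h}, {w}), got {x.shape}")
        return x

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = self._check_input(x)
        for layer in self.layers:
            if isinstance(layer, _Conv2d):
                layer._orig_hw = x.shape[2:]
            x = layer.forward(x, training)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def predict_proba(self, x: np.ndarray, batch_size: int = 128) -> np.ndarray:
        x = self._check_input(x)
        outs = [
            _softmax(self.forward(x[i : i + batch_size], training=False))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs, axis=0)

    # -- parameters --------------------------------------------------------

    def _param_layers(self):
        return [l for l in self.layers if hasattr(l, "params")]

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self._param_layers()):
            for k, v in layer.params().items():
                out[f"layer{i}.{k}"] = v.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self._param_layers()):
            layer.set_params({k: state[f"layer{i}.{k}"].copy() for k in layer.params()})

    @property
    def parameter_count(self) -> int:
        return sum(v.size for v in self.state_dict().values())


def build_model(cfg: ArchitectureConfig, rng: np.random.Generator | None = None) -> PulseCNN:
    return PulseCNN(cfg, rng)


def predict(model: PulseCNN, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class labels (argmax, ties broken toward the lowest index) + probabilities."""
    proba = model.predict_proba(images)
    return proba.argmax(axis=1), proba


def evaluate_error(model: PulseCNN, X: np.ndarray, y: np.ndarray) -> float:
    """Classification error (1 - accuracy) in evaluation mode."""
    labels, _ = predict(model, X)
    return float(np.mean(labels != np.asarray(y)))


# ---------------------------------------------------------------------------
# Adam + training loop
# ---------------------------------------------------------------------------


class Adam:
    def __init__(self, lr: float, rho1: float, rho2: float, delta: float) -> None:
        self.lr, self.rho1, self.rho2, self.delta = lr, rho1, rho2, delta
        self.t = 0
        self.m: dict[int, np.ndarray] = {}
        self.v: dict[int, np.ndarray] = {}

    def step(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.rho1, self.rho2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for i, (p, g) in enumerate(zip(params, grads)):
            if i not in self.m:
                self.m[i] = np.zeros_like(p)
                self.v[i] = np.zeros_like(p)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            p -= self.lr * (self.m[i] / c1) / (np.sqrt(self.v[i] / c2) + self.delta)


class ConfigurationError(ValueError):
    pass


def train(
    model: PulseCNN,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    cfg: TrainingConfig = TrainingConfig(),
) -> TrainingHistory:
    """Mini-batch Adam on cross-entropy with best-on-test checkpointing.

    Each epoch records the mean training loss ("cost"), the training error and
    the test error (both in evaluation mode, dropout off); the weights with
    the minimum test error seen so far are kept as the checkpoint.  Two runs
    with the same seed produce identical histories.
    """
    if len(X_train) == 0 or len(X_test) == 0:
        raise ConfigurationError("training and test splits must be non-empty")
    y_train = np.asarray(y_train, dtype=np.int64)
    y_test = np.asarray(y_test, dtype=np.int64)

    root = np.random.default_rng(cfg.seed)
    shuffle_rng, dropout_rng = root.spawn(2)
    model.dropout.rng = dropout_rng

    opt = Adam(cfg.learning_rate, cfg.rho1, cfg.rho2, cfg.delta)
    history = TrainingHistory()
    best_err = np.inf

    n = len(X_train)
    for _epoch in range(cfg.epochs):
        perm = shuffle_rng.permutation(n)
        total_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            logits = model.forward(X_train[idx], training=True)
            loss, dlogits = softmax_cross_entropy(logits, y_train[idx])
            model.backward(dlogits)
            params, grads = [], []
            for layer in model._param_layers():
                for k in ("W", "b"):
                    params.append(layer.params()[k])
                    grads.append(layer.grads()[k])
            opt.step(params, grads)
            total_loss += loss * len(idx)
        history.cost.append(total_loss / n)
        history.train_error.append(evaluate_error(model, X_train, y_train))
        err = evaluate_error(model, X_test, y_test)
        history.test_error.append(err)
        if err < best_err:
            best_err = err
            history.best_epoch = len(history.test_error) - 1
            history.best_state = model.state_dict()
    return history


def save_checkpoint(path, state: dict[str, np.ndarray]) -> None:
    np.savez(path, **state)


def load_checkpoint(path) -> dict[str, np.ndarray]:
    with np.load(path) as z:
        return {k: z[k] for k in z.files}
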