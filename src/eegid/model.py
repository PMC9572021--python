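"""Two 1D-CNN variants for closed-set person identification on 1 s epochs.

Architecture per variant: a stack of [conv(1x5, stride 1, same padding) ->
batch norm -> ReLU -> max-pool(1x2, stride 1x2)] blocks — three blocks with
32/64/128 filters (variant A) or four with 32/64/128/256 (variant B) —
followed by global average pooling, a fully connected layer with one output
per enrolled subject, and softmax.  Training uses Adam with cross-entropy
loss, mini-batches of 64, a constant learning rate of 1e-3, per-epoch
shuffling, and restores the weights of the epoch with the lowest validation
loss (first occurrence on ties).

The network is implemented directly on numpy (forward and backward passes,
Adam) so the package has no deep-learning framework dependency; activations
use a channels-last layout and each convolution is one im2col GEMM, the
fastest arrangement measured for small kernels on a single CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DataShapeError, InvalidConfigError
from .preprocess import SegmentSet

_F32 = np.float32

VARIANT_FILTERS: dict[str, tuple[int, ...]] = {
    "A": (32, 64, 128),
    "B": (32, 64, 128, 256),
}


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters for one variant."""

    variant: str
    n_channels: int
    n_classes: int
    kernel: int = 5
    pool: int = 2

    def __post_init__(self) -> None:
        if self.variant not in VARIANT_FILTERS:
            raise InvalidConfigError(f"variant must be 'A' or 'B', got {self.variant!r}")
        if self.n_classes < 2:
            raise InvalidConfigError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.n_channels < 1 or self.kernel < 1 or self.pool < 1:
            raise InvalidConfigError("n_channels, kernel and pool must be positive")

    @property
    def filters_per_block(self) -> tuple[int, ...]:
        return VARIANT_FILTERS[self.variant]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (Adam + cross-entropy)."""

    max_epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    shuffle_each_epoch: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise InvalidConfigError("max_epochs, batch_size, learning_rate must be positive")


# ---------------------------------------------------------------------------
# layers
#
# Activations flow through the network in channels-last layout (B, L, C):
# on a single CPU this turns every convolution into one well-shaped GEMM
# (im2col rows of length K*Cin) and makes the batch-norm reductions run over
# contiguous columns, which measures several-fold faster than channels-first.


class Conv1d:
    """Stride-1 'same' 1-D convolution (cross-correlation) with bias.

    The canonical weight tensor is (C_out, C_in, K); forward/backward use
    its (K*C_in, C_out) column form.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * kernel))  # He initialization
        self.W = rng.normal(0.0, scale, (c_out, c_in, kernel)).astype(_F32)
        self.b = np.zeros(c_out, dtype=_F32)
        self.pad = (kernel - 1) // 2
        self._col = None
        self.skip_input_grad = False  # set on the first layer: dx is unused there

    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    def _wcol(self) -> np.ndarray:
        K = self.W.shape[2]
        return np.ascontiguousarray(self.W.transpose(2, 1, 0)).reshape(K * self.W.shape[1], -1)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, L, Cin = x.shape
        K = self.W.shape[2]
        xp = np.pad(x, ((0, 0), (self.pad, K - 1 - self.pad), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=1)  # (B, L, Cin, K)
        col = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B * L, K * Cin)
        if train:
            self._col = col
            self._shape = (B, L, Cin)
        y = col @ self._wcol() + self.b
        return y.reshape(B, L, -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, L, Cin = self._shape
        Cout, _, K = self.W.shape
        dy2 = dy.reshape(B * L, Cout)
        dwcol = self._col.T @ dy2  # (K*Cin, Cout)
        self.grads = {
            "W": np.ascontiguousarray(dwcol.reshape(K, Cin, Cout).transpose(2, 1, 0)),
            "b": dy2.sum(axis=0),
        }
        if self.skip_input_grad:
            self._col = None
            return None
        dcol = (dy2 @ self._wcol().T).reshape(B, L, K, Cin)
        dxp = np.zeros((B, L + K - 1, Cin), dtype=dy.dtype)
        for k in range(K):
            dxp[:, k : k + L, :] += dcol[:, :, k, :]
        self._col = None
        return dxp[:, self.pad : self.pad + L, :]


class BatchNorm1d:
    """Per-channel batch normalization over (batch, time)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=_F32)
        self.beta = np.zeros(c, dtype=_F32)
        self.running_mean = np.zeros(c, dtype=_F32)
        self.running_var = np.ones(c, dtype=_F32)
        self.momentum = momentum
        self.eps = eps

    @property
    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            flat = x.reshape(-1, x.shape[2])
            n = flat.shape[0]
            mean = flat.mean(axis=0)
            # E[x^2] - m^2 via einsum: much cheaper than ndarray.var here
            var = np.maximum(np.einsum("nc,nc->c", flat, flat) / n - mean * mean, 0.0)
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mean).astype(_F32)
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * var).astype(_F32)
            ivar = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
            xhat = (x - mean) * ivar
            self._xhat, self._ivar = xhat, ivar
            return self.gamma * xhat + self.beta
        ivar = 1.0 / np.sqrt(self.running_var + self.eps)
        return self.gamma * ((x - self.running_mean) * ivar) + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, ivar = self._xhat, self._ivar
        n = dy.shape[0] * dy.shape[1]
        dgamma = np.einsum("nc,nc->c", dy.reshape(-1, dy.shape[2]), xhat.reshape(-1, dy.shape[2]))
        dbeta = dy.reshape(-1, dy.shape[2]).sum(axis=0)
        self.grads = {"gamma": dgamma, "beta": dbeta}
        coef = self.gamma * ivar / n
        dx = coef * (n * dy - dbeta - xhat * dgamma)
        self._xhat = self._ivar = None
        return dx.astype(dy.dtype)

    # running statistics travel with the state dict but are not optimized
    @property
    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class ReLU:
    params: dict = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool1d:
    """Non-overlapping max pooling; a trailing odd sample is dropped.

    Size 2 (the only size the architecture uses) is evaluated with pairwise
    maximum/compare, which is far faster than an axis reduction over a
    length-2 axis; ties resolve to the earlier sample, matching argmax.
    """

    params: dict = {}

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, L, C = x.shape
        Lo = L // self.size
        if self.size == 2:
            a = x[:, 0 : 2 * Lo : 2, :]
            b = x[:, 1 : 2 * Lo : 2, :]
            if train:
                self._left_wins = a >= b
                self._in_len = L
            return np.maximum(a, b)
        xr = x[:, : Lo * self.size, :].reshape(B, Lo, self.size, C)
        if train:
            self._argmax = xr.argmax(axis=2)
            self._in_len = L
        return xr.max(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, Lo, C = dy.shape
        dx = np.zeros((B, self._in_len, C), dtype=dy.dtype)
        if self.size == 2:
            dx[:, 0 : 2 * Lo : 2, :] = dy * self._left_wins
            dx[:, 1 : 2 * Lo : 2, :] = dy * ~self._left_wins
            self._left_wins = None
            return dx
        dxr = np.zeros((B, Lo, self.size, C), dtype=dy.dtype)
        np.put_along_axis(dxr, self._argmax[:, :, None, :], dy[:, :, None, :], axis=2)
        dx[:, : Lo * self.size, :] = dxr.reshape(B, Lo * self.size, C)
        self._argmax = None
        return dx


class GlobalAvgPool:
    """Temporal mean of each feature map: (B, L, C) -> (B, C)."""

    params: dict = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._in_len = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.broadcast_to(dy[:, None, :] / self._in_len, (dy.shape[0], self._in_len, dy.shape[1])).copy()


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, (n_in, n_out)).astype(_F32)
        self.b = np.zeros(n_out, dtype=_F32)

    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads = {"W": self._x.T @ dy, "b": dy.sum(axis=0)}
        dx = dy @ self.W.T
        self._x = None
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# network


class CNN1D:
    """Sequential network for one variant; see module docstring."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        layers: list = []
        c_in = config.n_channels
        for c_out in config.filters_per_block:
            layers += [
                Conv1d(c_in, c_out, config.kernel, rng),
                BatchNorm1d(c_out),
                ReLU(),
                MaxPool1d(config.pool),
            ]
            c_in = c_out
        layers.append(GlobalAvgPool())
        layers.append(Dense(c_in, config.n_classes, rng))
        layers[0].skip_input_grad = True
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a (batch, channels, time) input tensor."""
        x = np.ascontiguousarray(np.transpose(x, (0, 2, 1)))  # to channels-last
        for layer in self.layers:
            x = layer.forward(x, train)
        return x  # logits

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def trainable(self):
        """Yield (layer_index, param_name, array) for every trainable tensor."""
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                yield i, name, layer.params[name]

    @property
    def n_parameters(self) -> int:
        return sum(arr.size for _, _, arr in self.trainable())

    def state_dict(self) -> dict:
        state = {}
        for i, name, arr in self.trainable():
            state[f"{i}.{name}"] = arr.copy()
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm1d):
                for name, arr in layer.buffers.items():
                    state[f"{i}.{name}"] = arr.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            for name in list(layer.params):
                setattr(layer, name, state[f"{i}.{name}"].copy())
            if isinstance(layer, BatchNorm1d):
                layer.running_mean = state[f"{i}.running_mean"].copy()
                layer.running_var = state[f"{i}.running_var"].copy()


def build_model(cfg: ModelConfig, seed: int = 0) -> CNN1D:
    """Instantiate an untrained network with seeded initialization."""
    return CNN1D(cfg, seed=seed)


def count_parameters(cfg: ModelConfig) -> int:
    """Closed-form trainable-parameter count for a configuration.

    Per block: Cout*Cin*K + Cout conv weights/bias plus 2*Cout batch-norm
    scale/shift; head: F_last*n_classes + n_classes.
    """
    total = 0
    c_in = cfg.n_channels
    for c_out in cfg.filters_per_block:
        total += c_out * c_in * cfg.kernel + c_out + 2 * c_out
        c_in = c_out
    total += c_in * cfg.n_classes + cfg.n_classes
    return total


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainedModel:
    """A trained network plus its configuration and training history."""

    config: ModelConfig
    network: CNN1D
    train_config: TrainConfig
    history: dict = field(default_factory=dict)
    best_epoch: int = 0  # 0-based index into history rows

    def __post_init__(self) -> None:
        losses = self.history.get("val_loss")
        if losses:
            expect = int(np.argmin(losses))  # first occurrence on ties
            if self.best_epoch != expect:
                raise InvalidConfigError(
                    f"best_epoch {self.best_epoch} is not the first argmin of val_loss"
                )


class _Adam:
    def __init__(self, network: CNN1D, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {f"{i}.{n}": np.zeros_like(a) for i, n, a in network.trainable()}
        self.v = {f"{i}.{n}": np.zeros_like(a) for i, n, a in network.trainable()}

    def step(self, network: CNN1D) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, layer in enumerate(network.layers):
            if not layer.params:
                continue
            for name, g in layer.grads.items():
                key = f"{i}.{name}"
                g = g.astype(_F32)
                self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
                self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
                mhat = self.m[key] / b1t
                vhat = self.v[key] / b2t
                new = layer.params[name] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
                setattr(layer, name, new.astype(_F32))


def _as_xy(s: SegmentSet, n_classes: int) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(s.subject_labels, dtype=np.int64)
    if len(y) and (y.min() < 0 or y.max() >= n_classes):
        raise DataShapeError(
            f"labels span [{y.min()}, {y.max()}] outside [0, {n_classes})"
        )
    return s.data.astype(_F32, copy=False), y


def evaluate_loss(network: CNN1D, X: np.ndarray, y: np.ndarray, batch_size: int = 256):
    """Mean cross-entropy and accuracy in evaluation mode (frozen BN stats)."""
    losses, correct = [], 0
    for lo in range(0, len(X), batch_size):
        xb, yb = X[lo : lo + batch_size], y[lo : lo + batch_size]
        p = network.predict_proba(xb)
        losses.append(-np.log(np.maximum(p[np.arange(len(yb)), yb], 1e-12)).sum())
        correct += int((p.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(X)), correct / len(X)


def train(
    network: CNN1D,
    train_set: SegmentSet,
    val_set: SegmentSet,
    tc: TrainConfig = TrainConfig(),
) -> TrainedModel:
    """Mini-batch Adam training with best-validation-loss checkpointing.

    Deterministic for a fixed (network init seed, tc.seed, data): reruns
    produce identical histories and the same restored weights.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise DataShapeError("train and validation sets must be non-empty")
    cfg = network.config
    if train_set.n_channels != cfg.n_channels:
        raise DataShapeError(
            f"{train_set.n_channels}-channel data fed to {cfg.n_channels}-channel model"
        )
    Xtr, ytr = _as_xy(train_set, cfg.n_classes)
    Xva, yva = _as_xy(val_set, cfg.n_classes)

    rng = np.random.default_rng(tc.seed)
    opt = _Adam(network, tc.learning_rate)
    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    best_loss, best_epoch, best_state = np.inf, 0, network.state_dict()

    n = len(Xtr)
    for epoch in range(tc.max_epochs):
        order = rng.permutation(n) if tc.shuffle_each_epoch else np.arange(n)
        ep_loss, ep_correct = 0.0, 0
        for lo in range(0, n, tc.batch_size):
            idx = order[lo : lo + tc.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            logits = network.forward(xb, train=True)
            p = softmax(logits)
            ep_loss += -np.log(np.maximum(p[np.arange(len(yb)), yb], 1e-12)).sum()
            ep_correct += int((p.argmax(axis=1) == yb).sum())
            dlogits = p.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            network.backward(dlogits.astype(_F32))
            opt.step(network)
        val_loss, val_acc = evaluate_loss(network, Xva, yva)
        history["train_loss"].append(float(ep_loss) / n)
        history["train_acc"].append(ep_correct / n)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        if val_loss < best_loss:  # strict: first argmin wins on ties
            best_loss, best_epoch = val_loss, epoch
            best_state = network.state_dict()

    network.load_state_dict(best_state)
    return TrainedModel(
        config=cfg, network=network, train_config=tc, history=history, best_epoch=best_epoch
    )


def predict(model: TrainedModel, s: SegmentSet, batch_size: int = 256):
    """(labels, probabilities); argmax with lowest-index tie-breaking."""
    if s.n_channels != model.config.n_channels:
        raise DataShapeError(
            f"{s.n_channels}-channel data fed to {model.config.n_channels}-channel model"
        )
    X = s.data.astype(_F32, copy=False)
    probs = np.concatenate(
        [model.network.predict_proba(X[lo : lo + batch_size]) for lo in range(0, len(X), batch_size)]
    ) if len(X) else np.empty((0, model.config.n_classes))
    return probs.argmax(axis=1), probs


# ---------------------------------------------------------------------------
# serialization


def save_model(model: TrainedModel, path) -> None:
    """Single-archive checkpoint: weights + configs + history."""
    meta = {
        "config": model.config.__dict__,
        "train_config": model.train_config.__dict__,
        "history": model.history,
        "best_epoch": model.best_epoch,
    }
    state = model.network.state_dict()
    np.savez_compressed(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_model(path) -> TrainedModel:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    cfg = ModelConfig(**meta["config"])
    net = CNN1D(cfg, seed=0)
    net.load_state_dict(state)
    return TrainedModel(
        config=cfg,
        network=net,
        train_config=TrainConfig(**meta["train_config"]),
        history=meta["history"],
        best_epoch=meta["best_epoch"],
    )
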