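"""Five CNN-LSTM classifier architectures and their training loop.

The model zoo spans a single conv block (Conv1D + ReLU + batch normalization
+ max pooling) feeding one to three LSTM layers — unidirectional or
bidirectional — then dense layers and a softmax head:

=============  ====  ==========================  ==================
name           conv  recurrent stack             dropout placement
=============  ====  ==========================  ==================
CNN-1-LSTM     yes   LSTM                        0.20 before output
CNN-2-LSTM     yes   LSTM -> LSTM                0.50 between, 0.20 before output
CNN-2-Bi-LSTM  yes   BiLSTM -> BiLSTM            0.50 between, 0.50 before output
CNN-3-LSTM     yes   LSTM x3, two dense layers   0.10/0.30/0.10 between, 0.10 before output
3-LSTM         no    LSTM x3                     same dropouts as CNN-3-LSTM
=============  ====  ==========================  ==================

Training uses Adam (lr 0.001, beta1 0.9, beta2 0.999) with categorical
cross-entropy, early stopping on validation loss (patience 30), and
learning-rate reduction on plateau (factor 0.1, patience 10); batch size 256
for standard training and 128 for per-subject calibration fine-tuning.

Everything runs on a compact CPU tensor core written here in NumPy: each
layer implements ``forward``/``backward`` and the optimiser updates raw
arrays, which keeps runs bit-deterministic for a given seed and makes the
closed-form parameter-count cross-checks exact.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io_core import ShapeError
from .preprocess import SpecError, WindowSet

ARCHITECTURE_NAMES = ("CNN-1-LSTM", "CNN-2-LSTM", "CNN-2-Bi-LSTM",
                      "CNN-3-LSTM", "3-LSTM")


class TrainingError(RuntimeError):
    pass


class TrainingDiverged(TrainingError):
    """Loss became non-finite during optimisation."""


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer composition and hyperparameters for one model.

    ``dropouts`` is ordered: one rate after each recurrent layer for the
    leading entries, and the final entry applied before the output layer.
    Layer widths (filters, units, dense sizes) are not part of the structural
    template and are set by the profile.
    """

    name: str
    conv_blocks: int
    conv_filters: int
    conv_kernel: int
    pool_size: int
    recurrent_layers: tuple[tuple[int, bool], ...]  # (units, bidirectional)
    dropouts: tuple[float, ...]
    dense_layers: tuple[int, ...]
    n_classes: int

    def __post_init__(self) -> None:
        if self.name not in ARCHITECTURE_NAMES:
            raise SpecError(f"unknown architecture {self.name!r}")
        if self.conv_blocks not in (0, 1):
            raise SpecError("conv_blocks must be 0 or 1")
        if any(not 0 <= r < 1 for r in self.dropouts):
            raise SpecError("dropout rates must be in [0, 1)")
        if self.n_classes < 2:
            raise SpecError("need at least 2 classes")
        if len(self.dropouts) > len(self.recurrent_layers) + 1:
            raise SpecError("more dropout rates than placement slots")


#: Structural templates: (has_conv, n_recurrent, bidirectional, dropouts,
#: n_dense).  Widths come from the profile.
_TEMPLATES: dict[str, tuple[bool, int, bool, tuple[float, ...], int]] = {
    "CNN-1-LSTM": (True, 1, False, (0.20,), 1),
    "CNN-2-LSTM": (True, 2, False, (0.50, 0.20), 1),
    "CNN-2-Bi-LSTM": (True, 2, True, (0.50, 0.50), 1),
    "CNN-3-LSTM": (True, 3, False, (0.10, 0.30, 0.10, 0.10), 2),
    "3-LSTM": (False, 3, False, (0.10, 0.30, 0.10, 0.10), 1),
}

#: Layer-width profiles.  "full" widths are this package's choices
#: (the structural templates fix composition, not widths); "tiny" keeps
#: end-to-end experiments fast on one CPU.
PROFILES: dict[str, dict] = {
    "full": {"conv_filters": 64, "conv_kernel": 3, "pool_size": 2,
             "units": (128, 64, 32), "dense": (128, 64)},
    "tiny": {"conv_filters": 8, "conv_kernel": 3, "pool_size": 2,
             "units": (16, 16, 16), "dense": (16, 16)},
}


def architecture(name: str, n_classes: int,
                 profile: str = "full") -> ArchitectureSpec:
    """Instantiate a named architecture template at a width profile."""
    if name not in _TEMPLATES:
        raise SpecError(f"unknown architecture {name!r}; "
                        f"expected one of {ARCHITECTURE_NAMES}")
    if profile not in PROFILES:
        raise SpecError(f"unknown profile {profile!r}")
    has_conv, n_rec, bidir, dropouts, n_dense = _TEMPLATES[name]
    p = PROFILES[profile]
    rec = tuple((p["units"][i], bidir) for i in range(n_rec))
    dense = tuple(p["dense"][:n_dense])
    return ArchitectureSpec(
        name=name, conv_blocks=1 if has_conv else 0,
        conv_filters=p["conv_filters"] if has_conv else 0,
        conv_kernel=p["conv_kernel"] if has_conv else 0,
        pool_size=p["pool_size"] if has_conv else 0,
        recurrent_layers=rec, dropouts=dropouts, dense_layers=dense,
        n_classes=n_classes,
    )


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation settings (defaults as used throughout)."""

    lr: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    max_epochs: int = 500
    early_stop_patience: int = 30
    lr_reduce_factor: float = 0.1
    lr_reduce_patience: int = 10
    lr_plateau_min_delta: float = 1e-4
    batch_size: int = 256
    seed: int = 0
    val_fraction: float = 0.1


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class _Layer:
    """Minimal layer protocol: params/grads dicts plus forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}  # non-trainable state

    def forward(self, x: np.ndarray, training: bool,
                rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[-2] if len(shape) > 1 else shape[0], shape[-1]
    if len(shape) == 3:  # conv kernel (k, in, out)
        fan_in = shape[0] * shape[1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape)


def _orthogonal(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    a = rng.standard_normal((max(shape), max(shape)))
    q, _ = np.linalg.qr(a)
    return q[: shape[0], : shape[1]]


class _Conv1D(_Layer):
    """Temporal convolution, valid padding, stride 1, channels last."""

    def __init__(self, in_ch: int, filters: int, kernel: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.kernel = kernel
        self.params["W"] = _glorot(rng, (kernel, in_ch, filters))
        self.params["b"] = np.zeros(filters)

    def forward(self, x, training, rng):
        win = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)
        # win: (N, T_out, C, k)
        self._win = win
        self._in_shape = x.shape
        return np.einsum("ntck,kcf->ntf", win, self.params["W"]) + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = np.einsum("ntck,ntf->kcf", self._win, dout)
        self.grads["b"] = dout.sum(axis=(0, 1))
        dx = np.zeros(self._in_shape)
        t_out = dout.shape[1]
        for j in range(self.kernel):
            dx[:, j: j + t_out, :] += dout @ self.params["W"][j].T
        return dx


class _ReLU(_Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class _BatchNorm(_Layer):
    """Feature-axis batch normalization over the (batch, time) axes."""

    def __init__(self, features: int, momentum: float = 0.99,
                 eps: float = 1e-3) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(features)
        self.params["beta"] = np.zeros(features)
        self.buffers["running_mean"] = np.zeros(features)
        self.buffers["running_var"] = np.ones(features)

    def forward(self, x, training, rng):
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            m = self.momentum
            self.buffers["running_mean"] = m * self.buffers["running_mean"] + (1 - m) * mean
            self.buffers["running_var"] = m * self.buffers["running_var"] + (1 - m) * var
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._m = x.shape[0] * x.shape[1]
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dout):
        self.grads["gamma"] = (dout * self._xhat).sum(axis=(0, 1))
        self.grads["beta"] = dout.sum(axis=(0, 1))
        dxhat = dout * self.params["gamma"]
        m = self._m
        return (dxhat - dxhat.mean(axis=(0, 1))
                - self._xhat * (dxhat * self._xhat).sum(axis=(0, 1)) / m) / self._std


class _MaxPool1D(_Layer):
    def __init__(self, pool: int) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x, training, rng):
        n, t, f = x.shape
        t_c = (t // self.pool) * self.pool
        self._in_shape = x.shape
        xr = x[:, :t_c].reshape(n, t_c // self.pool, self.pool, f)
        self._argmax = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, dout):
        n, t_out, f = dout.shape
        dx = np.zeros(self._in_shape)
        dxr = dx[:, : t_out * self.pool].reshape(n, t_out, self.pool, f)
        ni, ti, fi = np.ogrid[:n, :t_out, :f]
        dxr[ni, ti, self._argmax, fi] = dout
        return dx


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class _LSTM(_Layer):
    """Single-direction LSTM (gate order i, f, g, o).

    ``go_backwards`` processes the reversed sequence; with
    ``return_sequences`` its outputs are re-reversed into input time order.
    """

    def __init__(self, in_dim: int, units: int, return_sequences: bool,
                 go_backwards: bool, rng: np.random.Generator) -> None:
        super().__init__()
        self.units = units
        self.return_sequences = return_sequences
        self.go_backwards = go_backwards
        self.params["W"] = _glorot(rng, (in_dim, 4 * units))
        self.params["U"] = np.concatenate(
            [_orthogonal(rng, (units, units)) for _ in range(4)], axis=1)
        b = np.zeros(4 * units)
        b[units: 2 * units] = 1.0  # forget-gate bias
        self.params["b"] = b

    def forward(self, x, training, rng):
        if self.go_backwards:
            x = x[:, ::-1, :]
        n, t, _ = x.shape
        u = self.units
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        h = np.zeros((n, u))
        c = np.zeros((n, u))
        self._cache = []
        hs = np.empty((n, t, u))
        for step in range(t):
            xt = x[:, step, :]
            z = xt @ W + h @ U + b
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u: 2 * u])
            g = np.tanh(z[:, 2 * u: 3 * u])
            o = _sigmoid(z[:, 3 * u:])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            self._cache.append((xt, h, c, i, f, g, o, c_new))
            h, c = h_new, c_new
            hs[:, step, :] = h
        self._x_shape = x.shape
        if self.return_sequences:
            return hs[:, ::-1, :] if self.go_backwards else hs
        return h

    def backward(self, dout):
        n, t, in_dim = self._x_shape
        u = self.units
        W, U = self.params["W"], self.params["U"]
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros_like(self.params["b"])
        dx = np.zeros((n, t, in_dim))
        if self.return_sequences:
            dhs = dout[:, ::-1, :] if self.go_backwards else dout
        dh_next = np.zeros((n, u))
        dc_next = np.zeros((n, u))
        for step in range(t - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, c_new = self._cache[step]
            dh = dh_next.copy()
            if self.return_sequences:
                dh += dhs[:, step, :]
            elif step == t - 1:
                dh += dout
            tanh_c = np.tanh(c_new)
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c ** 2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - g ** 2), do * o * (1 - o),
            ], axis=1)
            dW += xt.T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, step, :] = dz @ W.T
            dh_next = dz @ U.T
            dc_next = dc * f
        self.grads["W"], self.grads["U"], self.grads["b"] = dW, dU, db
        if self.go_backwards:
            dx = dx[:, ::-1, :]
        return dx


class _Bidirectional(_Layer):
    """Forward and backward LSTMs with concatenated outputs."""

    def __init__(self, in_dim: int, units: int, return_sequences: bool,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.fw = _LSTM(in_dim, units, return_sequences, False, rng)
        self.bw = _LSTM(in_dim, units, return_sequences, True, rng)
        self.units = units

    @property
    def children(self) -> list[_Layer]:
        return [self.fw, self.bw]

    def forward(self, x, training, rng):
        return np.concatenate([self.fw.forward(x, training, rng),
                               self.bw.forward(x, training, rng)], axis=-1)

    def backward(self, dout):
        u = self.units
        if dout.ndim == 3:
            d_fw, d_bw = dout[..., :u], dout[..., u:]
        else:
            d_fw, d_bw = dout[:, :u], dout[:, u:]
        return self.fw.backward(d_fw) + self.bw.backward(d_bw)


class _Dense(_Layer):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = _glorot(rng, (in_dim, out_dim))
        self.params["b"] = np.zeros(out_dim)

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class _Dropout(_Layer):
    def __init__(self, rate: float) -> None:
        super().__init__()
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------

class ModelHandle:
    """A built (possibly trained) classifier."""

    def __init__(self, spec: ArchitectureSpec, input_shape: tuple[int, int],
                 layers: list[_Layer]) -> None:
        self.spec = spec
        self.input_shape = input_shape
        self.layers = layers
        self.train_seed: int | None = None

    def _flat_layers(self) -> list[_Layer]:
        out = []
        for layer in self.layers:
            out.extend(layer.children if isinstance(layer, _Bidirectional)
                       else [layer])
        return out

    def forward(self, x: np.ndarray, training: bool,
                rng: np.random.Generator) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def predict_proba(self, x: np.ndarray, batch: int = 2048) -> np.ndarray:
        rng = np.random.default_rng(0)  # unused in eval mode
        outs = []
        for i in range(0, len(x), batch):
            logits = self.forward(x[i: i + batch], training=False, rng=rng)
            outs.append(_softmax(logits))
        return np.concatenate(outs) if outs else np.empty((0, self.spec.n_classes))

    def clone(self) -> "ModelHandle":
        return copy.deepcopy(self)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_model(spec: ArchitectureSpec,
                input_shape: tuple[int, int],
                init_seed: int = 0) -> ModelHandle:
    """Assemble the layer stack for ``spec`` on (window length, channels)."""
    ws, n_ch = input_shape
    if ws < 1 or n_ch < 1:
        raise ShapeError(f"invalid input shape {input_shape}")
    rng = np.random.default_rng(init_seed)
    layers: list[_Layer] = []
    t, feat = ws, n_ch
    if spec.conv_blocks == 1:
        layers += [_Conv1D(feat, spec.conv_filters, spec.conv_kernel, rng),
                   _ReLU(), _BatchNorm(spec.conv_filters),
                   _MaxPool1D(spec.pool_size)]
        t = (t - spec.conv_kernel + 1) // spec.pool_size
        feat = spec.conv_filters
        if t < 1:
            raise ShapeError(
                f"window length {ws} collapses to {t} steps after conv/pool"
            )
    between, pre_output = spec.dropouts[:-1], spec.dropouts[-1]
    n_rec = len(spec.recurrent_layers)
    for i, (units, bidir) in enumerate(spec.recurrent_layers):
        last = i == n_rec - 1
        if bidir:
            layers.append(_Bidirectional(feat, units, not last, rng))
            feat = 2 * units
        else:
            layers.append(_LSTM(feat, units, not last, False, rng))
            feat = units
        if i < len(between) and between[i] > 0:
            layers.append(_Dropout(between[i]))
    for units in spec.dense_layers:
        layers += [_Dense(feat, units, rng), _ReLU()]
        feat = units
    layers.append(_Dropout(pre_output))
    layers.append(_Dense(feat, spec.n_classes, rng))
    return ModelHandle(spec, input_shape, layers)


def count_parameters(model: ModelHandle) -> tuple[int, int]:
    """(total, trainable) parameter counts.

    Batch-normalization scale/shift are trainable; its running moments are
    the non-trainable remainder.
    """
    trainable = sum(p.size for layer in model._flat_layers()
                    for p in layer.params.values())
    non_trainable = sum(b.size for layer in model._flat_layers()
                        for b in layer.buffers.values())
    return trainable + non_trainable, trainable


def model_size_mb(total_params: int, bytes_per_param: int = 4) -> float:
    """Model size in MB (2**20 bytes), rounded to 2 decimals."""
    if total_params < 0:
        raise ValueError("parameter count cannot be negative")
    return round(total_params * bytes_per_param / 2 ** 20, 2)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class History:
    loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    stop_epoch: int = 0
    best_epoch: int = 0
    batch_size: int = 0


class _Adam:
    def __init__(self, cfg: TrainingConfig) -> None:
        self.beta1, self.beta2 = cfg.beta1, cfg.beta2
        self.eps = 1e-7
        self.lr = cfg.lr
        self.state: dict[tuple[int, str], tuple[np.ndarray, np.ndarray]] = {}
        self.t = 0

    def step(self, layers: list[_Layer]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for li, layer in enumerate(layers):
            for name, p in layer.params.items():
                g = layer.grads[name]
                key = (li, name)
                m, v = self.state.get(key, (np.zeros_like(p), np.zeros_like(p)))
                m = b1 * m + (1 - b1) * g
                v = b2 * v + (1 - b2) * g * g
                self.state[key] = (m, v)
                m_hat = m / (1 - b1 ** self.t)
                v_hat = v / (1 - b2 ** self.t)
                p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def _eval_loss_acc(model: ModelHandle, x: np.ndarray, y: np.ndarray,
                   batch: int = 2048) -> tuple[float, float]:
    probs = model.predict_proba(x, batch=batch)
    eps = 1e-12
    loss = float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))
    acc = float(np.mean(probs.argmax(axis=1) == y))
    return loss, acc


def _stratified_split(labels: np.ndarray, frac: float,
                      seed: int) -> tuple[np.ndarray, np.ndarray]:
    from sklearn.model_selection import train_test_split

    idx = np.arange(len(labels))
    fit_idx, val_idx = train_test_split(idx, test_size=frac, stratify=labels,
                                        random_state=seed)
    return np.sort(fit_idx), np.sort(val_idx)


def train_model(model: ModelHandle, train: WindowSet,
                cfg: TrainingConfig = TrainingConfig()
                ) -> tuple[ModelHandle, History]:
    """Optimise ``model`` in place and return it with its History.

    A stratified ``val_fraction`` of the training windows is carved out for
    early stopping and the learning-rate schedule; the weights of the best
    validation epoch are restored at the end.  All randomness (validation
    carve-out, shuffling, dropout) derives from ``cfg.seed``.
    """
    if not train.normalized:
        raise TrainingError("training windows must be normalized first")
    classes = np.unique(train.labels)
    if len(classes) < 2:
        raise TrainingError("training set contains a single class")
    if classes.max() >= model.spec.n_classes:
        raise TrainingError("label index exceeds model n_classes")
    fit_idx, val_idx = _stratified_split(train.labels, cfg.val_fraction, cfg.seed)
    x_fit, y_fit = train.windows[fit_idx], train.labels[fit_idx]
    x_val, y_val = train.windows[val_idx], train.labels[val_idx]
    y_fit_oh = _one_hot(y_fit, model.spec.n_classes)

    rng = np.random.default_rng(cfg.seed)
    adam = _Adam(cfg)
    layers = model._flat_layers()
    history = History(batch_size=cfg.batch_size)
    best_val = np.inf
    best_weights: list[dict[str, np.ndarray]] | None = None
    best_buffers: list[dict[str, np.ndarray]] | None = None
    wait_stop = wait_lr = 0
    lr_best = np.inf

    for epoch in range(1, cfg.max_epochs + 1):
        perm = rng.permutation(len(x_fit))
        epoch_loss = 0.0
        for start in range(0, len(perm), cfg.batch_size):
            sel = perm[start: start + cfg.batch_size]
            xb, yb = x_fit[sel], y_fit_oh[sel]
            logits = model.forward(xb, training=True, rng=rng)
            probs = _softmax(logits)
            loss = float(-np.mean(np.sum(yb * np.log(probs + 1e-12), axis=1)))
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}; aborting"
                )
            epoch_loss += loss * len(sel)
            model.backward((probs - yb) / len(sel))
            adam.step(layers)
        val_loss, val_acc = _eval_loss_acc(model, x_val, y_val)
        history.loss.append(epoch_loss / len(perm))
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        history.lr.append(adam.lr)

        if val_loss < best_val:
            best_val = val_loss
            history.best_epoch = epoch
            best_weights = [{k: v.copy() for k, v in l.params.items()}
                            for l in layers]
            best_buffers = [{k: v.copy() for k, v in l.buffers.items()}
                            for l in layers]
            wait_stop = 0
        else:
            wait_stop += 1
        if val_loss < lr_best - cfg.lr_plateau_min_delta:
            lr_best = val_loss
            wait_lr = 0
        else:
            wait_lr += 1
            if wait_lr > cfg.lr_reduce_patience:
                adam.lr *= cfg.lr_reduce_factor
                wait_lr = 0
        history.stop_epoch = epoch
        if wait_stop >= cfg.early_stop_patience:
            break

    if best_weights is not None:
        for layer, w, b in zip(layers, best_weights, best_buffers):
            for k, v in w.items():
                layer.params[k] = v
            for k, v in b.items():
                layer.buffers[k] = v
    model.train_seed = cfg.seed
    return model, history


def fine_tune(model: ModelHandle, calibration: WindowSet,
              cfg: TrainingConfig | None = None,
              *, skip_if_empty: bool = False
              ) -> tuple[ModelHandle, History]:
    """Continue optimisation on a held-out subject's calibration windows.

    The learning rate is reset to 0.001 and the batch size to 128; the same
    early-stopping criteria apply.  The pretrained model is left untouched —
    a fine-tuned copy is returned.
    """
    if calibration is None or len(calibration) == 0:
        if skip_if_empty:
            return model, History()
        raise TrainingError("empty calibration set")
    if len(np.unique(calibration.subject_ids)) != 1:
        raise TrainingError("calibration windows must come from one subject")
    if cfg is None:
        cfg = TrainingConfig(batch_size=128)
    cfg = replace(cfg, lr=0.001, batch_size=128)
    tuned = model.clone()
    return train_model(tuned, calibration, cfg)


def predict(model: ModelHandle, ws: WindowSet) -> tuple[np.ndarray, np.ndarray]:
    """Class indices and the softmax probability matrix for ``ws``."""
    if ws.n_channels != model.input_shape[1]:
        raise ShapeError(f"window set has {ws.n_channels} channels; model "
                         f"expects {model.input_shape[1]}")
    if ws.windows.shape[1] != model.input_shape[0]:
        raise ShapeError(f"window length {ws.windows.shape[1]} differs from "
                         f"model input {model.input_shape[0]}")
    probs = model.predict_proba(ws.windows)
    return probs.argmax(axis=1), probs
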