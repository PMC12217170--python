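"""Compact patch-classification CNN, implemented directly on numpy.

The classifier maps a 64x64 intensity window to the probability that
its center pixel is a vessel pixel. The architecture is three
convolutional blocks of two sub-blocks each (conv -> batch norm ->
ReLU), every block closed by 2x2 max pooling and dropout (rate 0.25),
with filter counts doubling per block (F, 2F, 4F); the flattened
features pass through three fully-connected blocks (dense -> batch norm
-> ReLU -> dropout) into a single sigmoid output. That is ten weighted
layers: six convolutions, three hidden dense layers and the output.

Everything — He initialisation, epoch shuffling, dropout masks — draws
from one seeded generator, so training is bit-reproducible. Training
uses binary cross-entropy with Adam. Inference runs the network in
evaluation mode (batch-norm running statistics, no dropout), which
makes predictions independent of how windows are batched.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "VesselPatchCNN",
    "build_classifier",
    "train_classifier",
    "predict_vessel_prob",
    "save_model",
    "load_model",
]

_F32 = np.float32


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters.

    Defaults give the reference architecture: 64-px input, base filter
    count 32 doubling per block, 3x3 kernels, three blocks of two conv
    sub-blocks, 2x2 pooling, dropout 0.25, dense widths (256, 128, 64)
    and one sigmoid output unit.
    """

    input_size: int = 64
    base_filters: int = 32
    conv_kernel: int = 3
    blocks: int = 3
    subblocks_per_block: int = 2
    pool: int = 2
    dropout_rate: float = 0.25
    fc_sizes: tuple[int, ...] = (256, 128, 64)
    output_units: int = 1

    def __post_init__(self) -> None:
        if self.input_size % self.pool ** self.blocks != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by "
                f"pool^blocks = {self.pool ** self.blocks}"
            )
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters (fixed-epoch schedule, BCE loss, Adam)."""

    epochs: int = 80
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


class _Param:
    __slots__ = ("val", "grad", "m", "v")

    def __init__(self, val: np.ndarray):
        self.val = val
        self.grad = np.zeros_like(val)
        self.m = np.zeros_like(val)
        self.v = np.zeros_like(val)


class _Layer:
    params: list[_Param] = []

    def forward(self, x, training, rng):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class _Conv2D(_Layer):
    """3x3 same-padding convolution in channels-last layout.

    Computed as one contiguous GEMM per kernel offset followed by a
    shifted accumulation — algebraically identical to im2col but
    without its large strided transpose copies, which dominate runtime
    on a single CPU core.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 is_input: bool = False):
        self.cin, self.cout, self.k = cin, cout, k
        self.is_input = is_input  # input layer: no gradient w.r.t. x needed
        fan_in = cin * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k * k, cin, cout))
        self.W = _Param(w.astype(_F32))
        self.b = _Param(np.zeros(cout, dtype=_F32))
        self.params = [self.W, self.b]

    def forward(self, x, training, rng):
        n, h, w, c = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._cache = (xp, (n, h, w, c))
        xf = xp.reshape(-1, c)
        hp, wp = h + 2 * p, w + 2 * p
        out = np.empty((n, h, w, self.cout), dtype=_F32)
        out[:] = self.b.val
        for idx in range(self.k * self.k):
            i, j = divmod(idx, self.k)
            # out[n,y,x] += xp[n, y+i, x+j] @ W[i,j]
            z = (xf @ self.W.val[idx]).reshape(n, hp, wp, self.cout)
            out += z[:, i:i + h, j:j + w]
        return out

    def backward(self, dy):
        xp, (n, h, w, c) = self._cache
        p = self.k // 2
        hp, wp = h + 2 * p, w + 2 * p
        xf = xp.reshape(-1, c)
        dyf = dy.reshape(-1, self.cout)
        self.b.grad = dyf.sum(axis=0)
        self.W.grad = np.empty_like(self.W.val)
        dxp = None if self.is_input else np.zeros_like(xp)
        dyp = np.zeros((n, hp, wp, self.cout), dtype=_F32)
        for idx in range(self.k * self.k):
            i, j = divmod(idx, self.k)
            dyp[:] = 0.0
            dyp[:, i:i + h, j:j + w] = dy
            dypf = dyp.reshape(-1, self.cout)
            self.W.grad[idx] = xf.T @ dypf
            if dxp is not None:
                dxp += (dypf @ self.W.val[idx].T).reshape(n, hp, wp, c)
        self._cache = None
        if dxp is None:
            return dy  # unused upstream
        return dxp[:, p:p + h, p:p + w, :]


class _BatchNorm(_Layer):
    """Batch normalisation over the sample (and spatial) axes.

    Operates on a 2-D (M, C) view; convolutional inputs are reshaped so
    statistics are per channel. Evaluation mode uses exponentially
    averaged running statistics (momentum 0.9), which keeps inference
    deterministic and batch-invariant.
    """

    momentum = 0.9
    eps = 1e-5

    def __init__(self, channels: int, spatial: bool):
        self.channels = channels
        self.spatial = spatial
        self.gamma = _Param(np.ones(channels, dtype=_F32))
        self.beta = _Param(np.zeros(channels, dtype=_F32))
        self.params = [self.gamma, self.beta]
        self.running_mean = np.zeros(channels, dtype=_F32)
        self.running_var = np.ones(channels, dtype=_F32)

    def _to2d(self, x):
        # channels are the trailing axis in both conv and dense sections,
        # so the per-channel view is a free reshape
        return x.reshape(-1, self.channels), x.shape

    def _from2d(self, x2, shape):
        return x2.reshape(shape)

    def forward(self, x, training, rng):
        x2, shape = self._to2d(x)
        if training:
            mean = x2.mean(axis=0)
            var = np.einsum("ij,ij->j", x2, x2, optimize=True) / x2.shape[0] - mean * mean
            np.maximum(var, 0.0, out=var)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x2 - mean) * ivstd
        out = self.gamma.val * xhat + self.beta.val
        if training:
            self._cache = (xhat, ivstd, shape)
        return self._from2d(out.astype(_F32), shape)

    def backward(self, dy):
        xhat, ivstd, shape = self._cache
        dy2, _ = self._to2d(dy)
        m = dy2.shape[0]
        self.gamma.grad = (dy2 * xhat).sum(axis=0)
        self.beta.grad = dy2.sum(axis=0)
        dxhat = dy2 * self.gamma.val
        dx2 = (ivstd / m) * (
            m * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )
        self._cache = None
        return self._from2d(dx2.astype(_F32), shape)


class _ReLU(_Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class _MaxPool2(_Layer):
    """2x2 max pooling, stride 2, channels-last; gradient follows the argmax."""

    def forward(self, x, training, rng):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        xr = np.ascontiguousarray(xr).reshape(n, h // 2, w // 2, 4, c)
        self._idx = xr.argmax(axis=3)
        self._shape = (n, h, w, c)
        return np.take_along_axis(xr, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dy):
        n, h, w, c = self._shape
        dxr = np.zeros((n, h // 2, w // 2, 4, c), dtype=_F32)
        np.put_along_axis(dxr, self._idx[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        dx = dxr.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return np.ascontiguousarray(dx).reshape(n, h, w, c)


class _Dropout(_Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return (x * self._mask).astype(_F32)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return (dy * self._mask).astype(_F32)


class _Flatten(_Layer):
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class _Dense(_Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        w = rng.normal(0.0, np.sqrt(2.0 / nin), size=(nin, nout))
        self.W = _Param(w.astype(_F32))
        self.b = _Param(np.zeros(nout, dtype=_F32))
        self.params = [self.W, self.b]

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.W.val + self.b.val

    def backward(self, dy):
        self.W.grad = self._x.T @ dy
        self.b.grad = dy.sum(axis=0)
        self._x = None
        return dy @ self.W.val.T


class VesselPatchCNN:
    """The assembled classifier.

    ``forward`` returns logits; :meth:`predict_proba` applies the
    sigmoid and accepts plain ``(N, s, s)`` windows, which is the
    protocol the segmentation module expects of any pixel classifier.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.rng = np.random.default_rng(seed)
        self.history: list[dict] = []
        self.train_provenance: dict | None = None
        layers: list[_Layer] = []
        cin = 1
        for block in range(config.blocks):
            cout = config.base_filters * 2 ** block
            for sub in range(config.subblocks_per_block):
                layers += [
                    _Conv2D(cin, cout, config.conv_kernel, self.rng,
                            is_input=(block == 0 and sub == 0)),
                    _BatchNorm(cout, spatial=True),
                    _ReLU(),
                ]
                cin = cout
            layers += [_MaxPool2(), _Dropout(config.dropout_rate)]
        layers.append(_Flatten())
        side = config.input_size // config.pool ** config.blocks
        nin = cin * side * side
        for width in config.fc_sizes:
            layers += [
                _Dense(nin, width, self.rng),
                _BatchNorm(width, spatial=False),
                _ReLU(),
                _Dropout(config.dropout_rate),
            ]
            nin = width
        layers.append(_Dense(nin, config.output_units, self.rng))
        self.layers = layers

    # -- introspection -------------------------------------------------

    @property
    def weighted_layers(self) -> list[_Layer]:
        """Convolutional and dense layers, in order."""
        return [l for l in self.layers if isinstance(l, (_Conv2D, _Dense))]

    @property
    def conv_filter_counts(self) -> list[int]:
        return [l.cout for l in self.layers if isinstance(l, _Conv2D)]

    @property
    def dropout_rates(self) -> list[float]:
        return [l.rate for l in self.layers if isinstance(l, _Dropout)]

    def count_params(self) -> int:
        """Number of trainable scalars (weights, biases, BN gains/offsets)."""
        return sum(p.val.size for l in self.layers for p in l.params)

    # -- computation ---------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = _as_nhwc(np.asarray(x, dtype=_F32))
        for layer in self.layers:
            out = layer.forward(out, training, self.rng)
        return out[:, 0]

    def backward(self, dlogit: np.ndarray) -> None:
        grad = dlogit[:, None].astype(_F32)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def recalibrate_bn(self, windows: np.ndarray, batch_size: int = 256) -> None:
        """Re-estimate batch-norm statistics with dropout disabled.

        Dropout inflates activation variance during training, so the
        exponentially averaged statistics collected then over-normalise
        at inference (when dropout is off) and deflate every
        probability. This pass recomputes exact per-channel moments over
        the given windows with dropout off — normalising each batch by
        its own statistics while accumulating — and installs the
        aggregate as the running statistics.
        """
        windows = _as_nhwc(np.asarray(windows, dtype=_F32))
        bns = [l for l in self.layers if isinstance(l, _BatchNorm)]
        acc = {id(bn): [0.0, 0.0, 0] for bn in bns}
        for start in range(0, len(windows), batch_size):
            out = windows[start:start + batch_size]
            for layer in self.layers:
                if isinstance(layer, _BatchNorm):
                    x2, shape = layer._to2d(out)
                    a = acc[id(layer)]
                    a[0] += x2.sum(axis=0, dtype=np.float64)
                    a[1] += np.einsum("ij,ij->j", x2, x2, dtype=np.float64)
                    a[2] += x2.shape[0]
                    mean = x2.mean(axis=0)
                    var = np.maximum(
                        np.einsum("ij,ij->j", x2, x2) / x2.shape[0] - mean * mean, 0.0
                    )
                    xhat = (x2 - mean) / np.sqrt(var + layer.eps)
                    out = layer._from2d(
                        (layer.gamma.val * xhat + layer.beta.val).astype(_F32), shape
                    )
                else:
                    out = layer.forward(out, False, self.rng)
        for bn in bns:
            s, ss, m = acc[id(bn)]
            mean = s / m
            bn.running_mean = mean.astype(_F32)
            bn.running_var = np.maximum(ss / m - mean * mean, 0.0).astype(_F32)

    def predict_proba(self, windows: np.ndarray, batch_size: int = 256) -> np.ndarray:
        windows = _as_nhwc(np.asarray(windows, dtype=_F32))
        s = self.config.input_size
        if windows.shape[1:] != (s, s, 1):
            raise ValueError(
                f"expected windows of shape (N, {s}, {s}), got {windows.shape}"
            )
        out = np.empty(len(windows), dtype=np.float64)
        for start in range(0, len(windows), batch_size):
            logits = self.forward(windows[start:start + batch_size], training=False)
            out[start:start + len(logits)] = _sigmoid(logits)
        return out

    def parameters(self) -> list[_Param]:
        return [p for l in self.layers for p in l.params]


def _as_nhwc(x: np.ndarray) -> np.ndarray:
    """Accept (N, s, s), (N, 1, s, s) or (N, s, s, 1); return (N, s, s, 1)."""
    if x.ndim == 3:
        return x[:, :, :, None]
    if x.ndim == 4 and x.shape[1] == 1 and x.shape[3] != 1:
        return x.transpose(0, 2, 3, 1)
    return x


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z.astype(np.float64)))


class _Adam:
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    def __init__(self, params: list[_Param], lr: float):
        self.params = params
        self.lr = lr
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p in self.params:
            g = p.grad.astype(_F32)
            p.m = self.beta1 * p.m + (1 - self.beta1) * g
            p.v = self.beta2 * p.v + (1 - self.beta2) * g * g
            p.val -= self.lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)


def build_classifier(config: ModelConfig = ModelConfig(), seed: int = 0) -> VesselPatchCNN:
    """Untrained classifier with seeded He-style initialisation."""
    return VesselPatchCNN(config, seed=seed)


def train_classifier(
    model: VesselPatchCNN,
    windows: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig = TrainConfig(),
) -> VesselPatchCNN:
    """Train in place with BCE + Adam for a fixed number of epochs.

    ``windows`` is ``(N, s, s)`` or ``(N, 1, s, s)``; ``labels`` is 0/1.
    Shuffling and dropout draw from a generator reseeded with
    ``config.seed``, so two calls with identical inputs coincide.
    Appends one ``{'epoch', 'loss', 'accuracy'}`` entry per epoch to
    ``model.history`` and records the config in ``model.train_provenance``.
    """
    windows = _as_nhwc(np.asarray(windows, dtype=_F32))
    labels = np.asarray(labels, dtype=np.float64).ravel()
    if len(windows) == 0:
        raise ValueError("empty training set")
    if len(windows) != len(labels):
        raise ValueError("windows and labels length mismatch")
    model.rng = np.random.default_rng(config.seed)
    opt = _Adam(model.parameters(), config.learning_rate)
    n = len(windows)
    for epoch in range(config.epochs):
        perm = model.rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            xb, yb = windows[idx], labels[idx]
            logits = model.forward(xb, training=True)
            p = np.clip(_sigmoid(logits), 1e-7, 1.0 - 1e-7)
            losses.append(-np.mean(yb * np.log(p) + (1 - yb) * np.log(1 - p)))
            correct += int(np.sum((p >= 0.5) == (yb >= 0.5)))
            model.backward((p - yb) / len(yb))
            opt.step()
        model.history.append(
            {"epoch": epoch, "loss": float(np.mean(losses)), "accuracy": correct / n}
        )
    model.recalibrate_bn(windows, config.batch_size)
    model.train_provenance = asdict(config)
    return model


def predict_vessel_prob(
    model: VesselPatchCNN, windows: np.ndarray, batch_size: int = 256
) -> np.ndarray:
    """Vessel probability in [0, 1] for each window (evaluation mode)."""
    return model.predict_proba(windows, batch_size=batch_size)


# -- serialization -----------------------------------------------------


def save_model(model: VesselPatchCNN, path) -> None:
    """Serialise weights, batch-norm statistics and configs to ``.npz``."""
    arrays = {}
    for i, layer in enumerate(model.layers):
        for j, p in enumerate(layer.params):
            arrays[f"p_{i}_{j}"] = p.val
        if isinstance(layer, _BatchNorm):
            arrays[f"rm_{i}"] = layer.running_mean
            arrays[f"rv_{i}"] = layer.running_var
    meta = {
        "model_config": asdict(model.config),
        "train_provenance": model.train_provenance,
        "history": model.history,
    }
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path) -> VesselPatchCNN:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        cfg = meta["model_config"]
        cfg["fc_sizes"] = tuple(cfg["fc_sizes"])
        model = VesselPatchCNN(ModelConfig(**cfg))
        for i, layer in enumerate(model.layers):
            for j, p in enumerate(layer.params):
                p.val = data[f"p_{i}_{j}"]
            if isinstance(layer, _BatchNorm):
                layer.running_mean = data[f"rm_{i}"]
                layer.running_var = data[f"rv_{i}"]
    model.train_provenance = meta["train_provenance"]
    model.history = meta["history"]
    return model
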