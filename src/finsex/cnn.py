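"""Whole-body sex classifier: a small residual convolutional network.

Architecture: a 3x3 convolutional stem, followed by residual stages of
increasing width (identity shortcuts where shapes match, 1x1 projections
where they widen or downsample), global mean pooling, and a 2-unit softmax
head giving (P(female), P(male)).  The default geometry takes 255x255x3
images through 96 stem filters widening to 384; a reduced geometry
(64x64 inputs, widths 16/32/64) trains in minutes on a single CPU and is
used throughout the test suite.

The network is implemented directly in NumPy: convolution as an im2col
matrix product (so the heavy lifting is BLAS), batch normalization with
running statistics, ReLU activations, cross-entropy loss, and Adam updates.
Seeded initialization and data ordering make training runs reproducible on
one device.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize

from finsex.imaging import FishSample

CLASSES = ("F", "M")  # class index 0 = female, 1 = male


class CnnConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CnnConfig:
    """Network geometry and training hyperparameters.

    ``stages`` is a list of (filters, blocks, downsample) triples; a
    downsampling stage enters with stride 2.  Widths must be nondecreasing
    and top out at ``max_filters``.
    """

    input_size: tuple[int, int] = (255, 255)
    channels: int = 3
    stem_filters: int = 96
    max_filters: int = 384
    kernel_size: int = 3
    stages: tuple[tuple[int, int, bool], ...] = ((96, 2, False), (192, 2, True), (384, 2, True))
    normalization: str = "batch"
    seed: int = 0
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        h, w = self.input_size
        if h < 32 or w < 32:
            raise CnnConfigError("input_size must be at least 32x32")
        if self.kernel_size % 2 != 1:
            raise CnnConfigError("kernel_size must be odd")
        if self.stem_filters > self.max_filters:
            raise CnnConfigError("stem_filters must be <= max_filters")
        if not self.stages:
            raise CnnConfigError("at least one stage required")
        widths = [f for f, _, _ in self.stages]
        if any(b < 1 for _, b, _ in self.stages) or any(f < 1 for f in widths):
            raise CnnConfigError("stage filters and blocks must be >= 1")
        if widths != sorted(widths) or max(widths) != self.max_filters:
            raise CnnConfigError(
                "inconsistent stage widths: must be nondecreasing and reach max_filters"
            )
        if self.normalization not in ("batch", "none"):
            raise CnnConfigError("normalization must be 'batch' or 'none'")

    def to_json(self) -> str:
        doc = {
            "input_size": list(self.input_size),
            "channels": self.channels,
            "stem_filters": self.stem_filters,
            "max_filters": self.max_filters,
            "kernel_size": self.kernel_size,
            "stages": [list(s) for s in self.stages],
            "normalization": self.normalization,
            "seed": self.seed,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "learning_rate": self.learning_rate,
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "CnnConfig":
        doc = json.loads(text)
        return cls(
            input_size=tuple(doc["input_size"]),
            channels=doc["channels"],
            stem_filters=doc["stem_filters"],
            max_filters=doc["max_filters"],
            kernel_size=doc["kernel_size"],
            stages=tuple(tuple(s) for s in doc["stages"]),
            normalization=doc["normalization"],
            seed=doc["seed"],
            epochs=doc["epochs"],
            batch_size=doc["batch_size"],
            learning_rate=doc["learning_rate"],
        )


def reduced_config(**overrides) -> CnnConfig:
    """Desk-scale geometry: 64x64 inputs, widths 16/32/64, one block each.

    The first stage downsamples immediately, so the widest maps are 8x8 and
    an epoch over a few hundred images takes seconds on one CPU.
    """
    base = dict(
        input_size=(64, 64),
        stem_filters=16,
        max_filters=64,
        stages=((16, 1, True), (32, 1, True), (64, 1, True)),
        epochs=20,
        batch_size=32,
        learning_rate=2e-3,
    )
    base.update(overrides)
    return CnnConfig(**base)


# -- layers -----------------------------------------------------------------


class Conv2d:
    """2-D convolution (same padding) as an im2col matrix product."""

    def __init__(self, cin: int, cout: int, k: int, stride: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (cin * k * k))  # He initialization
        self.W = rng.normal(0.0, scale, size=(cout, cin, k, k)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.k, self.stride, self.pad = k, stride, k // 2
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, C, H, Wd = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        Ho = (H + 2 * p - k) // s + 1
        Wo = (Wd + 2 * p - k) // s + 1
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            N * Ho * Wo, C * k * k
        )
        out = col @ self.W.reshape(self.W.shape[0], -1).T + self.b
        if train:
            self._cache = (col, x.shape, xp.shape, Ho, Wo)
        return out.reshape(N, Ho, Wo, -1).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        col, xshape, xpshape, Ho, Wo = self._cache
        N, C, H, Wd = xshape
        k, s, p = self.k, self.stride, self.pad
        cout = self.W.shape[0]
        dy_mat = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, cout)
        self.dW[...] = (dy_mat.T @ col).reshape(self.W.shape)
        self.db[...] = dy_mat.sum(axis=0)
        dcol = (dy_mat @ self.W.reshape(cout, -1)).reshape(N, Ho, Wo, C, k, k)
        dxp = np.zeros(xpshape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += dcol[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + H, p : p + Wd]


class BatchNorm2d:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)

    @property
    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        m = shape[0] * shape[2] * shape[3]
        self.dgamma[...] = (dy * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma[None, :, None, None]
        mean_dxhat = dxhat.mean(axis=(0, 2, 3))
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=(0, 2, 3))
        return inv[None, :, None, None] * (
            dxhat
            - mean_dxhat[None, :, None, None]
            - xhat * mean_dxhat_xhat[None, :, None, None]
        )


class Identity:
    params: list = []

    def forward(self, x, train):
        return x

    def backward(self, dy):
        return dy


class ReLU:
    params: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        mask = x > 0
        if train:
            self._mask = mask
        return x * mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


def _norm_layer(c: int, normalization: str):
    return BatchNorm2d(c) if normalization == "batch" else Identity()


class ResidualBlock:
    """conv-norm-relu-conv-norm with the block input re-added, then ReLU.

    The shortcut is the identity when shapes match; a strided 1x1
    projection (plus norm) otherwise.  With all convolution weights zero
    and no normalization, the block is the identity map on nonnegative
    inputs.
    """

    def __init__(self, cin: int, cout: int, stride: int, k: int, normalization: str,
                 rng: np.random.Generator):
        self.conv1 = Conv2d(cin, cout, k, stride, rng)
        self.norm1 = _norm_layer(cout, normalization)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, k, 1, rng)
        self.norm2 = _norm_layer(cout, normalization)
        self.relu_out = ReLU()
        if cin != cout or stride != 1:
            self.proj: Optional[Conv2d] = Conv2d(cin, cout, 1, stride, rng)
            self.proj_norm = _norm_layer(cout, normalization)
        else:
            self.proj = None
            self.proj_norm = Identity()

    @property
    def params(self):
        out = list(self.conv1.params) + list(self.norm1.params)
        out += list(self.conv2.params) + list(self.norm2.params)
        if self.proj is not None:
            out += list(self.proj.params) + list(self.proj_norm.params)
        return out

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = self.relu1.forward(self.norm1.forward(self.conv1.forward(x, train), train), train)
        h = self.norm2.forward(self.conv2.forward(h, train), train)
        sc = x if self.proj is None else self.proj_norm.forward(self.proj.forward(x, train), train)
        return self.relu_out.forward(h + sc, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dsum = self.relu_out.backward(dy)
        d = self.norm2.backward(dsum)
        d = self.conv2.backward(d)
        d = self.relu1.backward(d)
        d = self.norm1.backward(d)
        dmain = self.conv1.backward(d)
        if self.proj is None:
            dsc = dsum
        else:
            dsc = self.proj.backward(self.proj_norm.backward(dsum))
        return dmain + dsc


class GlobalAvgPool:
    params: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape).copy() / (H * W)


class Dense:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / cin)
        self.W = rng.normal(0.0, scale, size=(cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# -- model ------------------------------------------------------------------


class CnnModel:
    """The assembled network plus its training log."""

    def __init__(self, config: CnnConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k, norm = config.kernel_size, config.normalization
        self.stem = [
            Conv2d(config.channels, config.stem_filters, k, 1, rng),
            _norm_layer(config.stem_filters, norm),
            ReLU(),
        ]
        self.blocks: list[ResidualBlock] = []
        cin = config.stem_filters
        for filters, blocks, downsample in config.stages:
            for bi in range(blocks):
                stride = 2 if (downsample and bi == 0) else 1
                self.blocks.append(ResidualBlock(cin, filters, stride, k, norm, rng))
                cin = filters
        self.pool = GlobalAvgPool()
        self.head = Dense(cin, 2, rng)
        self.training_log: list[dict] = []

    def _layers(self):
        return [*self.stem, *self.blocks, self.pool, self.head]

    @property
    def params(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params)
        return out

    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.params))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a float32 NCHW batch."""
        for layer in self._layers():
            x = layer.forward(x, train)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self._layers()):
            d = layer.backward(d)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """(P(F), P(M)) rows for a preprocessed NCHW batch."""
        return softmax(self.forward(x, train=False))

    # -- persistence --------------------------------------------------------

    def _state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"p{i:03d}": p for i, (p, _) in enumerate(self.params)}
        bn = [l for l in self._layers_flat() if isinstance(l, BatchNorm2d)]
        for i, layer in enumerate(bn):
            state[f"bn{i:03d}_mean"] = layer.running_mean
            state[f"bn{i:03d}_var"] = layer.running_var
        return state

    def _layers_flat(self):
        for layer in self._layers():
            if isinstance(layer, ResidualBlock):
                yield from (layer.norm1, layer.norm2, layer.proj_norm)
            else:
                yield layer

    def save(self, path: str | Path) -> None:
        """Weights to .npz plus a JSON config sidecar."""
        path = Path(path)
        np.savez(path, **self._state_arrays())
        path.with_suffix(".json").write_text(self.config.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "CnnModel":
        path = Path(path)
        config = CnnConfig.from_json(path.with_suffix(".json").read_text())
        model = cls(config)
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
            for i, (p, _) in enumerate(model.params):
                p[...] = data[f"p{i:03d}"]
            bn = [l for l in model._layers_flat() if isinstance(l, BatchNorm2d)]
            for i, layer in enumerate(bn):
                layer.running_mean[...] = data[f"bn{i:03d}_mean"]
                layer.running_var[...] = data[f"bn{i:03d}_var"]
        return model


def build(config: CnnConfig) -> CnnModel:
    """Build an initialized (untrained) network from its configuration."""
    return CnnModel(config)


# -- training ---------------------------------------------------------------


class Adam:
    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def preprocess(images: Sequence, input_size: tuple[int, int]) -> np.ndarray:
    """Resize RGB images to the network input and scale to [-0.5, 0.5] NCHW."""
    out = np.empty((len(images), 3, *input_size), dtype=np.float32)
    for i, img in enumerate(images):
        arr = img.image if isinstance(img, FishSample) else np.asarray(img)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(f"image {i} is not HxWx3")
        if arr.shape[:2] != tuple(input_size):
            arr = resize(arr, input_size, preserve_range=True, anti_aliasing=True)
        out[i] = (arr.astype(np.float32) / 255.0 - 0.5).transpose(2, 0, 1)
    return out


def train(
    model: CnnModel,
    cohort: Sequence,
    labels: Sequence[str],
    epochs: Optional[int] = None,
    batch_size: Optional[int] = None,
    learning_rate: Optional[float] = None,
) -> CnnModel:
    """Train with cross-entropy and Adam; appends per-epoch loss/accuracy
    to ``model.training_log``.  Deterministic given the config seed."""
    cfg = model.config
    epochs = epochs or cfg.epochs
    batch_size = batch_size or cfg.batch_size
    lr = learning_rate or cfg.learning_rate
    y = np.asarray([CLASSES.index(lbl) for lbl in labels])
    if len(set(y.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    X = preprocess(cohort, cfg.input_size)
    n = len(y)
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.params, lr=lr)
    for epoch in range(epochs):
        order = rng.permutation(n)
        total_loss = 0.0
        correct = 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = X[idx], y[idx]
            logits = model.forward(xb, train=True)
            probs = softmax(logits)
            loss = -np.log(np.clip(probs[np.arange(len(yb)), yb], 1e-12, None)).mean()
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            model.backward(dlogits.astype(np.float32))
            opt.step()
            total_loss += loss * len(yb)
            correct += int((probs.argmax(axis=1) == yb).sum())
        model.training_log.append(
            {"epoch": epoch, "loss": total_loss / n, "accuracy": correct / n}
        )
    return model


def predict(model: CnnModel, sample) -> tuple[float, float, str]:
    """(P(male), P(female), predicted sex) for one sample or image.

    Predicted sex is the argmax; an exact 0.5 tie is classified female.
    """
    X = preprocess([sample], model.config.input_size)
    p_f, p_m = (float(v) for v in model.predict_proba(X)[0])
    return p_m, p_f, ("M" if p_m > p_f else "F")


def predict_batch(model: CnnModel, samples: Sequence, batch_size: int = 64) -> list[str]:
    """Predicted sexes for many samples (ties to female)."""
    X = preprocess(samples, model.config.input_size)
    out: list[str] = []
    for start in range(0, len(X), batch_size):
        probs = model.predict_proba(X[start : start + batch_size])
        out.extend("M" if pm > pf else "F" for pf, pm in probs)
    return out
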