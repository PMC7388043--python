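"""A small convolutional network for cough/noncough window classification.

The classifier maps one log-Mel spectrogram (80 x 122 by default) to a cough
probability through 5 convolutional layers with alternating 2x2 max-pooling,
a global max-pooling layer, and a single sigmoid output unit.  The first
layer uses 16 filters with a 1x7 kernel and "same" padding, so its feature
maps keep the input's spatial dimensions.  Weights are Xavier-initialised;
training uses minibatch gradient descent with Adam and dropout (rate 0.5)
on the pooled feature vector.

The implementation is plain numpy (im2col convolutions) — the networks here
are deliberately small, and a desk-scale preset with reduced channel widths
is provided for laptop-sized experiments.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ArchitectureSpec",
    "default_architecture",
    "desk_architecture",
    "CnnClassifier",
    "Adam",
    "DivergenceError",
]


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, iteration: int):
        super().__init__(f"non-finite loss at iteration {iteration}")
        self.iteration = iteration


@dataclasses.dataclass(frozen=True)
class ArchitectureSpec:
    """Channel widths and kernel shapes of the 5 convolutional layers.

    2x2 max-pooling follows each of the first four convolutions; the fifth is
    followed by global max-pooling and the sigmoid unit.
    """

    channels: tuple = (16, 32, 32, 64, 64)
    kernels: tuple = ((1, 7), (7, 1), (3, 3), (3, 3), (3, 3))
    dropout_rate: float = 0.5

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ArchitectureSpec":
        d = json.loads(s)
        return cls(
            channels=tuple(d["channels"]),
            kernels=tuple(tuple(k) for k in d["kernels"]),
            dropout_rate=d["dropout_rate"],
        )


def default_architecture() -> ArchitectureSpec:
    return ArchitectureSpec()


def desk_architecture() -> ArchitectureSpec:
    """Reduced channel widths for desk-scale corpora; same topology."""
    return ArchitectureSpec(channels=(16, 16, 16, 24, 24))


# ---------------------------------------------------------------------------
# layers

class _Conv2D:
    """Same-padding stride-1 convolution via im2col."""

    def __init__(self, c_in, c_out, kh, kw, rng, dtype):
        fan_in, fan_out = c_in * kh * kw, c_out * kh * kw
        limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
        self.W = rng.uniform(-limit, limit, (c_out, c_in * kh * kw)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.kh, self.kw = kh, kw
        self._cache = None

    def forward(self, x, train):
        n, c, h, w = x.shape
        ph, pw = self.kh // 2, self.kw // 2
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        cols = sliding_window_view(xp, (self.kh, self.kw), axis=(2, 3))
        cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, -1)
        out = cols @ self.W.T + self.b
        if train:
            self._cache = (cols, (n, c, h, w))
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, (n, c, h, w) = self._cache
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, -1)
        self.dW = dflat.T @ cols
        self.db = dflat.sum(axis=0)
        dcols = (dflat @ self.W).reshape(n, h, w, c, self.kh, self.kw)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)
        ph, pw = self.kh // 2, self.kw // 2
        dxp = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=dout.dtype)
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j]
        return dxp[:, :, ph:ph + h, pw:pw + w]

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class _ReLU:
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask

    def params(self):
        return []


class _MaxPool2:
    """2x2 max-pooling, stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x, train):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, :h2 * 2, :w2 * 2]
        win = xc.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(n, c, h2, w2, 4)
        self._arg = np.argmax(win, axis=-1)
        self._shape = (n, c, h, w)
        return np.take_along_axis(win, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._shape
        h2, w2 = h // 2, w // 2
        dwin = np.zeros((n, c, h2, w2, 4), dtype=dout.dtype)
        np.put_along_axis(dwin, self._arg[..., None], dout[..., None], axis=-1)
        dx = np.zeros((n, c, h, w), dtype=dout.dtype)
        dx[:, :, :h2 * 2, :w2 * 2] = (
            dwin.reshape(n, c, h2, w2, 2, 2)
                .transpose(0, 1, 2, 4, 3, 5)
                .reshape(n, c, h2 * 2, w2 * 2)
        )
        return dx

    def params(self):
        return []


class _GlobalMaxPool:
    def forward(self, x, train):
        n, c, h, w = x.shape
        flat = x.reshape(n, c, h * w)
        self._arg = np.argmax(flat, axis=-1)
        self._shape = (n, c, h, w)
        return np.take_along_axis(flat, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._shape
        dflat = np.zeros((n, c, h * w), dtype=dout.dtype)
        np.put_along_axis(dflat, self._arg[..., None], dout[..., None], axis=-1)
        return dflat.reshape(n, c, h, w)

    def params(self):
        return []


class _Dropout:
    """Inverted dropout; identity at inference."""

    def __init__(self, rate):
        self.rate = rate

    def forward(self, x, train, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask

    def params(self):
        return []


class _Dense:
    def __init__(self, c_in, rng, dtype):
        limit = np.sqrt(6.0 / (c_in + 1))
        self.W = rng.uniform(-limit, limit, (c_in, 1)).astype(dtype)
        self.b = np.zeros(1, dtype=dtype)

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Adam:
    """Adam optimiser over a flat list of (param, grad) arrays."""

    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self, params_and_grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(params_and_grads):
            m = self._m.setdefault(i, np.zeros_like(p))
            v = self._v.setdefault(i, np.zeros_like(p))
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class CnnClassifier:
    """Window classifier: log-Mel spectrogram -> cough probability.

    Spectrogram inputs are standardised per window (zero mean, unit variance)
    before entering the network; this removes the arbitrary dB offset of the
    log-Mel representation.  Dropout is active only during training, so
    inference is deterministic.
    """

    def __init__(self, arch: ArchitectureSpec | None = None,
                 input_shape=(80, 122), seed: int = 0, dtype=np.float32):
        self.arch = arch or default_architecture()
        self.input_shape = tuple(input_shape)
        self.seed = seed
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        layers = []
        c_in = 1
        for i, (c_out, (kh, kw)) in enumerate(zip(self.arch.channels, self.arch.kernels)):
            layers.append(_Conv2D(c_in, c_out, kh, kw, rng, dtype))
            layers.append(_ReLU())
            if i < 4:
                layers.append(_MaxPool2())
            c_in = c_out
        layers.append(_GlobalMaxPool())
        self._dropout = _Dropout(self.arch.dropout_rate)
        layers.append(self._dropout)
        layers.append(_Dense(c_in, rng, dtype))
        self.layers = layers
        self._train_rng = np.random.default_rng(seed + 1)

    # -- forward / backward ------------------------------------------------

    @staticmethod
    def prepare(spectrograms) -> np.ndarray:
        """Stack MelSpectrograms into a standardised (N, 1, H, W) batch."""
        x = np.stack([np.asarray(s.values, dtype=np.float64) for s in spectrograms])
        mean = x.mean(axis=(1, 2), keepdims=True)
        std = x.std(axis=(1, 2), keepdims=True)
        return ((x - mean) / (std + 1e-6))[:, None, :, :]

    def _forward(self, x, train):
        h = x.astype(self.dtype)
        for layer in self.layers:
            if isinstance(layer, _Dropout):
                h = layer.forward(h, train, rng=self._train_rng)
            else:
                h = layer.forward(h, train)
        return h[:, 0]  # logits

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        return self._forward(x, train=False)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Cough probability for a prepared (N, 1, H, W) batch."""
        return _sigmoid(self.predict_logits(x))

    def predict_proba_specs(self, spectrograms) -> np.ndarray:
        return self.predict_proba(self.prepare(spectrograms))

    def train_step(self, x: np.ndarray, y: np.ndarray, optimizer: Adam) -> float:
        """One minibatch gradient step; returns the batch cross-entropy."""
        z = self._forward(x, train=True)
        p = _sigmoid(z)
        # numerically stable BCE-with-logits
        loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
        dz = ((p - y) / y.size).astype(self.dtype)[:, None]
        grad = dz
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        pairs = []
        for layer in self.layers:
            for _, p_arr, g_name in layer.params():
                pairs.append((p_arr, getattr(layer, g_name)))
        optimizer.step(pairs)
        return loss

    def loss(self, x: np.ndarray, y: np.ndarray) -> float:
        z = self.predict_logits(x)
        return float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))

    # -- weights -----------------------------------------------------------

    def get_weights(self) -> list[np.ndarray]:
        return [p for layer in self.layers for _, p, _ in layer.params()]

    def set_weights(self, weights) -> None:
        own = self.get_weights()
        if len(own) != len(weights):
            raise ValueError("weight list does not match architecture")
        for p, w in zip(own, weights):
            if p.shape != w.shape:
                raise ValueError(f"shape mismatch {p.shape} vs {w.shape}")
            p[...] = w.astype(p.dtype)
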