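"""Minimal CPU neural-network engine (conv / pool / dense / dropout + Adam).

Self-contained float32 implementation with explicit forward/backward passes,
sized for the 30x30 patch classifier this package trains: convolutions are
3x3, stride 1, "same" padding, realized as an im2col matmul; pooling is 2x2
max with floor semantics.  Layers cache what backward needs; parameters and
their gradients live on the layer objects.  Determinism: all random state
(init, dropout, shuffling) comes from a single Generator owned by the net.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv3x3", "MaxPool2", "Dropout", "Flatten", "Dense", "SequentialNet", "Adam",
           "softmax", "cross_entropy"]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    n = len(y)
    return float(-np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean())


class Layer:
    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 same-padding convolution + optional ReLU, NHWC layout."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, relu: bool = True):
        scale = np.sqrt(2.0 / (9 * c_in))  # He init for ReLU stacks
        self.w = (rng.standard_normal((9 * c_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.relu = relu
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # N,H,W,C,3,3
        return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(n * h * w, 9 * c)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        cols = self._im2col(x)
        out = cols @ self.w + self.b
        out = out.reshape(n, h, w, -1)
        if self.relu:
            self._mask = out > 0
            out = out * self._mask
        self._cols, self._xshape = cols, x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        if self.relu:
            dout = dout * self._mask
        dflat = dout.reshape(n * h * w, -1)
        self.grads[0][...] = self._cols.T @ dflat
        self.grads[1][...] = dflat.sum(axis=0)
        dcols = (dflat @ self.w.T).reshape(n, h, w, 3, 3, c)
        dxp = np.zeros((n, h + 2, w + 2, c), dtype=np.float32)
        for i in range(3):
            for j in range(3):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, 1 : 1 + h, 1 : 1 + w, :]


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped (floor)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, : 2 * h2, : 2 * w2, :].reshape(n, h2, 2, w2, 2, c)
        out = xc.max(axis=(2, 4))
        self._mask = xc == out[:, :, None, :, None, :]
        self._xshape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        h2, w2 = h // 2, w // 2
        dx = np.zeros((n, h, w, c), dtype=np.float32)
        spread = self._mask * dout[:, :, None, :, None, :]
        dx[:, : 2 * h2, : 2 * w2, :] = spread.reshape(n, 2 * h2, 2 * w2, c)
        return dx


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate).astype(np.float32) / (1 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._xshape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, relu: bool = True):
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.relu = relu
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        out = x @ self.w + self.b
        if self.relu:
            self._mask = out > 0
            out = out * self._mask
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.relu:
            dout = dout * self._mask
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.w.T


class Adam:
    def __init__(self, lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            m, v = self.state.get(i, (np.zeros_like(p), np.zeros_like(p)))
            m = self.beta1 * m + (1 - self.beta1) * g
            v = self.beta2 * v + (1 - self.beta2) * g * g
            self.state[i] = (m, v)
            mh = m / (1 - self.beta1**self.t)
            vh = v / (1 - self.beta2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


class SequentialNet:
    """A stack of layers ending in logits; softmax/cross-entropy on top."""

    def __init__(self, layers: list[Layer], rng: np.random.Generator):
        self.layers = layers
        self.rng = rng

    @property
    def params(self) -> list[np.ndarray]:
        return [p for lay in self.layers for p in lay.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for lay in self.layers for g in lay.grads]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def predict_proba(self, x: np.ndarray, batch: int = 512) -> np.ndarray:
        outs = [softmax(self.forward(x[i : i + batch].astype(np.float32))) for i in range(0, len(x), batch)]
        return np.concatenate(outs) if outs else np.empty((0, 0))

    def train_batch(self, x: np.ndarray, y: np.ndarray, opt: Adam) -> float:
        logits = self.forward(x, train=True)
        probs = softmax(logits)
        loss = cross_entropy(probs, y)
        dlogits = probs.copy()
        dlogits[np.arange(len(y)), y] -= 1.0
        dlogits /= len(y)
        grad = dlogits.astype(np.float32)
        for lay in reversed(self.layers):
            grad = lay.backward(grad)
        opt.step(self.params, self.grads)
        return loss

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w
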