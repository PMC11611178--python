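"""Minimal feed-forward neural-network engine on numpy.

Implements exactly the layer types the two tracking networks need: 1-D
same-padding convolution (im2col + GEMM), batch normalization, fully
connected layers, ReLU/sigmoid, dropout, and an Adam optimizer with
decoupled weight decay. Gradients are hand-derived per layer; everything
runs in float32 on a single CPU.

All randomness (initialization, dropout masks) flows through the
``numpy.random.Generator`` handed to each layer, so training is
deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Layer:
    """Base class: layers expose params/grads as parallel lists."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state needed for inference (e.g. running stats)."""
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Conv1d(Layer):
    """Same-length 1-D convolution (zero padding), stride 1, odd kernel.

    Input/output layout: (batch, channels, length).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel width must be odd for same-length padding")
        self.cin, self.cout, self.k = in_channels, out_channels, kernel
        self.W = _he_init(rng, (out_channels, in_channels * kernel), in_channels * kernel)
        self.b = np.zeros(out_channels, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # x: (B, Cin, L) -> cols (B*L, Cin*K)
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        win = sliding_window_view(xp, self.k, axis=2)        # (B, Cin, L, K)
        cols = win.transpose(0, 2, 1, 3)                     # (B, L, Cin, K)
        b, l = x.shape[0], x.shape[2]
        return np.ascontiguousarray(cols).reshape(b * l, self.cin * self.k)

    def forward(self, x, training):
        b, _, l = x.shape
        cols = self._im2col(x)
        if training:
            self._cols = cols
            self._in_shape = x.shape
        y = cols @ self.W.T + self.b                          # (B*L, Cout)
        return y.reshape(b, l, self.cout).transpose(0, 2, 1)

    def backward(self, dy):
        b, _, l = dy.shape
        dyr = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(b * l, self.cout)
        self.dW[...] = dyr.T @ self._cols
        self.db[...] = dyr.sum(axis=0)
        # dx is the same-length correlation of dy with the channel-swapped,
        # spatially flipped kernel, so it reduces to one more im2col GEMM.
        wr = (self.W.reshape(self.cout, self.cin, self.k)[:, :, ::-1]
              .transpose(1, 0, 2).reshape(self.cin, self.cout * self.k))
        pad = self.k // 2
        dyp = np.pad(dy, ((0, 0), (0, 0), (pad, pad)))
        win = sliding_window_view(dyp, self.k, axis=2)        # (B, Cout, L, K)
        cols_dy = np.ascontiguousarray(win.transpose(0, 2, 1, 3)
                                       ).reshape(b * l, self.cout * self.k)
        self._cols = None
        return (cols_dy @ wr.T).reshape(b, l, self.cin).transpose(0, 2, 1)


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length) for (B, C, L) input."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def forward(self, x, training):
        c = x.shape[1]
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(1, c, 1)) * inv.reshape(1, c, 1)
        if training:
            self._cache = (xhat, inv.astype(DTYPE))
        return self.gamma.reshape(1, c, 1) * xhat + self.beta.reshape(1, c, 1)

    def backward(self, dy):
        xhat, inv = self._cache
        self._cache = None
        c = dy.shape[1]
        n = dy.shape[0] * dy.shape[2]
        self.dgamma[...] = (dy * xhat).sum(axis=(0, 2))
        self.dbeta[...] = dy.sum(axis=(0, 2))
        g = self.gamma.reshape(1, c, 1)
        dxhat = dy * g
        term = dxhat - dxhat.mean(axis=(0, 2), keepdims=True) \
            - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True) / n
        return term * inv.reshape(1, c, 1)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = _he_init(rng, (n_out, n_in), n_in)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training):
        if training:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy):
        self.dW[...] = dy.T @ self._x
        self.db[...] = dy.sum(axis=0)
        self._x = None
        return dy @ self.W


class ReLU(Layer):
    def forward(self, x, training):
        y = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Layer):
    """Logistic activation with the pre-activation clipped to ±8 so the
    derivative never underflows to exactly zero (keeps Adam able to pull a
    saturated regression head back into range)."""

    def forward(self, x, training):
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -8.0, 8.0)))
        self._y = y
        return y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p, self.rng = p, rng
        self._mask = None

    def forward(self, x, training):
        if not training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def buffers(self):
        return [b for layer in self.layers for b in layer.buffers()]

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))


class Adam:
    """Adam with decoupled weight decay (not applied to 1-D params: biases,
    batch-norm scales). ``lr`` may be reassigned between steps (schedules)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 weight_decay: float = 0.0, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= lr_t * m / (np.sqrt(v) + self.eps)
            if self.wd > 0.0 and p.ndim > 1:
                p -= self.lr * self.wd * p


def huber(err: np.ndarray, delta: float) -> np.ndarray:
    """Elementwise Huber penalty: quadratic within |err| <= delta, linear beyond."""
    if delta <= 0:
        raise ValueError("Huber delta must be positive")
    a = np.abs(err)
    return np.where(a <= delta, 0.5 * err ** 2, delta * (a - 0.5 * delta))


def huber_grad(err: np.ndarray, delta: float) -> np.ndarray:
    return np.clip(err, -delta, delta)
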