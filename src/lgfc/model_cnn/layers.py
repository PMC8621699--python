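"""Minimal NumPy neural-network layers with manual backpropagation.

No deep-learning framework is assumed by this package, so the handful of
layer types the four-branch classifier needs (1-D convolution, batch norm,
ReLU, max-pool, dropout, dense) are implemented here directly, together
with an Adam optimizer.  Everything is float32 and fully deterministic
given a seeded ``numpy.random.Generator``.

Conventions: convolutional activations have shape ``(batch, channels,
length)``; dense activations ``(batch, features)``.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Layer:
    """Base layer: forward caches what backward needs; params() exposes
    (param, grad) pairs for the optimizer."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []

    def n_params(self) -> int:
        return sum(p.size for p, _ in self.params())


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)  # He init
        self.W = rng.normal(0.0, scale, size=(n_in, n_out)).astype(F32)
        self.b = np.zeros(n_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Conv1D(Layer):
    """Valid 1-D convolution over (batch, in_channels, length)."""

    def __init__(self, c_in: int, c_out: int, width: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * width))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in, width)).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.width = width

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, L = x.shape
        k = self.width
        if L < k:
            raise ValueError(f"input length {L} shorter than kernel width {k}")
        Lout = L - k + 1
        # im2col: (B, Lout, C*k) @ (C*k, c_out)
        cols = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)  # (B, C, Lout, k)
        cols = cols.transpose(0, 2, 1, 3).reshape(B, Lout, C * k)
        self._cols = cols
        self._in_shape = x.shape
        out = cols @ self.W.reshape(self.W.shape[0], -1).T + self.b
        return out.transpose(0, 2, 1)  # (B, c_out, Lout)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, L = self._in_shape
        k = self.width
        g = grad.transpose(0, 2, 1)  # (B, Lout, c_out)
        Lout = g.shape[1]
        flat_g = g.reshape(-1, g.shape[2])  # (B*Lout, c_out)
        flat_cols = self._cols.reshape(-1, C * k)
        self.dW[...] = (flat_g.T @ flat_cols).reshape(self.W.shape)
        self.db[...] = flat_g.sum(axis=0)
        dcols = flat_g @ self.W.reshape(self.W.shape[0], -1)  # (B*Lout, C*k)
        dcols = dcols.reshape(B, Lout, C, k)
        dx = np.zeros((B, C, L), dtype=F32)
        for j in range(k):  # scatter-add column gradients back
            dx[:, :, j : j + Lout] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dx

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class BatchNorm(Layer):
    """Batch normalization per channel (axis 1) for 2-D or 3-D activations."""

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n_channels, dtype=F32)
        self.beta = np.zeros(n_channels, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_channels, dtype=F32)
        self.running_var = np.ones(n_channels, dtype=F32)
        self.momentum = momentum
        self.eps = eps

    def _axes(self, x: np.ndarray) -> tuple[int, ...]:
        return (0,) if x.ndim == 2 else (0, 2)

    def _shape(self, x: np.ndarray) -> tuple[int, ...]:
        return (1, -1) if x.ndim == 2 else (1, -1, 1)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes, shp = self._axes(x), self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        xhat = (x - mean.reshape(shp)) / np.sqrt(var.reshape(shp) + self.eps)
        self._xhat, self._var, self._train = xhat, var, train
        return self.gamma.reshape(shp) * xhat + self.beta.reshape(shp)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        axes, shp = self._axes(grad), self._shape(grad)
        xhat = self._xhat
        m = float(np.prod([grad.shape[a] for a in axes]))
        self.dgamma[...] = (grad * xhat).sum(axis=axes)
        self.dbeta[...] = grad.sum(axis=axes)
        inv_std = 1.0 / np.sqrt(self._var.reshape(shp) + self.eps)
        g = grad * self.gamma.reshape(shp)
        dx = (
            inv_std
            / m
            * (m * g - g.sum(axis=axes).reshape(shp) - xhat * (g * xhat).sum(axis=axes).reshape(shp))
        )
        return dx.astype(F32)

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling (size 2); odd tails are dropped."""

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, L = x.shape
        p = self.pool
        Lp = L // p
        if Lp == 0:
            raise ValueError(f"length {L} too short for pool size {p}")
        xv = x[:, :, : Lp * p].reshape(B, C, Lp, p)
        self._argmax = xv.argmax(axis=3)
        self._in_shape = x.shape
        return xv.max(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, L = self._in_shape
        p = self.pool
        Lp = L // p
        dx = np.zeros((B, C, Lp, p), dtype=F32)
        bi, ci, li = np.indices(self._argmax.shape)
        dx[bi, ci, li, self._argmax] = grad
        out = np.zeros((B, C, L), dtype=F32)
        out[:, :, : Lp * p] = dx.reshape(B, C, Lp * p)
        return out


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [pg for layer in self.layers for pg in layer.params()]

    @property
    def out_dim(self) -> int:
        """Output feature count of the last Dense layer."""
        for layer in reversed(self.layers):
            if isinstance(layer, Dense):
                return layer.W.shape[1]
        raise AttributeError("no Dense layer in block")


class Adam:
    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            p -= lr_t * self.m[i] / (np.sqrt(self.v[i]) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=F32)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(probs: np.ndarray, labels: np.ndarray, eps: float = 1e-7) -> float:
    p = np.clip(probs, eps, 1 - eps)
    return float(-np.mean(labels * np.log(p) + (1 - labels) * np.log(1 - p)))
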