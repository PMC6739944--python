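"""Minimal 1-D convolutional network core: layers, losses, RMSprop.

Everything is plain numpy (BLAS matmuls under the hood), which keeps training
deterministic on CPU for a fixed seed.  Shapes are channels-last:
``(batch, length, channels)``; DNA input has 4 channels (A, C, G, T).

Only what the sequence models need is implemented: Conv1D (valid padding,
stride 1), ReLU, per-channel batch normalization, non-overlapping max pooling,
dense layers, a fused sigmoid + binary-cross-entropy head, and RMSprop.
Backward passes are exercised against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base: parameters in ``params``, matching gradients in ``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1D(Layer):
    """Valid-padding stride-1 cross-correlation: (N, L, C) -> (N, L-w+1, K)."""

    def __init__(self, width: int, in_ch: int, out_ch: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        self.width, self.in_ch, self.out_ch = width, in_ch, out_ch
        scale = np.sqrt(2.0 / (width * in_ch))
        self.params["W"] = (rng.standard_normal((width * in_ch, out_ch)) * scale).astype(dtype)
        self.params["b"] = np.zeros(out_ch, dtype=dtype)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if x.shape[1] < self.width:
            raise ValueError(
                f"input length {x.shape[1]} below filter width {self.width}"
            )
        # windows: (N, P, C, w) -> (N, P, w*C) matching W's (w*C, K) layout
        win = sliding_window_view(x, self.width, axis=1)
        n, p = win.shape[0], win.shape[1]
        xcol = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(n, p, -1)
        self._xcol_shape = (n, p, x.shape[1], x.shape[2])
        self._xcol = xcol
        return xcol @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, p, _, c = self._xcol_shape
        k, w = self.out_ch, self.width
        self.grads["W"] = self._xcol.reshape(n * p, w * c).T @ dy.reshape(n * p, k)
        self.grads["b"] = dy.sum(axis=(0, 1))
        # full correlation of dy with the flipped kernel recovers dx
        pad = np.zeros((n, p + 2 * (w - 1), k), dtype=dy.dtype)
        pad[:, w - 1 : w - 1 + p] = dy
        win = sliding_window_view(pad, w, axis=1)          # (N, L, K, w)
        dcol = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(n, -1, w * k)
        Wf = (
            self.params["W"].reshape(w, c, k)[::-1]        # flip taps
            .transpose(0, 2, 1).reshape(w * k, c)
        )
        return dcol @ Wf


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0)


class BatchNorm1D(Layer):
    """Per-channel normalization over batch and position axes."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(channels, dtype=dtype)
        self.params["beta"] = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_std
        self._m = x.shape[0] * x.shape[1]
        self._train = train
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, m = self._xhat, self._inv_std, self._m
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 1))
        self.grads["beta"] = dy.sum(axis=(0, 1))
        dxhat = dy * self.params["gamma"]
        if not self._train:
            return dxhat * inv_std
        return (inv_std / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 1))
            - xhat * (dxhat * xhat).sum(axis=(0, 1))
        )


class MaxPool1D(Layer):
    """Non-overlapping pooling (stride = pool size); trailing remainder dropped."""

    def __init__(self, pool: int) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, length, k = x.shape
        p = self.pool
        n_out = length // p
        self._in_shape = x.shape
        xr = x[:, : n_out * p].reshape(n, n_out, p, k)
        self._arg = xr.argmax(axis=2)
        return np.take_along_axis(xr, self._arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, length, k = self._in_shape
        p = self.pool
        n_out = length // p
        dxr = np.zeros((n, n_out, p, k), dtype=dy.dtype)
        np.put_along_axis(dxr, self._arg[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[:, : n_out * p] = dxr.reshape(n, n_out * p, k)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: str | None = None, dtype=np.float32) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / n_in) if activation == "relu" else np.sqrt(1.0 / n_in)
        self.params["W"] = (rng.standard_normal((n_in, n_out)) * scale).astype(dtype)
        self.params["b"] = np.zeros(n_out, dtype=dtype)
        self.activation = activation

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        if self.activation == "sigmoid":
            self._a = sigmoid(z)
            return self._a
        if self.activation == "relu":
            self._mask = z > 0
            return np.where(self._mask, z, 0)
        return z

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.activation == "sigmoid":
            dy = dy * self._a * (1.0 - self._a)
        elif self.activation == "relu":
            dy = np.where(self._mask, dy, 0)
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross entropy over all entries; returns (loss, dloss/dlogits)."""
    z = logits
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = (sigmoid(z) - y) / z.size
    return loss, grad.astype(z.dtype)


class RMSprop:
    """RMSprop: gradient scaling by a running mean of squared gradients."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3, rho: float = 0.9,
                 eps: float = 1e-8) -> None:
        self.layers, self.lr, self.rho, self.eps = layers, lr, rho, eps
        self.cache = [
            {k: np.zeros_like(v) for k, v in layer.params.items()} for layer in layers
        ]

    def step(self) -> None:
        for layer, cache in zip(self.layers, self.cache):
            for k, p in layer.params.items():
                g = layer.grads[k].astype(p.dtype)
                cache[k] = self.rho * cache[k] + (1.0 - self.rho) * g * g
                p -= self.lr * g / (np.sqrt(cache[k]) + self.eps)


def l1l2_penalty(W: np.ndarray, l1: float, l2: float) -> tuple[float, np.ndarray]:
    """Elastic penalty l1*sum|w| + l2*sum w^2 with its gradient."""
    if l1 == 0.0 and l2 == 0.0:
        return 0.0, np.zeros_like(W)
    value = l1 * float(np.abs(W).sum()) + l2 * float((W * W).sum())
    grad = l1 * np.sign(W) + 2.0 * l2 * W
    return value, grad.astype(W.dtype)
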