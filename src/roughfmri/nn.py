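"""Minimal NumPy neural-network engine for 1-D convolutional regression.

Implements exactly the building blocks the path calibrator needs — 1-D
convolution (same padding) via im2col/GEMM, leaky ReLU, inverted dropout,
non-overlapping max pooling, dense layers, mean-squared-error loss and the
Adam optimiser — with explicit reverse-mode gradients.  All heavy lifting
is BLAS matmuls, so training runs at practical speed on a single CPU.
Gradients are verified against central finite differences in the test
suite.

Shapes follow the channels-last convention: activations are
``(batch, length, channels)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1DSame", "LeakyReLU", "Dropout", "MaxPool1D", "Flatten", "Dense",
    "Sequential", "Adam", "mse_loss",
]


class Layer:
    """Base layer: stateless unless it has ``params``/``grads`` lists."""

    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x, *, train: bool, rng=None):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError


class Conv1DSame(Layer):
    """1-D convolution with 'same' zero padding and unit stride.

    Weight shape (k * in_ch, out_ch) acting on im2col patches; padding is
    (k-1)//2 left and the remainder right, so output length equals input
    length for any kernel size.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng, dtype=np.float32):
        super().__init__()
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        fan_in = kernel * in_ch
        w = rng.standard_normal((fan_in, out_ch)) * np.sqrt(2.0 / fan_in)
        self.W = w.astype(dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.pad_l = (kernel - 1) // 2
        self.pad_r = kernel - 1 - self.pad_l

    def forward(self, x, *, train: bool, rng=None):
        B, L, C = x.shape
        xp = np.zeros((B, L + self.kernel - 1, C), dtype=x.dtype)
        xp[:, self.pad_l:self.pad_l + L] = x
        # (B, L, C, k) strided view -> (B, L, C*k) copy, C-major then tap
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=1)
        self._cols = np.ascontiguousarray(cols).reshape(B, L, C * self.kernel)
        self._in_shape = (B, L, C)
        return self._cols @ self.W + self.b

    def backward(self, dout):
        B, L, C = self._in_shape
        k = self.kernel
        flat_cols = self._cols.reshape(B * L, C * k)
        flat_dout = dout.reshape(B * L, self.out_ch)
        self.grads[0][...] = flat_cols.T @ flat_dout
        self.grads[1][...] = flat_dout.sum(axis=0)
        dcols = (flat_dout @ self.W.T).reshape(B, L, C, k)
        dxp = np.zeros((B, L + k - 1, C), dtype=dout.dtype)
        for j in range(k):
            dxp[:, j:j + L] += dcols[:, :, :, j]
        return dxp[:, self.pad_l:self.pad_l + L]


class LeakyReLU(Layer):
    """max(x, alpha * x); default slope alpha = 0.1."""

    def __init__(self, alpha: float = 0.1):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, *, train: bool, rng=None):
        self._neg = x < 0
        out = x.copy()
        out[self._neg] *= self.alpha
        return out

    def backward(self, dout):
        dx = dout.copy()
        dx[self._neg] *= self.alpha
        return dx


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, *, train: bool, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the length axis (floor division);
    trailing elements that do not fill a window are dropped."""

    def __init__(self, size: int = 3):
        super().__init__()
        self.size = size

    def forward(self, x, *, train: bool, rng=None):
        B, L, C = x.shape
        Lo = L // self.size
        if Lo < 1:
            raise ValueError(
                f"input length {L} shorter than pool size {self.size}")
        xw = x[:, :Lo * self.size].reshape(B, Lo, self.size, C)
        self._arg = xw.argmax(axis=2)
        self._in_shape = (B, L, C)
        return np.take_along_axis(xw, self._arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dout):
        B, L, C = self._in_shape
        Lo = L // self.size
        dxw = np.zeros((B, Lo, self.size, C), dtype=dout.dtype)
        np.put_along_axis(dxw, self._arg[:, :, None, :], dout[:, :, None, :], axis=2)
        dx = np.zeros((B, L, C), dtype=dout.dtype)
        dx[:, :Lo * self.size] = dxw.reshape(B, Lo * self.size, C)
        return dx


class Flatten(Layer):
    def forward(self, x, *, train: bool, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng, dtype=np.float32):
        super().__init__()
        w = rng.standard_normal((in_dim, out_dim)) * np.sqrt(2.0 / in_dim)
        self.W = w.astype(dtype)
        self.b = np.zeros(out_dim, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, *, train: bool, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


class Sequential:
    """Plain layer stack with explicit forward/backward passes."""

    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, *, train: bool = False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def get_weights(self):
        return [p.copy() for p in self.params]

    def set_weights(self, weights):
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class Adam:
    """Adam optimiser with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m[...] = self.beta1 * m + (1.0 - self.beta1) * g
            v[...] = self.beta2 * v + (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error over all elements, with its gradient in pred."""
    diff = pred - target
    loss = float(np.mean(diff ** 2))
    return loss, (2.0 / diff.size) * diff
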