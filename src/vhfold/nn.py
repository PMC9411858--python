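"""Minimal numpy building blocks for 1-D convolutional residual networks.

Layers operate on arrays of shape (batch, channels, length) in float64 and
implement exact analytic backward passes (verified against finite
differences in the test suite). Convolutions are stride-1, odd-kernel,
zero-padded "same" convolutions with optional dilation, evaluated as im2col
matrix products so the heavy lifting stays in BLAS.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def params(self) -> list[Parameter]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trained state (e.g. batch-norm running statistics)."""
        return []

    def forward(self, x: np.ndarray, training: bool, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """Same-padded stride-1 1-D convolution (cross-correlation) with dilation."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 dilation: int = 1, rng: np.random.Generator | None = None,
                 name: str = "conv"):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (in_channels * kernel))  # He initialization
        self.weight = Parameter(rng.normal(0.0, std, (out_channels, in_channels, kernel)),
                                f"{name}.weight")
        self.bias = Parameter(np.zeros(out_channels), f"{name}.bias")
        self.kernel = kernel
        self.dilation = dilation
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, training, rng=None):
        b, c, length = x.shape
        k, d = self.kernel, self.dilation
        pad = d * (k - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        idx = np.arange(length)[:, None] + d * np.arange(k)[None, :]
        cols = xp[:, :, idx]                                   # (B, C, L, K)
        cols2 = cols.transpose(0, 2, 1, 3).reshape(b * length, c * k)
        wmat = self.weight.value.reshape(self.weight.value.shape[0], c * k)
        out = (cols2 @ wmat.T).reshape(b, length, -1).transpose(0, 2, 1)
        out += self.bias.value[None, :, None]
        self._cache = (cols2, (b, c, length, pad))
        return out

    def backward(self, dout):
        cols2, (b, c, length, pad) = self._cache
        k, d = self.kernel, self.dilation
        o = self.weight.value.shape[0]
        dout2 = dout.transpose(0, 2, 1).reshape(b * length, o)
        self.weight.grad += (dout2.T @ cols2).reshape(o, c, k)
        self.bias.grad += dout.sum(axis=(0, 2))
        wmat = self.weight.value.reshape(o, c * k)
        dcols = (dout2 @ wmat).reshape(b, length, c, k).transpose(0, 2, 1, 3)
        dxp = np.zeros((b, c, length + 2 * pad))
        for j in range(k):
            dxp[:, :, j * d:j * d + length] += dcols[:, :, :, j]
        return dxp[:, :, pad:pad + length]


class BatchNorm1d(Layer):
    """Per-channel normalization over (batch, length) with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn"):
        self.gamma = Parameter(np.ones(channels), f"{name}.gamma")
        self.beta = Parameter(np.zeros(channels), f"{name}.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def forward(self, x, training, rng=None):
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            # in-place so buffers() references stay valid
            self.running_mean *= 1 - self.momentum
            self.running_mean += self.momentum * mean
            self.running_var *= 1 - self.momentum
            self.running_var += self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        self._cache = (xhat, inv_std, training)
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, dout):
        xhat, inv_std, training = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2))
        self.beta.grad += dout.sum(axis=(0, 2))
        dxhat = dout * self.gamma.value[None, :, None]
        if not training:
            return dxhat * inv_std[None, :, None]
        n = xhat.shape[0] * xhat.shape[2]
        sum_dxhat = dxhat.sum(axis=(0, 2), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (inv_std[None, :, None] / n) * (n * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)


class ReLU(Layer):
    def forward(self, x, training, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self._mask = None

    def forward(self, x, training, rng=None):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class ResidualBlock(Layer):
    """Pre-activation residual block: x + conv(relu(bn(conv(relu(bn(x)))))).

    Channel count is preserved so the skip connection is the identity.
    """

    def __init__(self, channels: int, kernel: int, dilation: int = 1,
                 rng=None, name: str = "res"):
        self.layers = [
            BatchNorm1d(channels, name=f"{name}.bn1"),
            ReLU(),
            Conv1d(channels, channels, kernel, dilation, rng, name=f"{name}.conv1"),
            BatchNorm1d(channels, name=f"{name}.bn2"),
            ReLU(),
            Conv1d(channels, channels, kernel, dilation, rng, name=f"{name}.conv2"),
        ]

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def buffers(self):
        return [b for layer in self.layers for b in layer.buffers()]

    def forward(self, x, training, rng=None):
        h = x
        for layer in self.layers:
            h = layer.forward(h, training, rng)
        return x + h

    def backward(self, dout):
        dh = dout
        for layer in reversed(self.layers):
            dh = layer.backward(dh)
        return dout + dh


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def buffers(self):
        return [b for layer in self.layers for b in layer.buffers()]

    def forward(self, x, training, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Adam:
    """Adam with conventional moment defaults (beta1=0.9, beta2=0.999)."""

    def __init__(self, parameters: list[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.parameters = parameters
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in parameters]
        self.v = [np.zeros_like(p.value) for p in parameters]
        self.t = 0

    def zero_grad(self):
        for p in self.parameters:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.parameters, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
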