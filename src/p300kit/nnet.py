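"""Minimal feed-forward network engine (numpy, manual backprop).

Implements exactly the layer types the detector needs — dense, 1D
convolution with stride, batch normalization, ReLU, dropout, flatten —
plus RMSprop and Adam optimizers and the MSE / binary-cross-entropy
losses.  Weight initialization is Glorot-uniform, seeded through a
``numpy.random.Generator`` so training is bit-reproducible.

Shapes follow the (batch, time, channels) convention; batch norm
normalizes over every axis except the last.
"""
from __future__ import annotations

from typing import Iterable, List, Optional

import numpy as np


def _glorot(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    trainable: bool = True

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> List[np.ndarray]:
        return []

    def grads(self) -> List[np.ndarray]:
        return []


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; inactive at inference (every unit preserved)."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not (0 <= rate < 1):
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class BatchNorm(Layer):
    """Normalizes over all axes except the last (the feature axis)."""

    def __init__(self, n_features: int, momentum: float = 0.99, eps: float = 1e-3):
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.dgamma = np.zeros(n_features)
        self.dbeta = np.zeros(n_features)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train=False):
        self._in_shape = x.shape
        flat = x.reshape(-1, x.shape[-1])
        if train:
            mean = flat.mean(axis=0)
            var = flat.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (flat - mean) * self._istd
        out = self.gamma * self._xhat + self.beta
        self._train = train
        return out.reshape(self._in_shape)

    def backward(self, grad):
        g = grad.reshape(-1, grad.shape[-1])
        self.dgamma[...] = (g * self._xhat).sum(axis=0)
        self.dbeta[...] = g.sum(axis=0)
        if not self._train:
            dx = g * self.gamma * self._istd
            return dx.reshape(self._in_shape)
        m = g.shape[0]
        gxhat = g * self.gamma
        dx = (self._istd / m) * (
            m * gxhat - gxhat.sum(axis=0) - self._xhat * (gxhat * self._xhat).sum(axis=0)
        )
        return dx.reshape(self._in_shape)

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]


class Conv1D(Layer):
    """Valid (no padding) strided 1D convolution on (batch, time, channels)."""

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 stride: int, rng: np.random.Generator):
        fan_in = kernel * in_channels
        self.W = _glorot(rng, (kernel, in_channels, filters), fan_in, filters)
        self.b = np.zeros(filters)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.kernel = kernel
        self.stride = stride

    @staticmethod
    def output_steps(length: int, kernel: int, stride: int) -> int:
        if length < kernel:
            raise ValueError(f"input length {length} shorter than kernel {kernel}")
        return (length - kernel) // stride + 1

    def forward(self, x, train=False):
        N, T, C = x.shape
        k, s = self.kernel, self.stride
        steps = self.output_steps(T, k, s)
        self._x = x
        Wf = self.W.reshape(k * C, -1)
        out = np.empty((N, steps, Wf.shape[1]))
        for t in range(steps):
            win = x[:, t * s: t * s + k, :].reshape(N, k * C)
            out[:, t, :] = win @ Wf + self.b
        return out

    def backward(self, grad):
        x = self._x
        N, T, C = x.shape
        k, s = self.kernel, self.stride
        steps = grad.shape[1]
        Wf = self.W.reshape(k * C, -1)
        dWf = np.zeros_like(Wf)
        dx = np.zeros_like(x)
        self.db[...] = grad.sum(axis=(0, 1))
        for t in range(steps):
            win = x[:, t * s: t * s + k, :].reshape(N, k * C)
            g = grad[:, t, :]
            dWf += win.T @ g
            dx[:, t * s: t * s + k, :] += (g @ Wf.T).reshape(N, k, C)
        self.dW[...] = dWf.reshape(self.W.shape)
        return dx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Sequential:
    def __init__(self, layers: Iterable[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> List[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> List[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def get_weights(self) -> List[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: List[np.ndarray]) -> None:
        own = self.params()
        if len(own) != len(weights):
            raise ValueError("weight list length mismatch")
        for p, w in zip(own, weights):
            p[...] = w

    def state(self) -> List[np.ndarray]:
        """All arrays needed to reproduce inference (incl. BN statistics)."""
        out = []
        for layer in self.layers:
            out.extend(layer.params())
            if isinstance(layer, BatchNorm):
                out.extend([layer.running_mean, layer.running_var])
        return out


class RMSprop:
    def __init__(self, lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-7):
        self.lr, self.rho, self.eps = lr, rho, eps
        self._cache: Optional[List[np.ndarray]] = None

    def step(self, params: List[np.ndarray], grads: List[np.ndarray]) -> None:
        if self._cache is None:
            self._cache = [np.zeros_like(p) for p in params]
        for p, g, c in zip(params, grads, self._cache):
            c[...] = self.rho * c + (1 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(c) + self.eps)


class Adam:
    def __init__(self, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m: Optional[List[np.ndarray]] = None
        self._v: Optional[List[np.ndarray]] = None
        self._t = 0

    def step(self, params: List[np.ndarray], grads: List[np.ndarray]) -> None:
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self._t += 1
        b1t = 1 - self.beta1 ** self._t
        b2t = 1 - self.beta2 ** self._t
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    z = logits.ravel()
    yv = y.ravel().astype(float)
    loss = float(np.mean(np.maximum(z, 0) - z * yv + np.log1p(np.exp(-np.abs(z)))))
    grad = ((sigmoid(z) - yv) / len(z)).reshape(logits.shape)
    return loss, grad


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(diff * diff)), 2.0 * diff / diff.size
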