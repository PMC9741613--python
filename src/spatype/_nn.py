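"""Minimal feed-forward neural-network core (numpy, manual backprop).

Implements exactly the primitives the annotation models need: affine
layers, GELU/ELU/ReLU nonlinearities, inverted dropout, batch
normalization, a sequential container and the Adam optimizer.  Forward
passes cache what the matching backward pass needs; parameters and their
gradients live on the layers as plain numpy arrays.

All randomness (weight init, dropout masks) flows through an explicit
``numpy.random.Generator`` so training is reproducible bit-for-bit given a
seed.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
from scipy.special import erf

__all__ = [
    "Linear", "GELU", "ELU", "ReLU", "Dropout", "BatchNorm", "Sequential", "Adam",
    "softmax", "log_softmax",
]


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=axis, keepdims=True))


class Layer:
    """Base class: stateless unless it declares ``params``."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (e.g. batch-norm running moments)."""
        return []

    def forward(self, x: np.ndarray, train: bool, rng: Optional[np.random.Generator]) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # Glorot-uniform init
        bound = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-bound, bound, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: Optional[np.ndarray] = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.dW[...] = self._x.T @ g
        self.db[...] = g.sum(axis=0)
        return g @ self.W.T


class GELU(Layer):
    """Exact Gaussian-error linear unit: x * Phi(x)."""

    def forward(self, x, train, rng):
        self._x = x
        self._cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        return x * self._cdf

    def backward(self, g):
        pdf = np.exp(-0.5 * self._x ** 2) / np.sqrt(2.0 * np.pi)
        return g * (self._cdf + self._x * pdf)


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x, train, rng):
        self._neg = x < 0
        self._exp = np.where(self._neg, np.exp(np.minimum(x, 0.0)), 1.0)
        return np.where(self._neg, self.alpha * (self._exp - 1.0), x)

    def backward(self, g):
        return g * np.where(self._neg, self.alpha * self._exp, 1.0)


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in eval mode or at rate 0."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class BatchNorm(Layer):
    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.dgamma = np.zeros(n)
        self.dbeta = np.zeros(n)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def forward(self, x, train, rng):
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._train = train
        return self.gamma * self._xhat + self.beta

    def backward(self, g):
        self.dgamma[...] = (g * self._xhat).sum(axis=0)
        self.dbeta[...] = g.sum(axis=0)
        if not self._train:
            return g * self.gamma / self._std
        n = g.shape[0]
        gx = g * self.gamma
        return (gx - gx.mean(axis=0) - self._xhat * (gx * self._xhat).mean(axis=0)) / self._std


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def buffers(self):
        return [b for l in self.layers for b in l.buffers()]

    def forward(self, x, train, rng):
        for l in self.layers:
            x = l.forward(x, train, rng)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: Iterable[np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Iterable[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def state_dict(layers: Iterable[Layer]) -> list[np.ndarray]:
    """Snapshot all parameters and buffers (copies) for checkpointing."""
    layers = list(layers)
    flat = [p for l in layers for p in l.params()] + [b for l in layers for b in l.buffers()]
    return [p.copy() for p in flat]


def load_state(layers: Iterable[Layer], state: list[np.ndarray]) -> None:
    layers = list(layers)
    flat = [p for l in layers for p in l.params()] + [b for l in layers for b in l.buffers()]
    if len(flat) != len(state):
        raise ValueError("checkpoint does not match model architecture")
    for p, s in zip(flat, state):
        p[...] = s
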