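"""Minimal numpy neural-net primitives used by the recognition model.

Layers operate on frame matrices ``[N, D]`` (frames pooled across a batch of
clips); each exposes ``forward`` and ``backward`` plus a dict of parameters
and gradients so optimizer groups can be assigned per module.
"""

from __future__ import annotations

import numpy as np

LEAKY_SLOPE = 0.01


def leaky_relu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, LEAKY_SLOPE * x)


def leaky_relu_grad(x: np.ndarray, dy: np.ndarray) -> np.ndarray:
    return np.where(x > 0, dy, LEAKY_SLOPE * dy)


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        # He-style init for leaky-rectifier nets
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.gW = self._x.T @ dy
        self.gb = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    def grads(self) -> dict[str, np.ndarray]:
        return {"W": self.gW, "b": self.gb}


class BatchNorm:
    """Per-feature normalization over the pooled batch x time axis."""

    def __init__(self, d: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(d)
        self.beta = np.zeros(d)
        self.run_mean = np.zeros(d)
        self.run_var = np.ones(d)
        self.momentum = momentum
        self.eps = eps
        self.ggamma = np.zeros(d)
        self.gbeta = np.zeros(d)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if training:
            self._cache = (xhat, inv_std)
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        n = dy.shape[0]
        self.ggamma = (dy * xhat).sum(axis=0)
        self.gbeta = dy.sum(axis=0)
        dxhat = dy * self.gamma
        return (
            inv_std
            / n
            * (n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
        )

    def params(self) -> dict[str, np.ndarray]:
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self) -> dict[str, np.ndarray]:
        return {"gamma": self.ggamma, "beta": self.gbeta}

    def state(self) -> dict[str, np.ndarray]:
        return {"run_mean": self.run_mean, "run_var": self.run_var}


class Dropout:
    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None = None) -> np.ndarray:
        if not training or self.p == 0.0:
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


def log_softmax(z: np.ndarray) -> np.ndarray:
    zmax = z.max(axis=-1, keepdims=True)
    s = z - zmax
    return s - np.log(np.exp(s).sum(axis=-1, keepdims=True))


class AdaDelta:
    """Adaptive-gradient method with per-parameter accumulators.

    Defaults follow the adaptive-delta recipe: lr 1.0, rho 0.95, eps 1e-8.
    The ``lr`` attribute is the annealable multiplier on the computed update.
    """

    def __init__(self, lr: float = 1.0, rho: float = 0.95, eps: float = 1e-8):
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self._Eg: dict[int, np.ndarray] = {}
        self._Ex: dict[int, np.ndarray] = {}

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        for i, (p, g) in enumerate(zip(params, grads)):
            Eg = self._Eg.setdefault(i, np.zeros_like(p))
            Ex = self._Ex.setdefault(i, np.zeros_like(p))
            Eg *= self.rho
            Eg += (1 - self.rho) * g * g
            dx = -np.sqrt((Ex + self.eps) / (Eg + self.eps)) * g
            Ex *= self.rho
            Ex += (1 - self.rho) * dx * dx
            p += self.lr * dx


class Adam:
    """Adaptive-moment method; default lr 1e-4 as used for the encoder group."""

    def __init__(self, lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            m = self._m.setdefault(i, np.zeros_like(p))
            v = self._v.setdefault(i, np.zeros_like(p))
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1 ** self.t)
            vhat = v / (1 - self.beta2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
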