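"""Minimal fully connected network machinery with manual backpropagation.

Just what the adversarial imputer needs: dense layers with seeded fan-in
initialization, batch normalization, relu/tanh, and sgd / momentum / adam
updates.  Everything is float64 numpy and deterministic given the seed.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = data
        self.grad = np.zeros_like(data)


class Dense:
    """Affine layer; weights ~ U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(n_in)
        self.W = Param(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.W.data.T

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]


class BatchNorm:
    """Batch normalization with running statistics for inference."""

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(dim))
        self.beta = Param(np.zeros(dim))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean) / std
        self._cache = (xhat, std, x.shape[0])
        return self.gamma.data * xhat + self.beta.data

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, std, n = self._cache
        self.gamma.grad += (g * xhat).sum(axis=0)
        self.beta.grad += g.sum(axis=0)
        gx = g * self.gamma.data
        # batch-statistics backward (biased variance)
        return (gx - gx.mean(axis=0) - xhat * (gx * xhat).mean(axis=0)) / std

    @property
    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class Activation:
    def __init__(self, kind: str):
        if kind not in ("relu", "tanh"):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind
        self._cache: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if self.kind == "relu":
            out = np.maximum(x, 0.0)
        else:
            out = np.tanh(x)
        self._cache = out
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        out = self._cache
        if self.kind == "relu":
            return g * (out > 0)
        return g * (1.0 - out * out)

    @property
    def params(self) -> list[Param]:
        return []


class MLP:
    """Feed-forward stack ending in a linear (logit) layer."""

    def __init__(
        self,
        n_in: int,
        n_out: int,
        hidden_layers: int,
        neurons: int,
        activation: str,
        rng: np.random.Generator,
        batch_norm: bool = False,
    ):
        self.layers: list = []
        width = n_in
        for _ in range(hidden_layers):
            self.layers.append(Dense(width, neurons, rng))
            if batch_norm:
                self.layers.append(BatchNorm(neurons))
            self.layers.append(Activation(activation))
            width = neurons
        self.layers.append(Dense(width, n_out, rng))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        """Propagate output-logit gradients; returns the input gradient."""
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    @property
    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class Optimizer:
    """First-order updates: plain sgd, classical momentum (0.9), or adam."""

    def __init__(self, params: list[Param], kind: str, lr: float):
        if kind not in ("sgd", "momentum", "adam"):
            raise ValueError(f"unknown optimizer {kind!r}")
        self.params = params
        self.kind = kind
        self.lr = lr
        self.t = 0
        if kind == "momentum":
            self.v = [np.zeros_like(p.data) for p in params]
        elif kind == "adam":
            self.m = [np.zeros_like(p.data) for p in params]
            self.v = [np.zeros_like(p.data) for p in params]
            self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if self.kind == "sgd":
                p.data -= self.lr * g
            elif self.kind == "momentum":
                self.v[i] = 0.9 * self.v[i] - self.lr * g
                p.data += self.v[i]
            else:
                self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
                self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
                mhat = self.m[i] / (1 - self.beta1**self.t)
                vhat = self.v[i] / (1 - self.beta2**self.t)
                p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            p.grad[...] = 0.0
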