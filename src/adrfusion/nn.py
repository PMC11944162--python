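"""Neural-network building blocks on top of :mod:`adrfusion.autodiff`.

Modules follow the familiar ``forward``/``parameters``/``train``/``eval``
idiom.  Initialisation is uniform Glorot everywhere, drawn from a
``numpy.random.Generator`` supplied by the caller so models are fully
reproducible from a single integer seed.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import Tensor


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...] | None = None) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Parameter(Tensor):
    """A Tensor that is always trainable."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: recursive parameter collection and train/eval mode."""

    def __init__(self) -> None:
        self.training = True

    def parameters(self) -> Iterator[Parameter]:
        seen: set[int] = set()
        for value in self.__dict__.values():
            yield from _params_of(value, seen)

    def train(self) -> "Module":
        for m in self._submodules():
            m.training = True
        self.training = True
        return self

    def eval(self) -> "Module":
        for m in self._submodules():
            m.training = False
        self.training = False
        return self

    def _submodules(self) -> Iterator["Module"]:
        for value in self.__dict__.values():
            yield from _modules_of(value)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _params_of(value, seen: set[int]):
    if isinstance(value, Parameter):
        if id(value) not in seen:
            seen.add(id(value))
            yield value
    elif isinstance(value, Module):
        for p in value.parameters():
            if id(p) not in seen:
                seen.add(id(p))
                yield p
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _params_of(v, seen)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _params_of(v, seen)


def _modules_of(value):
    if isinstance(value, Module):
        yield value
        yield from value._submodules()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _modules_of(v)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _modules_of(v)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        self.W = Parameter(glorot_uniform(rng, in_dim, out_dim))
        self.b = Parameter(np.zeros(out_dim)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return out


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.table = Parameter(rng.normal(0.0, 1.0 / math.sqrt(dim),
                                          size=(n_tokens, dim)))

    def forward(self, ids: np.ndarray) -> Tensor:
        return self.table[np.asarray(ids, dtype=np.intp)]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=-1, keepdims=True)
        return centred / (var + self.eps).sqrt() * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0,1): {p}")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class Adam:
    """Adaptive-moment optimizer (the package default for all training)."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
            if self.weight_decay:  # decoupled (AdamW-style)
                p.data -= self.lr * self.weight_decay * p.data

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def binary_cross_entropy_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean BCE over all (sample, label) cells, computed stably from logits.

    Uses the identity ``bce = softplus(z) - y*z`` which avoids log(0) for
    saturated sigmoids.
    """
    y = Tensor(np.asarray(targets, dtype=np.float64))
    return (logits.softplus() - logits * y).mean()
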