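"""Neural-network building blocks on top of :mod:`m6atmr.autodiff`.

Deliberately small: linear and embedding layers, layer normalization, the
Adam optimizer, and Glorot initialization.  Modules expose ``parameters()``
returning the flat list of trainable tensors.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["glorot", "Linear", "Embedding", "LayerNorm", "Adam"]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           shape: tuple[int, ...] | None = None) -> Tensor:
    """Glorot/Xavier uniform initialization as a trainable tensor."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Linear:
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int,
                 bias: bool = True, identity_init: bool = False):
        if identity_init and d_in == d_out:
            self.W = Tensor(np.eye(d_in), requires_grad=True)
        else:
            self.W = glorot(rng, d_in, d_out)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        return y + self.b if self.b is not None else y

    def parameters(self) -> list[Tensor]:
        return [self.W] + ([self.b] if self.b is not None else [])


class Embedding:
    def __init__(self, rng: np.random.Generator, n_tokens: int, d: int):
        self.W = Tensor(rng.normal(0.0, 1.0 / np.sqrt(d), size=(n_tokens, d)),
                        requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.W.take_rows(idx)

    def parameters(self) -> list[Tensor]:
        return [self.W]


class LayerNorm:
    def __init__(self, d: int, eps: float = 1e-5):
        self.g = Tensor(np.ones(d), requires_grad=True)
        self.b = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.g + self.b

    def parameters(self) -> list[Tensor]:
        return [self.g, self.b]


class Adam:
    """Adam with the standard bias correction; operates in place."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
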