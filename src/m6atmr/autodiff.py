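"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients.  Only the operations needed by the package's
networks are provided (broadcast arithmetic, batched matmul, softmax, sigmoid,
ReLU, reductions, embedding lookup, 1-D convolution, a numerically stable
binary cross-entropy on logits).  Everything runs in float64 on CPU.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "bce_with_logits", "concat", "no_grad", "pairwise_l1"]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager that disables graph recording (saves memory)."""

    def __enter__(self):
        self._old = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._old
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward_fn", "_prev")

    def __init__(self, data, requires_grad: bool = False,
                 _prev: Sequence["Tensor"] = (),
                 _backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        enabled = _GRAD_ENABLED[0]
        self.requires_grad = bool(requires_grad) and enabled
        self.grad: np.ndarray | None = None
        self._prev = tuple(_prev) if enabled else ()
        self._backward_fn = _backward if enabled else None

    @property
    def _backward(self):
        return self._backward_fn

    @_backward.setter
    def _backward(self, fn):
        # dropping the closure under no_grad releases captured activations
        self._backward_fn = fn if _GRAD_ENABLED[0] else None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without argument requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))
        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(-g)
        out._backward = _bw
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))
        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / other.data ** 2,
                                               other.data.shape))
        out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))
        out._backward = _bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, self.requires_grad or other.requires_grad,
                     (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g @ np.swapaxes(other.data, -1, -2),
                                              self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                               other.data.shape))
        out._backward = _bw
        return out

    # ------------------------------------------------------------ elementwise
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0))
        out._backward = _bw
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * np.sign(self.data))
        out._backward = _bw
        return out

    def sigmoid(self):
        y = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # stable logistic
        out = Tensor(y, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * y * (1.0 - y))
        out._backward = _bw
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * y)
        out._backward = _bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)
        out._backward = _bw
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accumulate(y * (g - dot))
        out._backward = _bw
        return out

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape: int):
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))
        out._backward = _bw
        return out

    def transpose(self, *axes: int):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        inv = np.argsort(axes)

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))
        out._backward = _bw
        return out

    @property
    def T(self):
        return self.transpose()

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def _bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())
        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------------ gather/conv
    def take_rows(self, idx: np.ndarray):
        """Row lookup ``self[idx]`` (embedding tables); idx is an int array."""
        idx = np.asarray(idx)
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, idx.reshape(-1), g.reshape(-1, self.data.shape[-1]))
                self._accumulate(acc)
        out._backward = _bw
        return out

    def conv1d3(self, w: "Tensor", b: "Tensor"):
        """Single-channel 1-D convolution, kernel 3, zero padding 1.

        ``self`` has shape (batch, length); ``w`` shape (3,), ``b`` scalar.
        """
        x = self.data
        pad = np.pad(x, ((0, 0), (1, 1)))
        y = (w.data[0] * pad[:, :-2] + w.data[1] * pad[:, 1:-1]
             + w.data[2] * pad[:, 2:] + b.data)
        out = Tensor(y, self.requires_grad or w.requires_grad or b.requires_grad,
                     (self, w, b))

        def _bw(g):
            if self.requires_grad:
                gp = np.pad(g, ((0, 0), (1, 1)))
                dx = (w.data[0] * gp[:, 2:] + w.data[1] * gp[:, 1:-1]
                      + w.data[2] * gp[:, :-2])
                self._accumulate(dx)
            if w.requires_grad:
                dw = np.array([(g * pad[:, :-2]).sum(),
                               (g * pad[:, 1:-1]).sum(),
                               (g * pad[:, 2:]).sum()])
                w._accumulate(dw)
            if b.requires_grad:
                b._accumulate(np.array(g.sum()).reshape(b.data.shape))
        out._backward = _bw
        return out


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])
    out._backward = _bw
    return out


def pairwise_l1(E: Tensor) -> Tensor:
    """All-pairs Manhattan distance matrix of the rows of E, shape (m, m).

    Forward uses scipy's cdist; backward materializes the (chunk, m, d) sign
    tensor in row chunks to keep memory bounded.
    """
    from scipy.spatial.distance import cdist

    X = E.data
    D = cdist(X, X, metric="cityblock")
    out = Tensor(0.5 * (D + D.T), E.requires_grad, (E,))

    def _bw(g):
        if not E.requires_grad:
            return
        m, d = X.shape
        gs = g + g.T
        acc = np.empty_like(X)
        chunk = max(1, int(2 ** 24 / max(m * d, 1)))
        for lo in range(0, m, chunk):
            hi = min(m, lo + chunk)
            sign = np.sign(X[lo:hi, None, :] - X[None, :, :])
            acc[lo:hi] = np.einsum("cm,cmd->cd", gs[lo:hi], sign)
        E._accumulate(acc)
    out._backward = _bw
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray | Tensor) -> Tensor:
    """Mean binary cross-entropy between ``sigmoid(logits)`` and targets.

    Computed as ``mean(softplus(logits) - targets * logits)`` which is stable
    for large |logits|; targets must lie in [0, 1] and carry no gradient.
    """
    t = targets.data if isinstance(targets, Tensor) else np.asarray(targets, dtype=np.float64)
    if t.min() < 0.0 or t.max() > 1.0:
        raise ValueError("BCE targets must lie in [0, 1]")
    x = logits.data
    softplus = np.logaddexp(0.0, x)
    val = np.mean(softplus - t * x)
    out = Tensor(val, logits.requires_grad, (logits,))

    def _bw(g):
        if logits.requires_grad:
            sig = 0.5 * (1.0 + np.tanh(0.5 * x))
            logits._accumulate(g * (sig - t) / x.size)
    out._backward = _bw
    return out
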