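"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A tape-free define-by-run engine: each :class:`Tensor` records its parents and
a closure that accumulates gradients into them.  Only the operations the
residue-graph networks need are implemented (dense linear algebra, pointwise
nonlinearities, row gather / scatter-add for message passing, softmax,
concatenation).  Everything runs in float64 so gradients can be checked
against central finite differences.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "zeros", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast when producing it from `shape`."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __sub__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g, other.shape))

        return self._make(self.data - other.data, (self, other), backward)

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) - self

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    # -- shape ops ------------------------------------------------------------

    @property
    def T(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            self._accum(g.T)

        return self._make(self.data.T, (self,), backward)

    def reshape(self, *shape: int) -> "Tensor":
        old = self.shape

        def backward(g: np.ndarray) -> None:
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def take_rows(self, index: np.ndarray) -> "Tensor":
        """Gather rows (axis 0); the adjoint scatter-adds."""
        index = np.asarray(index, dtype=np.intp)

        def backward(g: np.ndarray) -> None:
            acc = np.zeros_like(self.data)
            np.add.at(acc, index, g)
            self._accum(acc)

        return self._make(self.data[index], (self,), backward)

    def scatter_add_rows(self, index: np.ndarray, n_rows: int) -> "Tensor":
        """Sum rows of self into `n_rows` buckets given by `index` (axis 0)."""
        index = np.asarray(index, dtype=np.intp)
        out = np.zeros((n_rows,) + self.shape[1:], dtype=np.float64)
        np.add.at(out, index, self.data)

        def backward(g: np.ndarray) -> None:
            self._accum(g[index])

        return self._make(out, (self,), backward)

    def slice_cols(self, start: int, stop: int) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            acc = np.zeros_like(self.data)
            acc[:, start:stop] = g
            self._accum(acc)

        return self._make(self.data[:, start:stop], (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), backward)

    def mean(self) -> "Tensor":
        n = self.data.size

        def backward(g: np.ndarray) -> None:
            self._accum(np.full(self.shape, g / n))

        return self._make(self.data.mean(), (self,), backward)

    # -- pointwise nonlinearities --------------------------------------------

    def square(self) -> "Tensor":
        return self * self

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g: np.ndarray) -> None:
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g: np.ndarray) -> None:
            self._accum(g * mask)

        return self._make(np.where(mask, self.data, 0.0), (self,), backward)

    def sigmoid(self) -> "Tensor":
        s = _sigmoid(self.data)

        def backward(g: np.ndarray) -> None:
            self._accum(g * s * (1.0 - s))

        return self._make(s, (self,), backward)

    def silu(self) -> "Tensor":
        s = _sigmoid(self.data)
        out_data = self.data * s

        def backward(g: np.ndarray) -> None:
            self._accum(g * (s + out_data * (1.0 - s)))

        return self._make(out_data, (self,), backward)

    def softmax_rows(self) -> "Tensor":
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)

        def backward(g: np.ndarray) -> None:
            dot = (g * p).sum(axis=-1, keepdims=True)
            self._accum(p * (g - dot))

        return self._make(p, (self,), backward)

    def weighted_bce_with_logits(self, targets: np.ndarray,
                                 weights: np.ndarray) -> "Tensor":
        """Mean of w * BCE(sigmoid(z), y), computed stably from logits."""
        z = self.data
        y = np.asarray(targets, dtype=np.float64)
        w = np.asarray(weights, dtype=np.float64)
        # log(1+e^z) without overflow
        log1pexp = np.logaddexp(0.0, z)
        loss = w * (log1pexp - y * z)
        n = loss.size

        def backward(g: np.ndarray) -> None:
            self._accum(g * w * (_sigmoid(z) - y) / n)

        return self._make(loss.mean(), (self,), backward)

    # -- backprop driver ------------------------------------------------------

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse sweep in topological order, seeding d(self)/d(self)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def zeros(*shape: int, requires_grad: bool = False) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=requires_grad)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    out = Tensor(data, requires_grad=any(t.requires_grad for t in tensors))

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    if out.requires_grad:
        out._parents = tuple(tensors)
        out._backward = backward
    return out
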