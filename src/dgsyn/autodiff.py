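"""Minimal reverse-mode automatic differentiation over numpy arrays.

All networks in this package are small dense models over molecular graphs,
expression profiles and a triple hypergraph, so the engine favours clarity
over kernel coverage: a :class:`Tensor` wraps an ``ndarray`` and records its
parents together with a closure that accumulates gradients into them;
``backward()`` walks the tape in reverse topological order. Broadcasting
follows numpy semantics and gradients are un-broadcast back to each parent's
shape. Everything is float64.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "stack", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling tape construction (evaluation mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` back down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- autograd core --------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative post-order DFS (graphs can be deep for long loops)
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            pending = [p for p in node._parents if id(p) not in seen and p.requires_grad]
            if pending:
                stack.append(node)
                stack.extend(pending)
            else:
                seen.add(id(node))
                topo.append(node)
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- elementwise arithmetic -----------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(
            self.data + other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
        )
        if out.requires_grad:
            def backward(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(g)
                if b.requires_grad:
                    b._accum(g)
            out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(
            self.data * other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
        )
        if out.requires_grad:
            def backward(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(g * b.data)
                if b.requires_grad:
                    b._accum(g * a.data)
            out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) * self.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        out = Tensor(self.data ** exponent, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            def backward(g, a=self, p=exponent):
                a._accum(g * p * a.data ** (p - 1.0))
            out._backward = backward
        return out

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, v=out.data: a._accum(g * v)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g / a.data)
        return out

    # -- nonlinearities ---------------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, m=mask: a._accum(g * m)
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        mask = np.where(self.data > 0, 1.0, slope)
        out = Tensor(self.data * mask, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, m=mask: a._accum(g * m)
        return out

    def sigmoid(self) -> "Tensor":
        v = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(v, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, v=v: a._accum(g * v * (1.0 - v))
        return out

    def tanh(self) -> "Tensor":
        v = np.tanh(self.data)
        out = Tensor(v, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, v=v: a._accum(g * (1.0 - v * v))
        return out

    # -- reductions -------------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            requires_grad=self.requires_grad,
            parents=(self,),
        )
        if out.requires_grad:
            def backward(g, a=self, axis=axis, keepdims=keepdims):
                if axis is None:
                    a._accum(np.broadcast_to(g, a.shape))
                else:
                    if not keepdims:
                        g = np.expand_dims(g, axis)
                    a._accum(np.broadcast_to(g, a.shape))
            out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def amax(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Max along one axis; ties share the gradient equally."""
        v = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == v).astype(np.float64)
        mask /= mask.sum(axis=axis, keepdims=True)
        out_data = v if keepdims else np.squeeze(v, axis=axis)
        out = Tensor(out_data, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            def backward(g, a=self, m=mask, axis=axis, keepdims=keepdims):
                if not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum(g * m)
            out._backward = backward
        return out

    # -- shape ops ----------------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g.reshape(a.shape))
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, inv=tuple(inv): a._accum(g.transpose(inv))
        return out

    def swap_last(self) -> "Tensor":
        axes = list(range(self.ndim))
        axes[-1], axes[-2] = axes[-2], axes[-1]
        return self.transpose(*axes)

    def gather(self, index) -> "Tensor":
        """Row gather along axis 0 with integer indices (repeats allowed)."""
        index = np.asarray(index, dtype=np.intp)
        out = Tensor(self.data[index], requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            def backward(g, a=self, idx=index):
                acc = np.zeros_like(a.data)
                np.add.at(acc, idx, g)
                a._accum(acc)
            out._backward = backward
        return out

    # -- linear algebra -------------------------------------------------------------
    def matmul(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(
            self.data @ other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
        )
        if out.requires_grad:
            def backward(g, a=self, b=other):
                if a.requires_grad:
                    ga = g @ np.swapaxes(b.data, -1, -2)
                    a._accum(_unbroadcast(ga, a.shape))
                if b.requires_grad:
                    gb = np.swapaxes(a.data, -1, -2) @ g
                    b._accum(_unbroadcast(gb, b.shape))
            out._backward = backward
        return out

    __matmul__ = matmul


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    requires = any(t.requires_grad for t in tensors)
    out = Tensor(data, requires_grad=requires, parents=tuple(tensors))
    if out.requires_grad:
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def backward(g, parts=tensors, splits=splits, axis=axis):
            for part, piece in zip(parts, np.split(g, splits, axis=axis)):
                if part.requires_grad:
                    part._accum(piece)
        out._backward = backward
    return out


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)
    requires = any(t.requires_grad for t in tensors)
    out = Tensor(data, requires_grad=requires, parents=tuple(tensors))
    if out.requires_grad:
        def backward(g, parts=tensors, axis=axis):
            for i, part in enumerate(parts):
                if part.requires_grad:
                    part._accum(np.take(g, i, axis=axis))
        out._backward = backward
    return out
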