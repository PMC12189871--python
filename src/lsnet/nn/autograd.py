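"""Reverse-mode automatic differentiation on numpy arrays.

A small, self-contained tape-based autograd: :class:`Tensor` wraps an
``ndarray`` and records, for every differentiable operation, a closure that
accumulates gradients into its parents.  The op set is exactly what an
anchor-based convolutional detector needs — elementwise arithmetic,
exp/log/arctan, sigmoid/SiLU, broadcasting reductions, matmul, slicing and
concatenation — plus the spatial primitives (convolution, pooling,
up-sampling, batch normalisation) defined in :mod:`lsnet.nn.functional`.

Gradients follow numpy broadcasting semantics: a parent broadcast up to the
child's shape receives its gradient summed back down to its own shape.
Arrays keep their dtype, so loss arithmetic can run in float64 for
gradient-checking while model weights stay float32.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "stack", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev, _GRAD_ENABLED = _GRAD_ENABLED, False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- bookkeeping ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self) -> int:
        return self.data.size

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:
        return f"Tensor({self.data!r}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- autodiff ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar outputs")
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=self.data.dtype)

        # topological order over the tape
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents
                         if id(p) not in seen and p.requires_grad]
            ready = True
            for p in unvisited:
                if p._parents:
                    stack.append(p)
                    ready = False
            if ready:
                seen.add(id(node))
                topo.append(node)
                stack.pop()

        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._parents == () or node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            node._backward_dispatch(g, grads)

    def _backward_dispatch(self, g: np.ndarray, grads: dict[int, np.ndarray]) -> None:
        contribs = self._backward(g)
        for parent, pg in zip(self._parents, contribs):
            if not parent.requires_grad or pg is None:
                continue
            pg = _unbroadcast(np.asarray(pg), parent.data.shape)
            key = id(parent)
            if parent._parents and parent._backward is not None:
                grads[key] = pg if key not in grads else grads[key] + pg
            else:
                parent.grad = pg if parent.grad is None else parent.grad + pg

    # -- elementwise arithmetic ---------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        return Tensor._make(self.data + other.data, (self, other),
                            lambda g: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        other = as_tensor(other)
        return Tensor._make(self.data - other.data, (self, other),
                            lambda g: (g, -g))

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor._make(self.data * other.data, (self, other),
                            lambda g, a=self.data, b=other.data: (g * b, g * a))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data
        return Tensor._make(a / b, (self, other),
                            lambda g: (g / b, -g * a / (b * b)))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __pow__(self, p: float):
        a = self.data
        return Tensor._make(a ** p, (self,),
                            lambda g: (g * p * a ** (p - 1),))

    def square(self):
        a = self.data
        return Tensor._make(a * a, (self,), lambda g: (2.0 * g * a,))

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor._make(out, (self,), lambda g: (g * 0.5 / out,))

    def exp(self):
        out = np.exp(self.data)
        return Tensor._make(out, (self,), lambda g: (g * out,))

    def log(self):
        a = self.data
        return Tensor._make(np.log(a), (self,), lambda g: (g / a,))

    def arctan(self):
        a = self.data
        return Tensor._make(np.arctan(a), (self,),
                            lambda g: (g / (1.0 + a * a),))

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out, (self,), lambda g: (g * out * (1.0 - out),))

    def silu(self):
        a = self.data
        s = 1.0 / (1.0 + np.exp(-a))
        return Tensor._make(a * s, (self,),
                            lambda g: (g * s * (1.0 + a * (1.0 - s)),))

    def maximum(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data
        mask = a >= b
        return Tensor._make(np.maximum(a, b), (self, other),
                            lambda g: (g * mask, g * ~mask))

    def minimum(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data
        mask = a <= b
        return Tensor._make(np.minimum(a, b), (self, other),
                            lambda g: (g * mask, g * ~mask))

    def clip(self, lo=None, hi=None):
        a = self.data
        mask = np.ones_like(a, dtype=bool)
        if lo is not None:
            mask &= a >= lo
        if hi is not None:
            mask &= a <= hi
        return Tensor._make(np.clip(a, lo, hi), (self,),
                            lambda g: (g * mask,))

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.data.shape),)

        return Tensor._make(out, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims: bool = False):
        out = self.data.max(axis=axis, keepdims=keepdims)

        def backward(g):
            full = out if keepdims or axis is None else np.expand_dims(out, axis)
            gg = g if keepdims or axis is None else np.expand_dims(g, axis)
            mask = self.data == full
            # split gradient between ties, matching the subgradient convention
            norm = mask.sum(axis=axis, keepdims=True) if axis is not None else mask.sum()
            return (gg * mask / norm,)

        return Tensor._make(out, (self,), backward)

    # -- shape manipulation --------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._make(self.data.reshape(shape), (self,),
                            lambda g: (g.reshape(old),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(self.data.transpose(axes), (self,),
                            lambda g: (g.transpose(inv),))

    def __getitem__(self, idx):
        def backward(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._make(self.data[idx], (self,), backward)

    # -- linear algebra -------------------------------------------------
    def matmul(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data

        def backward(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return (ga, gb)

        return Tensor._make(a @ b, (self, other), backward)

    __matmul__ = matmul


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, backward)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def backward(g):
        return tuple(np.moveaxis(g, axis, 0))

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis),
                        tensors, backward)
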