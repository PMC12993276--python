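"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A tape-based scalar-output autodiff engine sufficient for the feed-forward
networks and likelihood losses in this package: dense layers, element-wise
nonlinearities, log-gamma terms of count likelihoods, reductions, and
branching via :func:`where`. Gradients are accumulated on leaf tensors by
calling :meth:`Tensor.backward` on a scalar loss.

Broadcasting follows NumPy semantics; gradients of broadcast operands are
summed back to the operand's shape.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np
from scipy.special import digamma, gammaln

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size-1 in the original shape
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[Array] = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Optional[Callable[[Array], None]] = None

    # -- construction -----------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph ------------------------------------------------------------
    def _make(self, data: Array, parents: tuple["Tensor", ...],
              backward: Callable[[Array], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def backward(self) -> None:
        """Backpropagate from a scalar tensor, accumulating leaf gradients."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            # iterative post-order to avoid recursion limits on deep nets
            stack: list[tuple[Tensor, bool]] = [(t, False)]
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

        visit(self)
        grads: dict[int, Array] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                node._backward_dispatch(g, grads)
            else:
                node.grad = g if node.grad is None else node.grad + g

    def _backward_dispatch(self, g: Array, grads: dict[int, Array]) -> None:
        # _backward fills per-parent grads via closure; we route through a
        # temporary attribute-free protocol: _backward returns list of grads.
        parent_grads = self._backward(g)
        for p, pg in zip(self._parents, parent_grads):
            if not p.requires_grad or pg is None:
                continue
            pg = _unbroadcast(pg, p.data.shape)
            if p._backward is None:
                p.grad = pg if p.grad is None else p.grad + pg
            else:
                key = id(p)
                grads[key] = pg if key not in grads else grads[key] + pg

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)
        return self._make(self.data + other.data, (self, other),
                          lambda g: (g, g))

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = Tensor._lift(other)
        return self._make(self.data - other.data, (self, other),
                          lambda g: (g, -g))

    def __rsub__(self, other):
        return Tensor._lift(other) - self

    def __mul__(self, other):
        other = Tensor._lift(other)
        return self._make(self.data * other.data, (self, other),
                          lambda g: (g * other.data, g * self.data))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        return self._make(
            self.data / other.data, (self, other),
            lambda g: (g / other.data,
                       -g * self.data / (other.data ** 2)))

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        return self._make(self.data ** e, (self,),
                          lambda g: (g * e * self.data ** (e - 1.0),))

    def __matmul__(self, other):
        other = Tensor._lift(other)
        return self._make(self.data @ other.data, (self, other),
                          lambda g: (g @ other.data.T, self.data.T @ g))

    # -- elementwise -------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return self._make(np.log(self.data), (self,),
                          lambda g: (g / self.data,))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(s, (self,), lambda g: (g * s * (1.0 - s),))

    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        expm = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out = np.where(pos, self.data, expm)
        dgrad = np.where(pos, 1.0, expm + alpha)
        return self._make(out, (self,), lambda g: (g * dgrad,))

    def lgamma(self):
        x = self.data
        return self._make(gammaln(x), (self,), lambda g: (g * digamma(x),))

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through the interior."""
        mask = (self.data >= lo) & (self.data <= hi)
        return self._make(np.clip(self.data, lo, hi), (self,),
                          lambda g: (g * mask,))

    # -- reductions / shaping ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.data.shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        orig = self.data.shape
        return self._make(self.data.reshape(*shape), (self,),
                          lambda g: (g.reshape(orig),))

    @property
    def T(self):
        return self._make(self.data.T, (self,), lambda g: (g.T,))


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along `axis` with gradient split back to operands."""
    ts = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out = Tensor(data)
    if any(t.requires_grad for t in ts):
        out.requires_grad = True
        out._parents = tuple(ts)
        out._backward = backward
    return out


def where(cond: Array, a, b) -> Tensor:
    """Elementwise select; `cond` is a constant boolean array."""
    a = Tensor._lift(a)
    b = Tensor._lift(b)
    cond = np.asarray(cond, dtype=bool)
    data = np.where(cond, a.data, b.data)

    def backward(g):
        return (np.where(cond, g, 0.0), np.where(cond, 0.0, g))

    out = Tensor(data)
    if a.requires_grad or b.requires_grad:
        out.requires_grad = True
        out._parents = (a, b)
        out._backward = backward
    return out
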