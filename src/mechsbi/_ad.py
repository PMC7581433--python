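"""Minimal reverse-mode automatic differentiation over numpy arrays.

The conditional density estimators in :mod:`mechsbi.density` need gradients of
scalar losses with respect to network weights, and gradients of log-densities
with respect to their *inputs* (for differentiable posteriors and path
optimization).  This module provides a small tape-based engine that covers
exactly the operations those networks use: elementwise arithmetic with numpy
broadcasting, 2-D matrix products, smooth nonlinearities, reductions, slicing
and concatenation.

It is deliberately tiny: a :class:`Tensor` wraps an ``ndarray`` together with
the closures needed to push gradients back to its parents.  ``backward()`` on
a scalar Tensor runs the tape in reverse topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "concat", "logsumexp"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over broadcast dimensions so it matches `shape`."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


class Tensor:
    __slots__ = ("value", "grad", "_parents", "_bw")

    def __init__(self, value, parents=(), bw=None):
        self.value = np.asarray(value, dtype=float)
        self.grad = None
        self._parents = parents
        self._bw = bw  # callable(out_grad) -> tuple of parent grads

    # -- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    def detach(self) -> "Tensor":
        return Tensor(self.value)

    def backward(self):
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in topo:
            node.grad = None
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._bw is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._bw(node.grad)):
                if g is None:
                    continue
                g = _unbroadcast(g, parent.value.shape)
                parent.grad = g if parent.grad is None else parent.grad + g

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        o = _as_tensor(other)
        return Tensor(self.value + o.value, (self, o), lambda g: (g, g))

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.value, (self,), lambda g: (-g,))

    def __sub__(self, other):
        o = _as_tensor(other)
        return Tensor(self.value - o.value, (self, o), lambda g: (g, -g))

    def __rsub__(self, other):
        return _as_tensor(other) - self

    def __mul__(self, other):
        o = _as_tensor(other)
        return Tensor(self.value * o.value, (self, o),
                      lambda g: (g * o.value, g * self.value))

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = _as_tensor(other)
        return Tensor(self.value / o.value, (self, o),
                      lambda g: (g / o.value, -g * self.value / o.value ** 2))

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __matmul__(self, other):
        o = _as_tensor(other)
        return Tensor(self.value @ o.value, (self, o),
                      lambda g: (g @ o.value.T, self.value.T @ g))

    def __pow__(self, k: float):
        return Tensor(self.value ** k, (self,),
                      lambda g: (g * k * self.value ** (k - 1),))

    def __getitem__(self, idx):
        def bw(g):
            out = np.zeros_like(self.value)
            np.add.at(out, idx, g)
            return (out,)
        return Tensor(self.value[idx], (self,), bw)

    # -- nonlinearities --------------------------------------------------
    def exp(self):
        out = np.exp(self.value)
        return Tensor(out, (self,), lambda g: (g * out,))

    def log(self):
        return Tensor(np.log(self.value), (self,), lambda g: (g / self.value,))

    def tanh(self):
        out = np.tanh(self.value)
        return Tensor(out, (self,), lambda g: (g * (1.0 - out ** 2),))

    def sigmoid(self):
        out = 0.5 * (np.tanh(0.5 * self.value) + 1.0)
        return Tensor(out, (self,), lambda g: (g * out * (1.0 - out),))

    def softplus(self):
        # numerically stable log(1 + e^x)
        out = np.logaddexp(0.0, self.value)
        sig = 0.5 * (np.tanh(0.5 * self.value) + 1.0)
        return Tensor(out, (self,), lambda g: (g * sig,))

    def sqrt(self):
        out = np.sqrt(self.value)
        return Tensor(out, (self,), lambda g: (g * 0.5 / out,))

    # -- reductions / reshaping ------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is None:
                return (np.broadcast_to(g, self.value.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.value.shape).copy(),)
        return Tensor(self.value.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.value.shape
        return Tensor(self.value.reshape(*shape), (self,),
                      lambda g: (g.reshape(old),))


def tensor(value) -> Tensor:
    """Create a leaf tensor (trainable parameter or differentiable input)."""
    return Tensor(np.asarray(value, dtype=float))


def concat(parts: list, axis: int = -1) -> Tensor:
    parts = [_as_tensor(p) for p in parts]
    sizes = [p.value.shape[axis] for p in parts]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate([p.value for p in parts], axis=axis),
                  tuple(parts), bw)


def logsumexp(x: Tensor, axis: int = -1) -> Tensor:
    """Differentiable log-sum-exp along `axis` (max-shifted for stability)."""
    m = np.max(x.value, axis=axis, keepdims=True)
    shifted = x - Tensor(m)  # max treated as a constant shift
    s = shifted.exp().sum(axis=axis).log()
    return s + Tensor(np.squeeze(m, axis=axis))
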