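"""Reverse-mode automatic differentiation over numpy arrays.

A minimal, vectorized autodiff used to train the joint-embedding networks
and to fit the GLM baselines: a :class:`Tensor` wraps a float64 ndarray,
operations build a DAG, and :meth:`Tensor.backward` accumulates gradients by
reverse topological traversal.  Broadcasting follows numpy semantics;
gradients of broadcast operands are summed back to the operand's shape.

The module-level functions (``exp``, ``log``, ``softplus``, ...) dispatch on
their argument: applied to plain ndarrays they compute with numpy/scipy, so
likelihood code written against this module runs identically in evaluation
(pure numpy) and training (graph-building) mode.
"""

from __future__ import annotations

import numpy as np
from scipy import special as sp_special

__all__ = [
    "Tensor",
    "is_tensor",
    "value_of",
    "exp",
    "log",
    "log1p",
    "sqrt",
    "tanh",
    "absolute",
    "sigmoid",
    "softplus",
    "lgamma",
    "logaddexp",
    "relu",
    "maximum_const",
    "matmul",
    "concatenate",
    "sum_",
    "mean_",
    "detach",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("value", "grad", "_parents", "_backward", "name")

    # make ndarray <op> Tensor defer to the reflected Tensor methods instead
    # of numpy broadcasting the Tensor as an object scalar
    __array_ufunc__ = None

    def __init__(self, value, parents=(), backward=None, name=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.name = name

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def detach(self) -> "Tensor":
        """A new leaf tensor sharing this value but cut from the graph."""
        return Tensor(self.value)

    def item(self) -> float:
        return float(self.value)

    def __repr__(self):
        return f"Tensor(shape={self.value.shape}, name={self.name})"

    # ------------------------------------------------------------------
    def backward(self, seed: np.ndarray | None = None) -> None:
        """Accumulate gradients of this (scalar) tensor into the graph leaves."""
        if seed is None:
            if self.value.ndim != 0 and self.value.size != 1:
                raise ValueError("backward() without seed requires a scalar tensor")
            seed = np.ones_like(self.value)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(seed, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.value.shape)
        if self.grad is None:
            self.grad = g
        else:
            self.grad = self.grad + g

    # ------------------------------------------------------------------
    # arithmetic
    def __add__(self, other):
        a, b = self, _wrap(other)
        out = Tensor(a.value + b.value, (a, b))
        out._backward = lambda g: (a._accum(g), b._accum(g))
        return out

    __radd__ = __add__

    def __neg__(self):
        a = self
        out = Tensor(-a.value, (a,))
        out._backward = lambda g: a._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        a, b = self, _wrap(other)
        out = Tensor(a.value * b.value, (a, b))
        out._backward = lambda g: (a._accum(g * b.value), b._accum(g * a.value))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, _wrap(other)
        out = Tensor(a.value / b.value, (a, b))

        def back(g):
            a._accum(g / b.value)
            b._accum(-g * a.value / (b.value ** 2))

        out._backward = back
        return out

    def __rtruediv__(self, other):
        return _wrap(other) / self

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("Tensor ** only supports scalar exponents")
        a = self
        out = Tensor(a.value ** p, (a,))
        out._backward = lambda g: a._accum(g * p * a.value ** (p - 1))
        return out

    def __matmul__(self, other):
        a, b = self, _wrap(other)
        out = Tensor(a.value @ b.value, (a, b))

        def back(g):
            a._accum(g @ b.value.T)
            b._accum(a.value.T @ g)

        out._backward = back
        return out

    def __rmatmul__(self, other):
        return _wrap(other) @ self

    def __getitem__(self, idx):
        a = self
        out = Tensor(a.value[idx], (a,))

        def back(g):
            full = np.zeros_like(a.value)
            np.add.at(full, idx, g)
            a._accum(full)

        out._backward = back
        return out

    # ------------------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self
        out = Tensor(a.value.sum(axis=axis, keepdims=keepdims), (a,))

        def back(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.value.shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g, a.value.shape))

        out._backward = back
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else np.prod(
            [self.value.shape[ax] for ax in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        out = Tensor(a.value.reshape(shape), (a,))
        out._backward = lambda g: a._accum(g.reshape(a.value.shape))
        return out

    @property
    def T(self):
        a = self
        out = Tensor(a.value.T, (a,))
        out._backward = lambda g: a._accum(g.T)
        return out


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def value_of(x) -> np.ndarray:
    """Underlying ndarray of a Tensor, or the argument coerced to ndarray."""
    return x.value if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


def detach(x):
    return x.detach() if isinstance(x, Tensor) else x


# ----------------------------------------------------------------------
# unary elementwise ops: (numpy fn, derivative as fn of input value)
def _unary(x, fn, dfn):
    if isinstance(x, Tensor):
        out = Tensor(fn(x.value), (x,))
        out._backward = lambda g: x._accum(g * dfn(x.value))
        return out
    return fn(np.asarray(x, dtype=np.float64))


def exp(x):
    if isinstance(x, Tensor):
        val = np.exp(x.value)
        out = Tensor(val, (x,))
        out._backward = lambda g: x._accum(g * val)
        return out
    return np.exp(x)


def log(x):
    return _unary(x, np.log, lambda v: 1.0 / v)


def log1p(x):
    return _unary(x, np.log1p, lambda v: 1.0 / (1.0 + v))


def sqrt(x):
    return _unary(x, np.sqrt, lambda v: 0.5 / np.sqrt(v))


def tanh(x):
    if isinstance(x, Tensor):
        val = np.tanh(x.value)
        out = Tensor(val, (x,))
        out._backward = lambda g: x._accum(g * (1.0 - val ** 2))
        return out
    return np.tanh(x)


def absolute(x):
    return _unary(x, np.abs, np.sign)


def sigmoid(x):
    if isinstance(x, Tensor):
        val = sp_special.expit(x.value)
        out = Tensor(val, (x,))
        out._backward = lambda g: x._accum(g * val * (1.0 - val))
        return out
    return sp_special.expit(np.asarray(x, dtype=np.float64))


def softplus(x):
    return _unary(
        x, lambda v: np.logaddexp(0.0, v), lambda v: sp_special.expit(v)
    )


def relu(x):
    return _unary(x, lambda v: np.maximum(v, 0.0), lambda v: (v > 0).astype(float))


def maximum_const(x, c: float):
    """Elementwise max with a constant (subgradient 0 where clipped)."""
    return _unary(x, lambda v: np.maximum(v, c), lambda v: (v > c).astype(float))


def lgamma(x):
    return _unary(x, sp_special.gammaln, sp_special.digamma)


def logaddexp(a, b):
    """Stable log(exp(a) + exp(b)), differentiable through both arguments."""
    if isinstance(a, Tensor) or isinstance(b, Tensor):
        # a + softplus(b - a) is exact and stable for either ordering once we
        # anchor on the larger argument via the identity's symmetry.
        diff = _wrap(b) - _wrap(a)
        return _wrap(a) + softplus(diff)
    return np.logaddexp(a, b)


def matmul(a, b):
    if isinstance(a, Tensor) or isinstance(b, Tensor):
        return _wrap(a) @ _wrap(b)
    return np.asarray(a) @ np.asarray(b)


def concatenate(parts, axis=-1):
    if any(isinstance(p, Tensor) for p in parts):
        parts = [_wrap(p) for p in parts]
        out = Tensor(np.concatenate([p.value for p in parts], axis=axis), tuple(parts))
        sizes = [p.value.shape[axis] for p in parts]
        splits = np.cumsum(sizes)[:-1]

        def back(g):
            for p, piece in zip(parts, np.split(g, splits, axis=axis)):
                p._accum(piece)

        out._backward = back
        return out
    return np.concatenate(parts, axis=axis)


def sum_(x, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        return x.sum(axis=axis, keepdims=keepdims)
    return np.sum(x, axis=axis, keepdims=keepdims)


def mean_(x, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        return x.mean(axis=axis, keepdims=keepdims)
    return np.mean(x, axis=axis, keepdims=keepdims)
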