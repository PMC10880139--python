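"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine sufficient for training the transformer blocks of
this package on CPU: broadcast-aware arithmetic, batched matmul, reductions,
indexing, and fused numerically-stable softmax / log-sum-exp / GELU /
layer-norm primitives.  Everything is float64.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "no_grad",
    "astensor",
    "concat",
    "softmax",
    "logsumexp",
    "gelu",
    "relu",
    "layer_norm",
]

_GRAD_ENABLED = [True]

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


class no_grad:
    """Context manager disabling graph construction (evaluation mode)."""

    def __enter__(self):
        self._prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prev
        return False


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.requires_grad:
            self.grad = g if self.grad is None else self.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            grad = np.ones_like(self.data)
        topo, visited, stack = [], set(), [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -------------------------------------------------------------- arithmetic
    def __add__(self, other):
        a, b = self, astensor(other)

        def bw(g):
            a._accum(_unbroadcast(g, a.data.shape))
            b._accum(_unbroadcast(g, b.data.shape))

        return _make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __mul__(self, other):
        a, b = self, astensor(other)

        def bw(g):
            a._accum(_unbroadcast(g * b.data, a.data.shape))
            b._accum(_unbroadcast(g * a.data, b.data.shape))

        return _make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __neg__(self):
        a = self

        def bw(g):
            a._accum(-g)

        return _make(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __truediv__(self, other):
        a, b = self, astensor(other)

        def bw(g):
            a._accum(_unbroadcast(g / b.data, a.data.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data**2), b.data.shape))

        return _make(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, n):
        if not np.isscalar(n):
            raise TypeError("only scalar exponents are supported")
        a = self

        def bw(g):
            a._accum(g * n * a.data ** (n - 1))

        return _make(a.data**n, (a,), bw)

    def __matmul__(self, other):
        a, b = self, astensor(other)

        def bw(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            a._accum(_unbroadcast(ga, a.data.shape))
            b._accum(_unbroadcast(gb, b.data.shape))

        return _make(a.data @ b.data, (a, b), bw)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bw(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g, a.data.shape).copy())

        return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------------ shape & view
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        orig = a.data.shape

        def bw(g):
            a._accum(g.reshape(orig))

        return _make(a.data.reshape(shape), (a,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = tuple(np.argsort(axes))

        def bw(g):
            a._accum(g.transpose(inv))

        return _make(a.data.transpose(axes), (a,), bw)

    def swapaxes(self, ax1, ax2):
        a = self

        def bw(g):
            a._accum(np.swapaxes(g, ax1, ax2))

        return _make(np.swapaxes(a.data, ax1, ax2), (a,), bw)

    def broadcast_to(self, shape):
        a = self

        def bw(g):
            a._accum(_unbroadcast(g, a.data.shape))

        return _make(np.broadcast_to(a.data, shape).copy(), (a,), bw)

    def __getitem__(self, idx):
        a = self

        def bw(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return _make(a.data[idx], (a,), bw)

    # ---------------------------------------------------------------- pointwise
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            a._accum(g * out_data)

        return _make(out_data, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            a._accum(g / a.data)

        return _make(np.log(a.data), (a,), bw)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def bw(g):
            a._accum(g * 0.5 / out_data)

        return _make(out_data, (a,), bw)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bw(g):
            a._accum(g * (1.0 - out_data**2))

        return _make(out_data, (a,), bw)

    def abs(self):
        a = self

        def bw(g):
            a._accum(g * np.sign(a.data))

        return _make(np.abs(a.data), (a,), bw)


def _make(data, parents, backward) -> Tensor:
    t = Tensor(data)
    if _GRAD_ENABLED[0] and any(p.requires_grad for p in parents):
        t.requires_grad = True
        t._parents = parents
        t._backward = backward
    return t


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ------------------------------------------------------------------ fused ops
def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, offsets, axis=axis)):
            t._accum(piece)

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


def relu(x: Tensor) -> Tensor:
    x = astensor(x)

    def bw(g):
        x._accum(g * (x.data > 0))

    return _make(np.maximum(x.data, 0.0), (x,), bw)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    x = astensor(x)
    cdf = 0.5 * (1.0 + erf(x.data / _SQRT2))

    def bw(g):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x.data**2)
        x._accum(g * (cdf + x.data * pdf))

    return _make(x.data * cdf, (x,), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = astensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        x._accum(y * (g - (g * y).sum(axis=axis, keepdims=True)))

    return _make(y, (x,), bw)


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    x = astensor(x)
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    s = e.sum(axis=axis, keepdims=True)
    out = np.log(s) + m
    if not keepdims:
        out = np.squeeze(out, axis=axis)

    def bw(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        x._accum(g * (e / s))

    return _make(out, (x,), bw)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    x, gamma, beta = astensor(x), astensor(gamma), astensor(beta)
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv

    def bw(g):
        red = tuple(range(g.ndim - 1))
        beta._accum(_unbroadcast(g.sum(axis=red), beta.data.shape))
        gamma._accum(_unbroadcast((g * xhat).sum(axis=red), gamma.data.shape))
        gc = g * gamma.data
        x._accum(
            inv
            * (
                gc
                - gc.mean(axis=-1, keepdims=True)
                - xhat * (gc * xhat).mean(axis=-1, keepdims=True)
            )
        )

    return _make(gamma.data * xhat + beta.data, (x, gamma, beta), bw)
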