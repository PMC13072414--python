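"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine: each :class:`Tensor` wraps an ``ndarray`` and
remembers how to propagate gradients to its parents.  The op set is exactly
what a small vision transformer with contrastive / focal objectives needs
(broadcasted arithmetic, batched matmul, softmax, layer norm, GELU, reductions,
slicing and concatenation).  Gradients are retained on every node that
requires them, so intermediate quantities such as attention matrices can be
inspected after ``backward()`` — a prerequisite for gradient-weighted
attention rollout.

Everything runs in float64 for reproducibility; the models this engine is
meant for are desk-scale.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "cat", "softmax", "layer_norm", "gelu", "dropout"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were 1 in the original shape
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- graph construction helpers ------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _accumulate(self, grad: np.ndarray) -> None:
        # First contribution aliases the incoming array; later ones allocate a
        # fresh sum, so no buffer shared with another node is ever mutated.
        if self.grad is None:
            self.grad = grad
        else:
            self.grad = self.grad + grad

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other ** (-1.0)

    def __rtruediv__(self, other):
        return self._coerce(other) * self ** (-1.0)

    def __pow__(self, exponent: float):
        exponent = float(exponent)
        out = Tensor(self.data**exponent, _parents=(self,))

        def backward(g):
            if self.requires_grad:
                base = self.data
                with np.errstate(divide="ignore", invalid="ignore"):
                    d = exponent * base ** (exponent - 1.0)
                d = np.where(np.isfinite(d), d, 0.0)
                self._accumulate(_unbroadcast(g * d, base.shape))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = backward
        return out

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        value = np.exp(self.data)
        out = Tensor(value, _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * value)

        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = backward
        return out

    def maximum(self, floor: float):
        """Elementwise max with a constant (used for probability clamping / ReLU)."""
        mask = self.data > floor
        out = Tensor(np.where(mask, self.data, floor), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = backward
        return out

    # -- reductions ------------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ---------------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        out._backward = backward
        return out

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = backward
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = backward
        return out

    # -- autodiff driver ---------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


# -- free functions --------------------------------------------------------------


def cat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    value = np.exp(shifted)
    value /= value.sum(axis=axis, keepdims=True)
    out = Tensor(value, _parents=(x,))

    def backward(g):
        if x.requires_grad:
            inner = (g * value).sum(axis=axis, keepdims=True)
            x._accumulate(value * (g - inner))

    out._backward = backward
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    """Layer normalization over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(xhat * gamma.data + beta.data, _parents=(x, gamma, beta))
    n = x.data.shape[-1]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate(_unbroadcast(g * xhat, gamma.data.shape))
        if beta.requires_grad:
            beta._accumulate(_unbroadcast(g, beta.data.shape))
        if x.requires_grad:
            gx = g * gamma.data
            term = gx - gx.mean(axis=-1, keepdims=True) - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            x._accumulate(term * inv)

    out._backward = backward
    return out


_SQRT2 = math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    cdf = 0.5 * (1.0 + erf(x.data / _SQRT2))
    out = Tensor(x.data * cdf, _parents=(x,))

    def backward(g):
        if x.requires_grad:
            pdf = _INV_SQRT2PI * np.exp(-0.5 * x.data**2)
            x._accumulate(g * (cdf + x.data * pdf))

    out._backward = backward
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout: active only in training mode, identity otherwise."""
    if not training or p <= 0.0:
        return x
    keep = rng.random(x.shape) >= p
    return x * (keep.astype(np.float64) / (1.0 - p))
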