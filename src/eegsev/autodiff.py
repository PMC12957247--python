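"""A compact reverse-mode automatic-differentiation engine over numpy.

This provides exactly the operator set the package's neural regressors
need: broadcast arithmetic, (batched) matrix products, GELU/ReLU, axis
reductions, transposes, slicing, and a 1-D convolution / max-pool pair for
the convolutional baseline.  Gradients accumulate on every tensor in the
tape (not only leaves), which is what gradient-based attribution needs to
differentiate a target with respect to an intermediate activation.

All data is float64.  Finite-difference agreement of every operator is
enforced by the test suite.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable

import numpy as np
from scipy.special import erf

Array = np.ndarray

_SQRT2 = math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple["Tensor", ...] = (),
                 _backward: Callable[[Array], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self.grad: Array | None = None
        self._parents = _parents
        self._backward = _backward

    # -- construction helpers ------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accum(self, grad: Array) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def backward(g: Array) -> None:
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def backward(g: Array) -> None:
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) * self**-1.0

    def __pow__(self, exponent: float) -> "Tensor":
        p = float(exponent)
        out = Tensor(self.data**p, _parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1.0))
        return out

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def backward(g: Array) -> None:
            a, b = self.data, other.data
            if b.ndim == 1:  # (..., n) @ (n,) -> (...)
                self._accum(_unbroadcast(g[..., None] * b, self.shape))
                ga = (a * g[..., None]).reshape(-1, b.shape[0]).sum(axis=0)
                other._accum(ga)
            elif a.ndim == 1:  # (n,) @ (n, m) -> (m,)
                self._accum((b * g[None, :]).sum(axis=-1))
                other._accum(np.outer(a, g))
            else:
                self._accum(_unbroadcast(g @ np.swapaxes(b, -1, -2), self.shape))
                other._accum(_unbroadcast(np.swapaxes(a, -1, -2) @ g, other.shape))

        out._backward = backward
        return out

    # -- shape ops -----------------------------------------------------
    def transpose(self, *axes: int) -> "Tensor":
        axes_ = tuple(axes) if axes else tuple(range(self.ndim))[::-1]
        out = Tensor(np.transpose(self.data, axes_), _parents=(self,))
        inv = np.argsort(axes_)
        out._backward = lambda g: self._accum(np.transpose(g, inv))
        return out

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def reshape(self, *shape: int) -> "Tensor":
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.shape))
        return out

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], _parents=(self,))

        def backward(g: Array) -> None:
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accum(full)

        out._backward = backward
        return out

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def backward(g: Array) -> None:
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- nonlinearities ------------------------------------------------
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))
        out._backward = lambda g: self._accum(g * (self.data > 0.0))
        return out

    def gelu(self) -> "Tensor":
        """Exact (erf-based) GELU: x * Phi(x)."""
        cdf = 0.5 * (1.0 + erf(self.data / _SQRT2))
        out = Tensor(self.data * cdf, _parents=(self,))
        pdf = _INV_SQRT2PI * np.exp(-0.5 * self.data**2)
        out._backward = lambda g: self._accum(g * (cdf + self.data * pdf))
        return out

    # -- backprop ------------------------------------------------------
    def backward(self, grad: Array | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor, padding: int = 0) -> Tensor:
    """1-D convolution (cross-correlation), stride 1.

    ``x``: (B, C_in, L); ``weight``: (C_out, C_in, K); ``bias``: (C_out,).
    """
    xb, w, b = x.data, weight.data, bias.data
    if padding:
        xp = np.pad(xb, ((0, 0), (0, 0), (padding, padding)))
    else:
        xp = xb
    B, Cin, Lp = xp.shape
    Cout, _, K = w.shape
    Lout = Lp - K + 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)  # (B,Cin,Lout,K)
    out_data = np.einsum("bilk,oik->bol", windows, w, optimize=True) + b[None, :, None]
    out = Tensor(out_data, _parents=(x, weight, bias))

    def backward(g: Array) -> None:
        weight._accum(np.einsum("bol,bilk->oik", g, windows, optimize=True))
        bias._accum(g.sum(axis=(0, 2)))
        gx = np.zeros_like(xp)
        # scatter: gx[b, i, l+k] += g[b, o, l] * w[o, i, k]
        contrib = np.einsum("bol,oik->bilk", g, w, optimize=True)
        for k in range(K):
            gx[:, :, k:k + Lout] += contrib[:, :, :, k]
        if padding:
            gx = gx[:, :, padding:-padding]
        x._accum(gx)

    out._backward = backward
    return out


def maxpool1d(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping 1-D max pooling over the last axis (truncates remainder)."""
    B, C, L = x.data.shape
    Lout = L // size
    view = x.data[:, :, : Lout * size].reshape(B, C, Lout, size)
    idx = view.argmax(axis=-1)
    out = Tensor(view.max(axis=-1), _parents=(x,))

    def backward(g: Array) -> None:
        gx = np.zeros_like(x.data)
        gview = gx[:, :, : Lout * size].reshape(B, C, Lout, size)
        bb, cc, ll = np.meshgrid(np.arange(B), np.arange(C), np.arange(Lout),
                                 indexing="ij")
        gview[bb, cc, ll, idx] += g
        x._accum(gx)

    out._backward = backward
    return out


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adam optimizer over a list of :class:`Parameter`."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

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
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
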