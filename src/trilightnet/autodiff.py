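"""Reverse-mode automatic differentiation over NumPy arrays.

This is the numerical core of the package: a small define-by-run tape
holding exactly the operations the network needs (dense linear algebra,
3-D convolution and pooling, smooth activations, softmax) together with
their adjoints.  Arrays are plain ``numpy.ndarray``; a :class:`Tensor`
wraps one array plus an optional gradient and the closure that
backpropagates through the operation that produced it.

Gradient correctness is established by finite-difference checks in the
test suite; convolution adjoints are implemented with the
transposed-convolution offset trick so no quadratic im2col buffer is
needed on the backward pass.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = [
    "Tensor",
    "no_grad",
    "flop_counter",
    "concatenate",
    "conv3d",
    "maxpool3d",
    "softmax",
    "sigmoid",
    "relu",
    "silu",
    "gelu",
    "exp",
    "log",
    "sqrt",
    "clip",
]

_GRAD_ENABLED = True
_FLOPS: list | None = None  # single-element list while counting


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (evaluation-mode forward passes)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


@contextlib.contextmanager
def flop_counter():
    """Count floating-point operations (2 x multiply-accumulates) of every
    matrix product and convolution executed inside the block."""
    global _FLOPS
    prev = _FLOPS
    _FLOPS = [0]
    try:
        yield _FLOPS
    finally:
        _FLOPS = prev


def _count_macs(macs: int) -> None:
    if _FLOPS is not None:
        _FLOPS[0] += 2 * int(macs)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
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
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward: Callable | None = None

    # -- graph plumbing ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
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
                if p._parents or p.requires_grad:
                    stack.append((p, False))
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if g is None:
                    continue
                if not (parent.requires_grad or parent._parents):
                    continue
                g = np.asarray(g, dtype=parent.data.dtype)
                parent.grad = g if parent.grad is None else parent.grad + g

    # -- operators -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_ensure(other))

    def __rsub__(self, other):
        return add(_ensure(other), -self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(_ensure(other), self)

    def __pow__(self, exponent):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return getitem(self, key)

    def reshape(self, *shape):
        return reshape(self, *shape)

    def transpose(self, *axes):
        return transpose(self, axes if axes else None)

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return reduce_mean(self, axis, keepdims)

    def max(self, axis=None, keepdims=False):
        return reduce_max(self, axis, keepdims)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _ensure(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _node(data: np.ndarray, parents: Sequence[Tensor], backward: Callable) -> Tensor:
    track = _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents)
    out = Tensor(data, requires_grad=False)
    if track:
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = any(p.requires_grad for p in parents)
    return out


# ---------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    return _node(
        a.data + b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)),
    )


def mul(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    return _node(
        a.data * b.data,
        (a, b),
        lambda g: (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        ),
    )


def div(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    return _node(
        a.data / b.data,
        (a, b),
        lambda g: (
            _unbroadcast(g / b.data, a.data.shape),
            _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape),
        ),
    )


def power(a, exponent: float) -> Tensor:
    a = _ensure(a)
    e = float(exponent)
    out = a.data**e
    return _node(out, (a,), lambda g: (g * e * a.data ** (e - 1.0),))


def exp(a) -> Tensor:
    a = _ensure(a)
    out = np.exp(a.data)
    return _node(out, (a,), lambda g: (g * out,))


def log(a) -> Tensor:
    a = _ensure(a)
    return _node(np.log(a.data), (a,), lambda g: (g / a.data,))


def sqrt(a) -> Tensor:
    a = _ensure(a)
    out = np.sqrt(a.data)
    return _node(out, (a,), lambda g: (g * (0.5 / out),))


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp with straight-through gradient strictly inside the bounds."""
    a = _ensure(a)
    out = np.clip(a.data, lo, hi)
    mask = (a.data >= lo) & (a.data <= hi)
    return _node(out, (a,), lambda g: (g * mask,))


# ---------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------

def sigmoid(a) -> Tensor:
    a = _ensure(a)
    out = 1.0 / (1.0 + np.exp(-a.data))
    return _node(out, (a,), lambda g: (g * out * (1.0 - out),))


def relu(a) -> Tensor:
    a = _ensure(a)
    mask = a.data > 0
    return _node(a.data * mask, (a,), lambda g: (g * mask,))


def silu(a) -> Tensor:
    """x * sigmoid(x) (the SiLU / swish activation)."""
    a = _ensure(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    return _node(a.data * s, (a,), lambda g: (g * s * (1.0 + a.data * (1.0 - s)),))


def gelu(a) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    a = _ensure(a)
    x = a.data
    cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
    pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
    return _node(x * cdf, (a,), lambda g: (g * (cdf + x * pdf),))


def softmax(a, axis: int = -1) -> Tensor:
    """Numerically stable softmax (max-subtraction) along ``axis``."""
    a = _ensure(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    out = ez / ez.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        return (out * (g - dot),)

    return _node(out, (a,), backward)


# ---------------------------------------------------------------------
# shape manipulation
# ---------------------------------------------------------------------

def reshape(a, *shape) -> Tensor:
    a = _ensure(a)
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])
    orig = a.data.shape
    return _node(a.data.reshape(shape), (a,), lambda g: (g.reshape(orig),))


def transpose(a, axes=None) -> Tensor:
    a = _ensure(a)
    if axes is None:
        axes = tuple(reversed(range(a.data.ndim)))
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return _node(a.data.transpose(axes), (a,), lambda g: (g.transpose(inv),))


def getitem(a, key) -> Tensor:
    a = _ensure(a)

    def backward(g):
        out = np.zeros_like(a.data)
        np.add.at(out, key, g)
        return (out,)

    return _node(a.data[key], (a,), backward)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_ensure(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        sl = [slice(None)] * g.ndim
        grads = []
        for i in range(len(tensors)):
            sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            grads.append(g[tuple(sl)])
        return tuple(grads)

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


# ---------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------

def _norm_axis(axis, ndim):
    if axis is None:
        return tuple(range(ndim))
    if isinstance(axis, int):
        return (axis % ndim,)
    return tuple(a % ndim for a in axis)


def reduce_sum(a, axis=None, keepdims=False) -> Tensor:
    a = _ensure(a)
    axes = _norm_axis(axis, a.data.ndim)
    out = a.data.sum(axis=axes, keepdims=keepdims)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        return (np.broadcast_to(g, a.data.shape),)

    return _node(out, (a,), backward)


def reduce_mean(a, axis=None, keepdims=False) -> Tensor:
    a = _ensure(a)
    axes = _norm_axis(axis, a.data.ndim)
    n = float(np.prod([a.data.shape[ax] for ax in axes]))
    out = a.data.mean(axis=axes, keepdims=keepdims)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        return (np.broadcast_to(g / n, a.data.shape),)

    return _node(out, (a,), backward)


def reduce_max(a, axis=None, keepdims=False) -> Tensor:
    a = _ensure(a)
    axes = _norm_axis(axis, a.data.ndim)
    out = a.data.max(axis=axes, keepdims=True)
    mask = a.data == out
    counts = mask.sum(axis=axes, keepdims=True)
    result = out if keepdims else out.squeeze(axes)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        return (mask * (g / counts),)

    return _node(result, (a,), backward)


# ---------------------------------------------------------------------
# linear algebra
# ---------------------------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = _ensure(a), _ensure(b)
    out = a.data @ b.data
    _count_macs(out.size * a.data.shape[-1])

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return (_unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape))

    return _node(out, (a, b), backward)


# ---------------------------------------------------------------------
# 3-D convolution and pooling
# ---------------------------------------------------------------------

def _triple(v):
    return (v, v, v) if isinstance(v, int) else tuple(v)


def conv3d(x, w, b=None, stride=1, padding=0) -> Tensor:
    """3-D cross-correlation of ``x`` [B, Cin, D, H, W] with kernels
    ``w`` [Cout, Cin, kd, kh, kw]; optional bias per output channel."""
    x, w = _ensure(x), _ensure(w)
    bias = _ensure(b) if b is not None else None
    sd, sh, sw = _triple(stride)
    pd, ph, pw = _triple(padding)
    B, Cin, D, H, W = x.data.shape
    Cout, Cin_w, kd, kh, kw = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"conv3d: channel mismatch {Cin} vs {Cin_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
    if xp.shape[2] < kd or xp.shape[3] < kh or xp.shape[4] < kw:
        raise ValueError("conv3d: input smaller than kernel")
    win = sliding_window_view(xp, (kd, kh, kw), axis=(2, 3, 4))[:, :, ::sd, ::sh, ::sw]
    Do, Ho, Wo = win.shape[2:5]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
        B * Do * Ho * Wo, Cin * kd * kh * kw
    )
    wm = w.data.reshape(Cout, -1)
    out = cols @ wm.T
    _count_macs(out.size * wm.shape[1])
    out = out.reshape(B, Do, Ho, Wo, Cout).transpose(0, 4, 1, 2, 3)
    if bias is not None:
        out = out + bias.data.reshape(1, -1, 1, 1, 1)

    def backward(g):
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(-1, Cout)
        gw = (gm.T @ cols).reshape(w.data.shape)
        gb = g.sum(axis=(0, 2, 3, 4)) if bias is not None else None
        gx = None
        if x.requires_grad or x._parents:
            # transposed convolution by looping over kernel offsets:
            # memory-light and exact for any stride/padding
            gxp = np.zeros_like(xp)
            for i in range(kd):
                for j in range(kh):
                    for l in range(kw):
                        contrib = np.tensordot(g, w.data[:, :, i, j, l], axes=([1], [0]))
                        # contrib: [B, Do, Ho, Wo, Cin] -> [B, Cin, Do, Ho, Wo]
                        gxp[
                            :,
                            :,
                            i : i + sd * Do : sd,
                            j : j + sh * Ho : sh,
                            l : l + sw * Wo : sw,
                        ] += contrib.transpose(0, 4, 1, 2, 3)
            gx = gxp[:, :, pd : pd + D, ph : ph + H, pw : pw + W]
        if bias is not None:
            return (gx, gw, gb)
        return (gx, gw)

    parents = (x, w) if bias is None else (x, w, bias)
    return _node(out, parents, backward)


def maxpool3d(x, kernel=3, stride=2, padding=1) -> Tensor:
    """Max pooling over [B, C, D, H, W] with -inf padding."""
    x = _ensure(x)
    kd, kh, kw = _triple(kernel)
    sd, sh, sw = _triple(stride)
    pd, ph, pw = _triple(padding)
    B, C, D, H, W = x.data.shape
    neg = np.array(-np.inf, dtype=x.data.dtype)
    xp = np.pad(
        x.data,
        ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)),
        constant_values=neg,
    )
    win = sliding_window_view(xp, (kd, kh, kw), axis=(2, 3, 4))[:, :, ::sd, ::sh, ::sw]
    out = win.max(axis=(5, 6, 7))
    Do, Ho, Wo = out.shape[2:]

    def backward(g):
        mask = win == out[..., None, None, None]
        counts = mask.sum(axis=(5, 6, 7), keepdims=True)
        share = mask * (g[..., None, None, None] / counts)
        gxp = np.zeros_like(xp)
        for i in range(kd):
            for j in range(kh):
                for l in range(kw):
                    gxp[
                        :,
                        :,
                        i : i + sd * Do : sd,
                        j : j + sh * Ho : sh,
                        l : l + sw * Wo : sw,
                    ] += share[..., i, j, l]
        return (gxp[:, :, pd : pd + D, ph : ph + H, pw : pw + W],)

    return _node(out, (x,), backward)
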