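"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the tape in reverse topological order and
accumulates gradients.  The primitive set is exactly what the fusion network
needs: broadcasted arithmetic, (batched) matmul, reshape/transpose/slicing,
concatenation, elementwise nonlinearities, axis reductions, and im2col
lowering for 1-D/2-D convolution.  float32 is the working dtype; float64
inputs are kept as-is so finite-difference gradient checks stay precise.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "tensor", "add", "mul", "matmul", "exp", "log", "power",
    "sigmoid", "relu", "leaky_relu", "reduce_sum", "reduce_mean",
    "reduce_max", "reshape", "transpose", "getitem", "concat",
    "im2col1d", "im2col2d", "softmax", "log_softmax",
]


def _as_array(x):
    a = np.asarray(x)
    if not np.issubdtype(a.dtype, np.floating):
        a = a.astype(np.float32)
    return a


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph -------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self):
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        return add(_wrap(other), -self)

    def __truediv__(self, other):
        return mul(self, power(_wrap(other), -1.0))

    def __rtruediv__(self, other):
        return mul(_wrap(other), power(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if axes else None)

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return reduce_mean(self, axis, keepdims)

    def max(self, axis=None, keepdims=False):
        return reduce_max(self, axis, keepdims)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def tensor(data, requires_grad=False):
    return Tensor(data, requires_grad=requires_grad)


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward):
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _unbroadcast(g, shape):
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, s) in enumerate(zip(g.shape, shape)):
        if s == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# -- arithmetic ------------------------------------------------------------

def add(a, b):
    a, b = _wrap(a), _wrap(b)
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _make(data, (a, b), backward)


def mul(a, b):
    a, b = _wrap(a), _wrap(b)
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(data, (a, b), backward)


def matmul(a, b):
    """Matrix product with numpy's stacked-batch broadcasting (inputs >= 2-D)."""
    a, b = _wrap(a), _wrap(b)
    data = np.matmul(a.data, b.data)

    def backward(g):
        if a.requires_grad:
            if a.ndim == 2 and g.ndim == 3:
                # broadcast weight: contract batch and position axes in one gemm
                i, k = a.shape
                ga = np.matmul(g.transpose(1, 0, 2).reshape(i, -1),
                               b.data.transpose(0, 2, 1).reshape(-1, k))
                a._accumulate(ga)
            else:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            if b.ndim == 2 and g.ndim == 3:
                k, n = b.shape
                gb = np.matmul(a.data.reshape(-1, k).T, g.reshape(-1, n))
                b._accumulate(gb)
            else:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accumulate(_unbroadcast(gb, b.shape))

    return _make(data, (a, b), backward)


def power(a, p):
    a = _wrap(a)
    data = a.data ** p

    def backward(g):
        a._accumulate(g * p * a.data ** (p - 1))

    return _make(data, (a,), backward)


def exp(a):
    a = _wrap(a)
    data = np.exp(a.data)

    def backward(g):
        a._accumulate(g * data)

    return _make(data, (a,), backward)


def log(a):
    a = _wrap(a)
    data = np.log(a.data)

    def backward(g):
        a._accumulate(g / a.data)

    return _make(data, (a,), backward)


def sigmoid(a):
    a = _wrap(a)
    data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accumulate(g * data * (1.0 - data))

    return _make(data, (a,), backward)


def relu(a):
    a = _wrap(a)
    mask = a.data > 0
    data = a.data * mask

    def backward(g):
        a._accumulate(g * mask)

    return _make(data, (a,), backward)


def leaky_relu(a, slope=0.01):
    a = _wrap(a)
    mask = a.data > 0
    data = np.where(mask, a.data, slope * a.data)

    def backward(g):
        a._accumulate(g * np.where(mask, 1.0, slope))

    return _make(data, (a,), backward)


# -- reductions ------------------------------------------------------------

def reduce_sum(a, axis=None, keepdims=False):
    a = _wrap(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.shape).copy())

    return _make(data, (a,), backward)


def reduce_mean(a, axis=None, keepdims=False):
    a = _wrap(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[i] for i in np.atleast_1d(axis)])
    return mul(reduce_sum(a, axis, keepdims), 1.0 / float(n))


def reduce_max(a, axis=None, keepdims=False):
    a = _wrap(a)
    data = a.data.max(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        full = data
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
            full = np.expand_dims(data, axis)
        mask = (a.data == full)
        counts = mask.sum(axis=axis, keepdims=True)
        a._accumulate(mask * (g / counts))

    return _make(data, (a,), backward)


# -- shape ops -------------------------------------------------------------

def reshape(a, shape):
    a = _wrap(a)
    data = a.data.reshape(shape)
    orig = a.shape

    def backward(g):
        a._accumulate(g.reshape(orig))

    return _make(data, (a,), backward)


def transpose(a, axes=None):
    a = _wrap(a)
    data = a.data.transpose(axes)
    inv = None if axes is None else np.argsort(axes)

    def backward(g):
        a._accumulate(g.transpose(inv))

    return _make(data, (a,), backward)


def getitem(a, idx):
    a = _wrap(a)
    data = a.data[idx]

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        a._accumulate(full)

    return _make(data, (a,), backward)


def concat(tensors, axis=0):
    tensors = [_wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return _make(data, tuple(tensors), backward)


# -- convolution lowering --------------------------------------------------

def im2col1d(a, kernel, stride=1, pad=0):
    """(B, C, L) -> (B, C*kernel, L_out) patch matrix."""
    a = _wrap(a)
    B, C, L = a.shape
    xp = np.pad(a.data, ((0, 0), (0, 0), (pad, pad)))
    Lo = (L + 2 * pad - kernel) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=2)
    win = win[:, :, ::stride, :]                       # (B, C, Lo, k)
    data = win.transpose(0, 1, 3, 2).reshape(B, C * kernel, Lo)

    def backward(g):
        g = g.reshape(B, C, kernel, Lo)
        gx = np.zeros_like(xp)
        for i in range(kernel):
            gx[:, :, i:i + stride * Lo:stride] += g[:, :, i, :]
        if pad:
            gx = gx[:, :, pad:-pad]
        a._accumulate(gx)

    return _make(data, (a,), backward)


def im2col2d(a, kernel, stride=1, pad=0):
    """(B, C, H, W) -> (B, C*kh*kw, Ho*Wo) patch matrix."""
    a = _wrap(a)
    kh, kw = (kernel, kernel) if np.isscalar(kernel) else kernel
    B, C, H, W = a.shape
    xp = np.pad(a.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Ho = (H + 2 * pad - kh) // stride + 1
    Wo = (W + 2 * pad - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, :, :]          # (B, C, Ho, Wo, kh, kw)
    data = win.transpose(0, 1, 4, 5, 2, 3).reshape(B, C * kh * kw, Ho * Wo)

    def backward(g):
        g = g.reshape(B, C, kh, kw, Ho, Wo)
        gx = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gx[:, :, i:i + stride * Ho:stride,
                   j:j + stride * Wo:stride] += g[:, :, i, j]
        if pad:
            gx = gx[:, :, pad:-pad, pad:-pad]
        a._accumulate(gx)

    return _make(data, (a,), backward)


# -- composed --------------------------------------------------------------

def softmax(a, axis=-1):
    a = _wrap(a)
    shift = Tensor(a.data.max(axis=axis, keepdims=True))  # constant for stability
    e = exp(a - shift)
    return e / reduce_sum(e, axis=axis, keepdims=True)


def log_softmax(a, axis=-1):
    a = _wrap(a)
    shift = Tensor(a.data.max(axis=axis, keepdims=True))
    z = a - shift
    return z - log(reduce_sum(exp(z), axis=axis, keepdims=True))
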