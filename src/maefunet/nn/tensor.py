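"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine: a :class:`Tensor` wraps an ``ndarray`` and
records the closure needed to push gradients back to its parents.  All
arithmetic supports numpy broadcasting; gradients of broadcast operands are
summed back to the operand's shape.  Float64 throughout — determinism and
gradient-check fidelity matter more here than speed.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "gather_tokens",
    "matmul",
    "maxpool2x2",
    "resize_nearest",
    "scatter_tokens",
    "stack",
    "upsample2x2",
]


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float64, copy=False)
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            pending = [p for p in node._parents if id(p) not in seen]
            if pending:
                stack.extend(pending)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        self.grad = np.ones_like(self.data) if grad is None else _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        req = any(p.requires_grad or p._backward is not None for p in parents)
        out = Tensor(data)
        if req:
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            self_accum(g)
            other_accum(g)

        self_accum = lambda g: self._accumulate(_unbroadcast(g, self.shape))
        other_accum = lambda g: other._accumulate(_unbroadcast(g, other.shape))
        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: self._accumulate(-g))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            self._accumulate(_unbroadcast(g / other.data, self.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / (other.data**2), other.shape)
            )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        def backward(g):
            self._accumulate(g * p * self.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), backward)

    # -- elementwise functions --------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accumulate(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accumulate(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def gelu(self):
        """Gaussian error linear unit (tanh approximation)."""
        x = self.data
        c = np.sqrt(2.0 / np.pi)
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        out_data = 0.5 * x * (1.0 + t)

        def backward(g):
            dinner = c * (1.0 + 3 * 0.044715 * x**2)
            dt = (1.0 - t**2) * dinner
            self._accumulate(g * (0.5 * (1.0 + t) + 0.5 * x * dt))

        return Tensor._make(out_data, (self,), backward)

    def clip(self, lo: float, hi: float):
        mask = (self.data >= lo) & (self.data <= hi)

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions & shape ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g):
            self._accumulate(g.reshape(self.shape))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            buf = np.zeros_like(self.data)
            np.add.at(buf, idx, g)
            self._accumulate(buf)

        return Tensor._make(self.data[idx], (self,), backward)

    # -- composites ---------------------------------------------------------
    def softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def logsumexp(self, axis: int = -1, keepdims: bool = False):
        m = Tensor(self.data.max(axis=axis, keepdims=True))
        out = (self - m).exp().sum(axis=axis, keepdims=True).log() + m
        if not keepdims:
            out = out.reshape(tuple(s for i, s in enumerate(self.shape) if i != axis % self.ndim))
        return out

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


# -- multi-argument ops -----------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product with broadcasting over leading axes."""

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        a._accumulate(_unbroadcast(ga, a.shape))
        b._accumulate(_unbroadcast(gb, b.shape))

    return Tensor._make(np.matmul(a.data, b.data), (a, b), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    def backward(g):
        for i, t in enumerate(tensors):
            t._accumulate(np.take(g, i, axis=axis))

    return Tensor._make(
        np.stack([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def gather_tokens(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select tokens per batch element: (B, N, D), (B, K) -> (B, K, D)."""
    batch = np.arange(x.shape[0])[:, None]

    def backward(g):
        buf = np.zeros_like(x.data)
        np.add.at(buf, (batch, idx), g)
        x._accumulate(buf)

    return Tensor._make(x.data[batch, idx], (x,), backward)


def scatter_tokens(x: Tensor, idx: np.ndarray, n_total: int) -> Tensor:
    """Inverse of :func:`gather_tokens`: place (B, K, D) at idx in (B, N, D)."""
    batch = np.arange(x.shape[0])[:, None]
    out_data = np.zeros((x.shape[0], n_total, x.shape[2]))
    out_data[batch, idx] = x.data

    def backward(g):
        x._accumulate(g[batch, idx])

    return Tensor._make(out_data, (x,), backward)


def _im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh, ow = h + 2 * pad - kh + 1, w + 2 * pad - kw + 1
    s = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp, (b, c, kh, kw, oh, ow), (s[0], s[1], s[2], s[3], s[2], s[3])
    )
    return cols.reshape(b, c * kh * kw, oh * ow)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, pad: int = 1) -> Tensor:
    """2D convolution, stride 1, NCHW; weight (Cout, Cin, kh, kw)."""
    co, ci, kh, kw = weight.shape
    b, c, h, w = x.shape
    oh, ow = h + 2 * pad - kh + 1, w + 2 * pad - kw + 1
    cols = _im2col(x.data, kh, kw, pad)  # (B, C*kh*kw, OH*OW)
    wmat = weight.data.reshape(co, ci * kh * kw)
    out_data = np.matmul(wmat, cols).reshape(b, co, oh, ow)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]

    def backward(g):
        gmat = g.reshape(b, co, oh * ow)
        gw = np.matmul(
            gmat.transpose(1, 0, 2).reshape(co, b * oh * ow),
            cols.transpose(0, 2, 1).reshape(b * oh * ow, ci * kh * kw),
        )
        weight._accumulate(gw.reshape(weight.shape))
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        gcols = np.matmul(wmat.T[None], gmat)  # (B, C*kh*kw, OH*OW)
        gcols = gcols.reshape(b, ci, kh, kw, oh, ow)
        gx = np.zeros((b, ci, h + 2 * pad, w + 2 * pad))
        for i in range(kh):
            for j in range(kw):
                gx[:, :, i : i + oh, j : j + ow] += gcols[:, :, i, j]
        if pad:
            gx = gx[:, :, pad:-pad, pad:-pad]
        x._accumulate(gx)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out_data, parents, backward)


def maxpool2x2(x: Tensor) -> Tensor:
    b, c, h, w = x.shape
    xr = x.data.reshape(b, c, h // 2, 2, w // 2, 2)
    flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h // 2, w // 2, 4)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, arg[..., None], g[..., None], axis=-1)
        gx = gflat.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(gx.reshape(b, c, h, w))

    return Tensor._make(out_data, (x,), backward)


def upsample2x2(x: Tensor) -> Tensor:
    def backward(g):
        b, c, h2, w2 = g.shape
        gx = g.reshape(b, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
        x._accumulate(gx)

    return Tensor._make(
        x.data.repeat(2, axis=2).repeat(2, axis=3), (x,), backward
    )


def resize_nearest(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Nearest-neighbour spatial resize of an NCHW map to (out_h, out_w)."""
    b, c, h, w = x.shape
    if (h, w) == (out_h, out_w):
        return x
    rows = np.minimum((np.arange(out_h) * h // out_h), h - 1)
    cols = np.minimum((np.arange(out_w) * w // out_w), w - 1)

    def backward(g):
        buf = np.zeros_like(x.data)
        np.add.at(buf, (slice(None), slice(None), rows[:, None], cols[None, :]), g)
        x._accumulate(buf)

    return Tensor._make(x.data[:, :, rows[:, None], cols[None, :]], (x,), backward)
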