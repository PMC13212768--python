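"""Tape-based reverse-mode autodiff over NumPy arrays."""

from __future__ import annotations

import contextlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED[-1]
        self._backward = None
        self._parents: tuple = ()

    # -- helpers -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad):
        if self.grad is None:
            # copy: upstream buffers may be shared across consumers
            self.grad = np.array(grad, dtype=np.float64)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(
                    self.grad, self.data.shape).copy()
        else:
            self.grad += grad

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return self._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), bw)

    def __matmul__(self, other):
        other = self._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bw)

    # -- elementwise -------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self._accum(np.where(mask, g, 0.0))

        return self._make(np.maximum(self.data, 0.0), (self,), bw)

    def abs(self):
        sign = np.sign(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * sign)

        return self._make(np.abs(self.data), (self,), bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), bw)

    def sqrt(self):
        return self ** 0.5

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, key):
        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accum(full)

        return self._make(self.data[key], (self,), bw)

    @staticmethod
    def concat(tensors, axis=0):
        tensors = [Tensor._lift(t) for t in tensors]
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            parts = np.split(g, splits, axis=axis)
            for t, p in zip(tensors, parts):
                if t.requires_grad:
                    t._accum(p)

        data = np.concatenate([t.data for t in tensors], axis=axis)
        out = tensors[0]._make(data, tuple(tensors), bw)
        return out

    # -- structured ops ----------------------------------------------------
    def pad_hw(self, pad_h: int, pad_w: int, mode_h: str = "reflect",
               mode_w: str = "wrap"):
        """Pad the last two axes by index mapping ('reflect' or 'wrap').
        Gradient accumulates back through the map."""
        x = self

        def axis_index(n, p, mode):
            if p == 0:
                return np.arange(n)
            if mode == "wrap":
                return np.arange(-p, n + p) % n
            if mode == "reflect":
                return np.pad(np.arange(n), (p, p), mode="reflect")
            raise ValueError(f"unknown pad mode {mode!r}")

        ih = axis_index(x.shape[-2], pad_h, mode_h)
        iw = axis_index(x.shape[-1], pad_w, mode_w)
        data = x.data[..., ih[:, None], iw[None, :]]

        def bw(g):
            if x.requires_grad:
                grad = np.zeros_like(x.data)
                np.add.at(grad, (..., ih[:, None], iw[None, :]), g)
                x._accum(grad)

        return x._make(data, (x,), bw)

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1):
        """Valid-mode 2D convolution.  ``self``: (N, C, H, W); ``weight``:
        (O, C, kH, kW).  Pad beforehand with :meth:`pad_hw`."""
        x, w = self, weight
        kh, kw = w.shape[2], w.shape[3]
        win = sliding_window_view(x.data, (kh, kw), axis=(2, 3))
        win = win[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, kh, kw)
        out = np.einsum("nchwij,ocij->nohw", win, w.data, optimize=True)
        if bias is not None:
            out = out + bias.data[None, :, None, None]
        n, _, ho, wo = out.shape

        def bw(g):
            if w.requires_grad:
                w._accum(np.einsum("nchwij,nohw->ocij", win, g, optimize=True))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gx = np.zeros_like(x.data)
                gw = np.einsum("nohw,ocij->nchwij", g, w.data, optimize=True)
                for ki in range(kh):
                    for kj in range(kw):
                        gx[:, :, ki:ki + stride * ho:stride,
                           kj:kj + stride * wo:stride] += gw[:, :, :, :, ki, kj]
                x._accum(gx)

        parents = (x, w) if bias is None else (x, w, bias)
        return x._make(out, parents, bw)

    def conv_transpose2x2(self, weight: "Tensor", bias: "Tensor | None" = None):
        """Transpose convolution with 2x2 kernel and stride 2 (exact 2x
        upsampling, non-overlapping).  ``self``: (N, C, H, W); ``weight``:
        (C, O, 2, 2) -> output (N, O, 2H, 2W)."""
        x, w = self, weight
        n, c, h, wd = x.shape
        o = w.shape[1]
        y6 = np.einsum("nchw,coij->nohiwj", x.data, w.data, optimize=True)
        out = y6.reshape(n, o, 2 * h, 2 * wd)
        if bias is not None:
            out = out + bias.data[None, :, None, None]

        def bw(g):
            g6 = g.reshape(n, o, h, 2, wd, 2)
            if w.requires_grad:
                w._accum(np.einsum("nchw,nohiwj->coij", x.data, g6,
                                   optimize=True))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                x._accum(np.einsum("nohiwj,coij->nchw", g6, w.data,
                                   optimize=True))

        parents = (x, w) if bias is None else (x, w, bias)
        return x._make(out, parents, bw)

    def maxpool2x2(self):
        """2x2 max pooling with stride 2; H and W must be even."""
        x = self
        n, c, h, w = x.shape
        xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
        xf = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        arg = xf.argmax(axis=-1)
        out = np.take_along_axis(xf, arg[..., None], axis=-1)[..., 0]

        def bw(g):
            if not x.requires_grad:
                return
            gf = np.zeros_like(xf)
            np.put_along_axis(gf, arg[..., None], g[..., None], axis=-1)
            gx = gf.reshape(n, c, h // 2, w // 2, 2, 2).transpose(
                0, 1, 2, 4, 3, 5
            ).reshape(n, c, h, w)
            x._accum(gx)

        return x._make(out, (x,), bw)

    def spmm(self, a_csr):
        """``A @ x`` for a fixed scipy sparse matrix A; grad is ``A.T @ g``."""
        x = self
        at = a_csr.T.tocsr()

        def bw(g):
            if x.requires_grad:
                x._accum(at @ g)

        return x._make(a_csr @ x.data, (x,), bw)
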