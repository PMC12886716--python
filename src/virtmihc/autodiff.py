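"""Minimal reverse-mode automatic differentiation on numpy arrays.

The training objectives couple three convolutional networks through a
differentiable image warp, so gradients must flow through convolutions,
pooling, bilinear resampling and the warp itself.  This module provides a
small tape-based engine with exactly the operators those networks need.
All operators are vectorised numpy; there is no compilation step, and the
same code path runs in float32 (training) or float64 (gradient checks).

Conventions: image tensors are NCHW; displacement fields are (N, 2, H, W)
with component 0 = row offset (dy) and component 1 = column offset (dx),
in pixel units, gather semantics (output samples input at x + T(x)).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "where", "grid_sample"]


def _as_array(x, dtype=None):
    a = np.asarray(x)
    if dtype is not None and a.dtype != dtype:
        a = a.astype(dtype)
    if a.dtype == np.float16 or not np.issubdtype(a.dtype, np.floating):
        a = a.astype(np.float64)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        """Reverse-mode sweep from this (scalar or tensor) node."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out.requires_grad = any(p.requires_grad for p in parents)
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def __add__(self, other):
        o = Tensor._lift(other)

        def back(g):
            self._accumulate(_unbroadcast(g, self.shape))
            o._accumulate(_unbroadcast(g, o.shape))

        return Tensor._node(self.data + o.data, (self, o), back)

    __radd__ = __add__

    def __neg__(self):
        def back(g):
            self._accumulate(-g)

        return Tensor._node(-self.data, (self,), back)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        o = Tensor._lift(other)

        def back(g):
            self._accumulate(_unbroadcast(g * o.data, self.shape))
            o._accumulate(_unbroadcast(g * self.data, o.shape))

        return Tensor._node(self.data * o.data, (self, o), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = Tensor._lift(other)

        def back(g):
            self._accumulate(_unbroadcast(g / o.data, self.shape))
            o._accumulate(_unbroadcast(-g * self.data / (o.data ** 2), o.shape))

        return Tensor._node(self.data / o.data, (self, o), back)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")

        def back(g):
            self._accumulate(g * p * self.data ** (p - 1))

        return Tensor._node(self.data ** p, (self,), back)

    def __matmul__(self, other):
        o = Tensor._lift(other)
        if self.data.ndim != 2 or o.data.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")

        def back(g):
            self._accumulate(g @ o.data.T)
            o._accumulate(self.data.T @ g)

        return Tensor._node(self.data @ o.data, (self, o), back)

    def __getitem__(self, idx):
        def back(g):
            full = np.zeros_like(self.data)
            full[idx] += g
            self._accumulate(full)

        return Tensor._node(self.data[idx], (self,), back)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def back(g):
            self._accumulate(g.reshape(old))

        return Tensor._node(self.data.reshape(shape), (self,), back)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def back(g):
            self._accumulate(g.transpose(inv))

        return Tensor._node(self.data.transpose(axes), (self,), back)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        def back(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy()
                                 if np.ndim(g) else np.full_like(self.data, g))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return Tensor._node(self.data.sum(axis=axis, keepdims=keepdims),
                            (self,), back)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            ax = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------- elementwise
    def exp(self):
        out_data = np.exp(self.data)

        def back(g):
            self._accumulate(g * out_data)

        return Tensor._node(out_data, (self,), back)

    def log(self):
        def back(g):
            self._accumulate(g / self.data)

        return Tensor._node(np.log(self.data), (self,), back)

    def abs(self):
        def back(g):
            self._accumulate(g * np.sign(self.data))

        return Tensor._node(np.abs(self.data), (self,), back)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def back(g):
            self._accumulate(g * s * (1.0 - s))

        return Tensor._node(s, (self,), back)

    def softplus(self):
        """log(1 + e^x), computed stably; gradient is the sigmoid."""
        out_data = np.logaddexp(0.0, self.data)

        def back(g):
            self._accumulate(g / (1.0 + np.exp(-np.clip(self.data, -60, 60))))

        return Tensor._node(out_data, (self,), back)

    def leaky_relu(self, slope: float = 0.1):
        mask = self.data > 0

        def back(g):
            self._accumulate(g * np.where(mask, 1.0, slope))

        return Tensor._node(np.where(mask, self.data, slope * self.data),
                            (self,), back)

    # ----------------------------------------------------------- image kernels
    def conv2d(self, weight: "Tensor", bias: "Tensor", stride: int = 1,
               padding: int = 1):
        """2-D cross-correlation, NCHW; weight (Cout, Cin, k, k)."""
        x, w = self.data, weight.data
        n, cin, h, wid = x.shape
        cout, cin_w, k, _ = w.shape
        if cin != cin_w:
            raise ValueError(f"conv2d channel mismatch: {cin} vs {cin_w}")
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
            if padding else x
        view = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
        ho, wo = view.shape[2], view.shape[3]
        cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, cin * k * k)
        wmat = w.reshape(cout, cin * k * k)
        out = (cols @ wmat.T + bias.data).reshape(n, ho, wo, cout).transpose(
            0, 3, 1, 2)

        def back(g):
            dflat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, cout)
            weight._accumulate((dflat.T @ cols).reshape(w.shape))
            bias._accumulate(dflat.sum(axis=0))
            if self.requires_grad or self._parents:
                dcols = (dflat @ wmat).reshape(n, ho, wo, cin, k, k)
                dxp = np.zeros_like(xp)
                for i in range(k):
                    for j in range(k):
                        dxp[:, :, i:i + stride * ho:stride,
                            j:j + stride * wo:stride] += \
                            dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                if padding:
                    dxp = dxp[:, :, padding:-padding, padding:-padding]
                self._accumulate(dxp)

        return Tensor._node(out, (self, weight, bias), back)

    def maxpool2(self):
        """2x2 max pooling, stride 2; spatial dims must be even."""
        n, c, h, w = self.shape
        if h % 2 or w % 2:
            raise ValueError(f"maxpool2 needs even spatial dims, got {h}x{w}")
        xr = self.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(
            0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

        def back(g):
            gr = np.zeros_like(xr)
            np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
            self._accumulate(gr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(
                0, 1, 2, 4, 3, 5).reshape(n, c, h, w))

        return Tensor._node(out, (self,), back)

    def upsample2(self):
        """2x bilinear upsampling (half-pixel centres, edges clamped)."""
        n, c, h, w = self.shape
        ar = _interp_matrix(h, self.data.dtype)
        ac = _interp_matrix(w, self.data.dtype)
        xr = self.data.reshape(n * c, h, w)
        out = (ar @ xr) @ ac.T

        def back(g):
            gr = g.reshape(n * c, 2 * h, 2 * w)
            self._accumulate(((ar.T @ gr) @ ac).reshape(n, c, h, w))

        return Tensor._node(out.reshape(n, c, 2 * h, 2 * w), (self,), back)


_INTERP_CACHE: dict = {}


def _interp_matrix(h: int, dtype) -> np.ndarray:
    """(2h, h) bilinear interpolation weights for 2x upsampling."""
    key = (h, np.dtype(dtype).str)
    m = _INTERP_CACHE.get(key)
    if m is None:
        src = np.clip((np.arange(2 * h) + 0.5) / 2.0 - 0.5, 0, h - 1)
        lo = np.floor(src).astype(int)
        hi = np.minimum(lo + 1, h - 1)
        t = src - lo
        m = np.zeros((2 * h, h), dtype=dtype)
        rows = np.arange(2 * h)
        np.add.at(m, (rows, lo), 1.0 - t)
        np.add.at(m, (rows, hi), t)
        _INTERP_CACHE[key] = m
    return m


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return Tensor._node(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, back)


def where(cond: np.ndarray, a, b) -> Tensor:
    """Elementwise select; `cond` is a plain boolean array (not differentiated)."""
    a, b = Tensor._lift(a), Tensor._lift(b)
    cond = np.asarray(cond)

    def back(g):
        a._accumulate(_unbroadcast(np.where(cond, g, 0.0), a.shape))
        b._accumulate(_unbroadcast(np.where(cond, 0.0, g), b.shape))

    return Tensor._node(np.where(cond, a.data, b.data), (a, b), back)


def grid_sample(image, field) -> Tensor:
    """Warp `image` (N,C,H,W) by `field` (N,2,H,W): out(x) = image(x + T(x)).

    Bilinear interpolation with border replication; differentiable in both
    the image and the field (field gradient is zero where sampling clamps
    at the border).
    """
    image, field = Tensor._lift(image), Tensor._lift(field)
    n, c, h, w = image.shape
    if field.shape != (n, 2, h, w):
        raise ValueError(f"field shape {field.shape} does not match image "
                         f"{image.shape} (expected ({n}, 2, {h}, {w}))")
    img, f = image.data, field.data
    if not np.all(np.isfinite(f)):
        raise FloatingPointError("displacement field contains non-finite "
                                 "values")
    gy, gx = np.meshgrid(np.arange(h, dtype=img.dtype),
                         np.arange(w, dtype=img.dtype), indexing="ij")
    yy = gy[None] + f[:, 0]
    xx = gx[None] + f[:, 1]
    in_y = (yy >= 0) & (yy <= h - 1)
    in_x = (xx >= 0) & (xx <= w - 1)
    yy = np.clip(yy, 0, h - 1)
    xx = np.clip(xx, 0, w - 1)
    y0 = np.floor(yy).astype(np.intp)
    x0 = np.floor(xx).astype(np.intp)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    ty = (yy - y0).astype(img.dtype)
    tx = (xx - x0).astype(img.dtype)

    bidx = np.arange(n)[:, None, None]
    i00 = img[bidx, :, y0, x0].transpose(0, 3, 1, 2)
    i01 = img[bidx, :, y0, x1].transpose(0, 3, 1, 2)
    i10 = img[bidx, :, y1, x0].transpose(0, 3, 1, 2)
    i11 = img[bidx, :, y1, x1].transpose(0, 3, 1, 2)
    ty_, tx_ = ty[:, None], tx[:, None]
    out = (i00 * (1 - ty_) * (1 - tx_) + i01 * (1 - ty_) * tx_
           + i10 * ty_ * (1 - tx_) + i11 * ty_ * tx_)

    def back(g):
        if image.requires_grad or image._parents:
            dimg = np.zeros_like(img)
            flat = dimg.reshape(n, c, h * w)
            for yi, xi, wgt in ((y0, x0, (1 - ty_) * (1 - tx_)),
                                (y0, x1, (1 - ty_) * tx_),
                                (y1, x0, ty_ * (1 - tx_)),
                                (y1, x1, ty_ * tx_)):
                lin = (yi * w + xi)[:, None]              # (n,1,h,w)
                contrib = (g * wgt).reshape(n, c, h * w)
                np.add.at(flat, (np.arange(n)[:, None, None],
                                 np.arange(c)[None, :, None],
                                 np.broadcast_to(lin, (n, c, h, w)).reshape(
                                     n, c, h * w)), contrib)
            image._accumulate(dimg)
        if field.requires_grad or field._parents:
            dy = ((i10 - i00) * (1 - tx_) + (i11 - i01) * tx_)
            dx = ((i01 - i00) * (1 - ty_) + (i11 - i10) * ty_)
            gy_ = (g * dy).sum(axis=1) * in_y
            gx_ = (g * dx).sum(axis=1) * in_x
            field._accumulate(np.stack([gy_, gx_], axis=1))

    return Tensor._node(out, (image, field), back)
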