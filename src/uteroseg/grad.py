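"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine sized for the networks in this package: dense and
convolutional layers, bilinear grid sampling (the primitive behind deformable
convolution, ROIAlign and point-wise mask refinement), reductions and the
usual element-wise functions.  Arrays are float64 throughout; gradients are
accumulated by a topological backward sweep from a scalar loss.

Only the operations the detector actually uses are implemented; this is not a
general framework.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        raise TypeError("expected raw array, got Tensor")
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray plus the closure needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # numpy defers binary ops to us

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    # -- autograd engine ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    # -- elementwise binary ---------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)
        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2,
                                          other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2),
                                         self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                          other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise unary ----------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # stable logistic

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)

        def backward(g):
            self._accum(g * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            self._accum(g * sign)

        return Tensor._make(np.abs(self.data), (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis, keepdims: bool = False):
        """Max-reduce along `axis`; gradient flows to the (first) argmax."""
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == out_data)
        # route gradient only to the first maximal entry along the axis
        first = np.cumsum(mask, axis=axis) == 1
        mask = mask & first
        res = out_data if keepdims else np.squeeze(out_data, axis=axis)

        def backward(g):
            gg = np.asarray(g)
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(mask * gg)

        return Tensor._make(res, (self,), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(out_data, (self,), backward)


# -- free functions -----------------------------------------------------------

def concat(tensors: list, axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def stack(tensors: list, axis: int = 0) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, zero padding.

    y(p0) = sum_{pl in K} w(pl) * x(p0 + pl): the regular convolution that the
    deformable variant reduces to when all offsets vanish.
    """
    N, C, H, W = x.data.shape
    F, C2, KH, KW = w.data.shape
    if C != C2:
        raise ValueError(f"channel mismatch: input {C}, kernel {C2}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Ho = (H + 2 * pad - KH) // stride + 1
    Wo = (W + 2 * pad - KW) // stride + 1
    win = sliding_window_view(xp, (KH, KW), axis=(2, 3))[
        :, :, ::stride, ::stride]          # N,C,Ho,Wo,KH,KW
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * KH * KW)
    wm = w.data.reshape(F, C * KH * KW)
    out = cols @ wm.T
    if b is not None:
        out = out + b.data
    out_data = out.reshape(N, Ho, Wo, F).transpose(0, 3, 1, 2)

    def backward(g):
        gm = g.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, F)
        if w.requires_grad:
            w._accum((gm.T @ cols).reshape(F, C, KH, KW))
        if b is not None and b.requires_grad:
            b._accum(gm.sum(axis=0))
        if x.requires_grad:
            dcols = (gm @ wm).reshape(N, Ho, Wo, C, KH, KW)
            dxp = np.zeros_like(xp)
            for i in range(KH):
                for j in range(KW):
                    dxp[:, :, i:i + stride * Ho:stride,
                        j:j + stride * Wo:stride] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if pad:
                dxp = dxp[:, :, pad:-pad, pad:-pad]
            x._accum(dxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out_data, parents, backward)


def avg_pool2x2(x: Tensor) -> Tensor:
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("avg_pool2x2 needs even spatial dims")
    out_data = x.data.reshape(N, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def backward(g):
        gg = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
        x._accum(gg)

    return Tensor._make(out_data, (x,), backward)


def _bilinear_resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Sparse-ish 1-D interpolation matrix under the half-pixel convention."""
    M = np.zeros((n_out, n_in))
    if n_in == 1:
        M[:, 0] = 1.0
        return M
    scale = n_in / n_out
    for i in range(n_out):
        u = (i + 0.5) * scale - 0.5
        u = min(max(u, 0.0), n_in - 1.0)
        i0 = int(np.floor(u))
        i1 = min(i0 + 1, n_in - 1)
        t = u - i0
        M[i, i0] += 1.0 - t
        M[i, i1] += t
    return M


_RESIZE_CACHE: dict = {}


def upsample_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize (align_corners=False / half-pixel convention)."""
    N, C, H, W = x.data.shape
    key = (H, out_h)
    if key not in _RESIZE_CACHE:
        _RESIZE_CACHE[key] = _bilinear_resize_matrix(H, out_h)
    Mr = _RESIZE_CACHE[key]
    key = (W, out_w)
    if key not in _RESIZE_CACHE:
        _RESIZE_CACHE[key] = _bilinear_resize_matrix(W, out_w)
    Mc = _RESIZE_CACHE[key]
    out_data = np.einsum("oh,nchw,pw->ncop", Mr, x.data, Mc, optimize=True)

    def backward(g):
        x._accum(np.einsum("oh,ncop,pw->nchw", Mr, g, Mc, optimize=True))

    return Tensor._make(out_data, (x,), backward)


def grid_sample(x: Tensor, px: np.ndarray, py: np.ndarray,
                offs_x: Tensor | None = None,
                offs_y: Tensor | None = None) -> Tensor:
    """Bilinear point sampling of feature maps, NCHW.

    Samples x at continuous pixel coordinates (px + offs_x, py + offs_y) per
    batch element, where pixel (r, c) has its center at (c + 0.5, r + 0.5).
    Points outside the image contribute zero.  `px`, `py` are fixed base
    coordinates of shape (N, P); the optional offsets are differentiable
    Tensors of the same shape.  Returns (N, C, P).
    """
    N, C, H, W = x.data.shape
    sx = px + (offs_x.data if offs_x is not None else 0.0)
    sy = py + (offs_y.data if offs_y is not None else 0.0)
    u = sx - 0.5
    v = sy - 0.5
    x0 = np.floor(u).astype(np.int64)
    y0 = np.floor(v).astype(np.int64)
    tx = u - x0
    ty = v - y0

    vals = []      # per-corner gathered values (N, C, P)
    valid_all = []
    corners = []
    for dy in (0, 1):
        for dx in (0, 1):
            cx = x0 + dx
            cy = y0 + dy
            valid = (cx >= 0) & (cx < W) & (cy >= 0) & (cy < H)
            cxc = np.clip(cx, 0, W - 1)
            cyc = np.clip(cy, 0, H - 1)
            n_idx = np.arange(N)[:, None]
            val = x.data[n_idx, :, cyc, cxc]          # (N, P, C)
            val = val.transpose(0, 2, 1) * valid[:, None, :]
            vals.append(val)
            valid_all.append(valid)
            corners.append((cxc, cyc, dx, dy))
    wts = [((1 - tx) * (1 - ty)), (tx * (1 - ty)),
           ((1 - tx) * ty), (tx * ty)]                # (N, P) each
    out_data = sum(w[:, None, :] * v for w, v in zip(wts, vals))

    def backward(g):                                   # g: (N, C, P)
        if x.requires_grad:
            dx_full = np.zeros_like(x.data)
            n_idx = np.broadcast_to(np.arange(N)[:, None], sx.shape)
            for w, valid, (cxc, cyc, _, _) in zip(wts, valid_all, corners):
                contrib = (g * w[:, None, :]).transpose(0, 2, 1)  # N,P,C
                contrib = contrib * valid[:, :, None]
                np.add.at(dx_full, (n_idx, slice(None), cyc, cxc), contrib)
            x._accum(dx_full)
        if offs_x is not None and offs_x.requires_grad:
            # d out / d sx:  bilinear weights differentiated in tx
            dwx = [-(1 - ty), (1 - ty), -ty, ty]
            gx = sum((g * dw[:, None, :] * v).sum(axis=1)
                     for dw, v in zip(dwx, vals))
            offs_x._accum(gx)
        if offs_y is not None and offs_y.requires_grad:
            dwy = [-(1 - tx), -tx, (1 - tx), tx]
            gy = sum((g * dw[:, None, :] * v).sum(axis=1)
                     for dw, v in zip(dwy, vals))
            offs_y._accum(gy)

    parents = [x]
    if offs_x is not None:
        parents.append(offs_x)
    if offs_y is not None:
        parents.append(offs_y)
    return Tensor._make(out_data, tuple(parents), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = Tensor(x.data.max(axis=axis, keepdims=True))   # detached shift
    e = (x - m).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - m
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def binary_cross_entropy_with_logits(logits: Tensor, targets: np.ndarray,
                                     weights: np.ndarray | None = None) -> Tensor:
    """Mean BCE, computed stably from logits: -y log p - (1-y) log(1-p)."""
    t = np.asarray(targets, dtype=np.float64)
    # stable form: BCE = max(z,0) - z*y + log(1 + exp(-|z|))
    z = logits
    per = z.relu() - z * t + ((-z.abs()).exp() + 1.0).log()
    if weights is not None:
        per = per * np.asarray(weights, dtype=np.float64)
    return per.mean()
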