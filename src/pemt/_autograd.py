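"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the segmentation backbone and losses need:
elementwise arithmetic with broadcasting, reductions, ``log``/``clip``,
basic slicing, 3x3 same-padding convolution, 2x2 average pooling, nearest
2x upsampling, channel concatenation, inverted dropout and channel softmax.
Gradients are accumulated by a topological sweep from the scalar loss.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv3x3", "avg_pool2", "upsample2", "concat_channels",
           "dropout", "group_norm", "softmax_channels"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ------------------------------------------------
    @staticmethod
    def _op(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if g.dtype != self.data.dtype:
            g = g.astype(self.data.dtype)  # keep float32 graphs in float32
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> np.ndarray:
        return self.data

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # -- elementwise arithmetic ----------------------------------------
    @staticmethod
    def _coerce(x, like: np.dtype | None = None) -> "Tensor":
        if isinstance(x, Tensor):
            return x
        # pin python scalars to the peer's dtype to avoid float64 promotion
        if like is not None and np.isscalar(x):
            return Tensor(np.asarray(x, dtype=like))
        return Tensor(np.asarray(x))

    def __add__(self, other):
        other = Tensor._coerce(other, self.data.dtype)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._op(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            a._accum(-g)

        return Tensor._op(-a.data, (a,), bwd)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other, self.data.dtype))

    def __rsub__(self, other):
        return Tensor._coerce(other, self.data.dtype) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other, self.data.dtype)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._op(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other, self.data.dtype)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor._op(a.data / b.data, (a, b), bwd)

    def __rtruediv__(self, other):
        return Tensor._coerce(other, self.data.dtype) / self

    def __pow__(self, exponent: float):
        a = self
        out_data = a.data ** exponent

        def bwd(g):
            a._accum(g * exponent * a.data ** (exponent - 1))

        return Tensor._op(out_data, (a,), bwd)

    def log(self):
        a = self

        def bwd(g):
            a._accum(g / a.data)

        return Tensor._op(np.log(a.data), (a,), bwd)

    def clip_min(self, lo: float):
        """max(x, lo); gradient passes only where x > lo."""
        a = self
        mask = a.data > lo

        def bwd(g):
            a._accum(g * mask)

        return Tensor._op(np.maximum(a.data, lo), (a,), bwd)

    def relu(self):
        a = self
        mask = a.data > 0

        def bwd(g):
            a._accum(g * mask)

        return Tensor._op(a.data * mask, (a,), bwd)

    # -- reductions and shaping ----------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy()
                         if np.ndim(g) == a.data.ndim else np.full_like(a.data, g))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.data.shape).astype(a.data.dtype))

        return Tensor._op(out_data, (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[ax] for ax in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        a = self
        orig = a.data.shape

        def bwd(g):
            a._accum(g.reshape(orig))

        return Tensor._op(a.data.reshape(*shape), (a,), bwd)

    def __getitem__(self, idx):
        a = self

        def bwd(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return Tensor._op(a.data[idx], (a,), bwd)


# -- network operations (NCHW layout) ----------------------------------

def conv3x3(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """3x3 convolution with same (zero) padding.

    x: (N, Cin, H, W); w: (Cout, Cin, 3, 3); b: (Cout,).
    Implemented as nine shifted matmuls so the heavy lifting is BLAS.
    """
    xd, wd = x.data, w.data
    n, cin, h, wid = xd.shape
    nhw = n * h * wid
    cout = wd.shape[0]
    # channel-first padded layout: each of the nine shifts packs to a
    # (cin, n*H*W) matrix, so every shift is ONE large GEMM independent of
    # the batch size (Monte-Carlo passes run as a single big batch)
    xp = np.ascontiguousarray(np.pad(xd, ((0, 0), (0, 0), (1, 1), (1, 1)))
                              .transpose(1, 0, 2, 3))
    out = np.zeros((cout, nhw), dtype=np.result_type(xd, wd))
    for di in range(3):
        for dj in range(3):
            xs = np.ascontiguousarray(
                xp[:, :, di:di + h, dj:dj + wid]).reshape(cin, nhw)
            out += wd[:, :, di, dj] @ xs
    out = np.ascontiguousarray(
        out.reshape(cout, n, h, wid).transpose(1, 0, 2, 3))
    out += b.data.reshape(1, cout, 1, 1)
    # only the padded input is retained for backward; the shifted copies are
    # transient, which keeps live graph memory small

    def bwd(g):
        gf = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(cout, nhw)
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        need_dx = x.requires_grad
        if need_dx:
            gxp = np.zeros_like(xp)
        if w.requires_grad:
            gw = np.empty_like(wd)
        for di in range(3):
            for dj in range(3):
                if w.requires_grad:
                    xs = np.ascontiguousarray(
                        xp[:, :, di:di + h, dj:dj + wid]).reshape(cin, nhw)
                    gw[:, :, di, dj] = gf @ xs.T
                if need_dx:
                    gxp[:, :, di:di + h, dj:dj + wid] += (
                        wd[:, :, di, dj].T @ gf).reshape(cin, n, h, wid)
        if w.requires_grad:
            w._accum(gw)
        if need_dx:
            x._accum(np.ascontiguousarray(
                gxp[:, :, 1:-1, 1:-1].transpose(1, 0, 2, 3)))

    return Tensor._op(out, (x, w, b), bwd)


def conv1x1(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """1x1 convolution. w: (Cout, Cin)."""
    xd, wd = x.data, w.data
    n, cin, h, wid = xd.shape
    cout = wd.shape[0]
    xf = xd.reshape(n, cin, h * wid)
    out = (wd @ xf).reshape(n, cout, h, wid) + b.data.reshape(1, cout, 1, 1)

    def bwd(g):
        gf = g.reshape(n, cout, h * wid)
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w._accum(np.tensordot(gf, xf, axes=([0, 2], [0, 2])))
        if x.requires_grad:
            x._accum((wd.T @ gf).reshape(n, cin, h, wid))

    return Tensor._op(out, (x, w, b), bwd)


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling with stride 2."""
    xd = x.data
    n, c, h, w = xd.shape
    out = xd.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def bwd(g):
        gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
        x._accum(gx.astype(xd.dtype))

    return Tensor._op(out, (x,), bwd)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    xd = x.data
    out = np.repeat(np.repeat(xd, 2, axis=2), 2, axis=3)

    def bwd(g):
        n, c, h2, w2 = g.shape
        gx = g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
        x._accum(gx)

    return Tensor._op(out, (x,), bwd)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[1]

    def bwd(g):
        if a.requires_grad:
            a._accum(g[:, :ca])
        if b.requires_grad:
            b._accum(g[:, ca:])

    return Tensor._op(np.concatenate([a.data, b.data], axis=1), (a, b), bwd)


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity when rate == 0."""
    if rate <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= rate).astype(x.data.dtype)
    scale = np.asarray(1.0 / (1.0 - rate), dtype=x.data.dtype)
    mask = keep * scale

    def bwd(g):
        x._accum(g * mask)

    return Tensor._op(x.data * mask, (x,), bwd)


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int,
               eps: float = 1e-5) -> Tensor:
    """Group normalisation with per-channel affine parameters (fused op).

    Statistics are computed over (channels_per_group, H, W) per sample; no
    running statistics exist, so train and inference behave identically.
    """
    xd = x.data
    n, c, h, w = xd.shape
    g = min(groups, c)
    while c % g:
        g -= 1
    xr = xd.reshape(n, g, -1)
    mu = xr.mean(axis=2, keepdims=True)
    xc = xr - mu
    var = (xc * xc).mean(axis=2, keepdims=True)
    inv = 1.0 / np.sqrt(var + np.asarray(eps, dtype=xd.dtype))
    xhat = (xc * inv).reshape(n, c, h, w)
    gam = gamma.data.reshape(1, c, 1, 1)
    out = xhat * gam + beta.data.reshape(1, c, 1, 1)

    def bwd(grad):
        if beta.requires_grad:
            beta._accum(grad.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accum((grad * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            ghat = (grad * gam).reshape(n, g, -1)
            xh = xhat.reshape(n, g, -1)
            m1 = ghat.mean(axis=2, keepdims=True)
            m2 = (ghat * xh).mean(axis=2, keepdims=True)
            gx = (ghat - m1 - xh * m2) * inv
            x._accum(gx.reshape(n, c, h, w))

    return Tensor._op(out, (x, gamma, beta), bwd)


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over axis 1 (classes)."""
    xd = x.data
    z = xd - xd.max(axis=1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=1, keepdims=True)

    def bwd(g):
        dot = (g * s).sum(axis=1, keepdims=True)
        x._accum(s * (g - dot))

    return Tensor._op(s, (x,), bwd)
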