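"""Reverse-mode automatic differentiation over numpy arrays.

A compact tape-based engine providing exactly the operations the models in
this package need: strided/dilated 2-D convolution, transposed convolution,
channel concatenation, nearest-neighbour upsampling, the usual pointwise
nonlinearities, and scalar reductions.  Gradients of every primitive are
checked against central finite differences in the test suite.

Arrays follow the (N, C, H, W) layout throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "upsample_nearest",
]


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    def __init__(self, data, requires_grad: bool = False, _prev=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64 if np.asarray(data).dtype == np.float64 else np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._prev = tuple(_prev)
        self._backward = _backward

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd machinery ---------------------------------------------------
    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data
        out = Tensor(out_data, self.requires_grad or other.requires_grad, (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = _bw
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, self.requires_grad or other.requires_grad, (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    # -- pointwise ------------------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0))

        out._backward = _bw
        return out

    def leaky_relu(self, slope: float = 0.2):
        out_data = np.where(self.data > 0, self.data, slope * self.data)
        out = Tensor(out_data, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * np.where(self.data > 0, 1.0, slope))

        out._backward = _bw
        return out

    def sigmoid(self):
        # clip the logits so float32 exp cannot overflow; sigmoid saturates
        # far inside +-60 anyway
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))
        out = Tensor(s, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        out._backward = _bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = _bw
        return out

    def clamp(self, lo: float, hi: float):
        out_data = np.clip(self.data, lo, hi)
        out = Tensor(out_data, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * ((self.data >= lo) & (self.data <= hi)))

        out._backward = _bw
        return out

    def square(self):
        return self * self

    # -- reductions -----------------------------------------------------------
    def sum(self):
        out = Tensor(self.data.sum(), self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(np.full_like(self.data, g))

        out._backward = _bw
        return out

    def mean(self):
        return self.sum() / self.data.size


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _unbroadcast(g, shape):
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    g = np.asarray(g)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- structural ops ---------------------------------------------------------


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        any(t.requires_grad for t in tensors),
        tuple(tensors),
    )
    sizes = [t.data.shape[axis] for t in tensors]

    def _bw(g):
        start = 0
        for t, n in zip(tensors, sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(start, start + n)
                t._accumulate(g[tuple(sl)])
            start += n

    out._backward = _bw
    return out


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    """Nearest-neighbour upsampling by an integer factor on H and W."""
    f = int(factor)
    out_data = x.data.repeat(f, axis=2).repeat(f, axis=3)
    out = Tensor(out_data, x.requires_grad, (x,))
    n, c, h, w = x.data.shape

    def _bw(g):
        if x.requires_grad:
            x._accumulate(g.reshape(n, c, h, f, w, f).sum(axis=(3, 5)))

    out._backward = _bw
    return out


# -- convolution ------------------------------------------------------------


def _out_size(size, k, stride, pad, dil):
    eff = (k - 1) * dil + 1
    return (size + 2 * pad - eff) // stride + 1


def _im2col(xp, kh, kw, stride, dil, ho, wo):
    """(N, C, Hp, Wp) padded input -> (N, C*kh*kw, ho*wo) patch matrix."""
    n, c, hp, wp = xp.shape
    sn, sc, sh, sw = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, kh, kw, ho, wo),
        strides=(sn, sc, sh * dil, sw * dil, sh * stride, sw * stride),
        writeable=False,
    )
    return win.reshape(n, c * kh * kw, ho * wo)


def _col2im(cols, pshape, kh, kw, stride, dil, ho, wo):
    """Scatter-add inverse of :func:`_im2col`."""
    n, c = pshape[0], pshape[1]
    out = np.zeros(pshape, dtype=cols.dtype)
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i * dil : i * dil + stride * ho : stride, j * dil : j * dil + stride * wo : stride] += cols[:, :, i, j]
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D convolution (cross-correlation), weights of shape (O, C, kh, kw)."""
    n, c, h, wd = x.data.shape
    o, cw, kh, kw = w.data.shape
    if cw != c:
        raise ValueError(f"conv2d channel mismatch: input has {c}, weight expects {cw}")
    ho = _out_size(h, kh, stride, padding, dilation)
    wo = _out_size(wd, kw, stride, padding, dilation)
    if ho < 1 or wo < 1:
        raise ValueError("conv2d output would be empty; input too small for kernel/stride")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = np.ascontiguousarray(_im2col(xp, kh, kw, stride, dilation, ho, wo))
    wmat = w.data.reshape(o, c * kh * kw)
    out_data = np.matmul(wmat, cols).reshape(n, o, ho, wo)
    if b is not None:
        out_data = out_data + b.data.reshape(1, o, 1, 1)
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, any(t.requires_grad for t in prev), prev)

    def _bw(g):
        gmat = g.reshape(n, o, ho * wo)
        if w.requires_grad:
            w._accumulate(np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.matmul(wmat.T, gmat)
            gxp = _col2im(gcols, xp.shape, kh, kw, stride, dilation, ho, wo)
            if padding:
                gxp = gxp[:, :, padding:-padding or None, padding:-padding or None]
            x._accumulate(gxp)

    out._backward = _bw
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, padding: int = 0) -> Tensor:
    """Transposed 2-D convolution, weights of shape (C_in, O, kh, kw).

    Output size is ``(H - 1) * stride - 2 * padding + k``, the exact adjoint
    of :func:`conv2d` with the same stride/padding.
    """
    n, c, h, wd = x.data.shape
    cw, o, kh, kw = w.data.shape
    if cw != c:
        raise ValueError(f"conv_transpose2d channel mismatch: input has {c}, weight expects {cw}")
    hp = (h - 1) * stride + kh
    wp = (wd - 1) * stride + kw
    wmat = w.data.reshape(c, o * kh * kw)
    cols = np.matmul(wmat.T, x.data.reshape(n, c, h * wd))
    out_full = _col2im(cols, (n, o, hp, wp), kh, kw, stride, 1, h, wd)
    out_data = out_full[:, :, padding : hp - padding, padding : wp - padding]
    if b is not None:
        out_data = out_data + b.data.reshape(1, o, 1, 1)
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, any(t.requires_grad for t in prev), prev)

    def _bw(g):
        gp = np.pad(g, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        gcols = np.ascontiguousarray(_im2col(gp, kh, kw, stride, 1, h, wd))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w._accumulate(
                np.matmul(x.data.reshape(n, c, h * wd), gcols.transpose(0, 2, 1)).sum(axis=0).reshape(w.data.shape)
            )
        if x.requires_grad:
            x._accumulate(np.matmul(wmat, gcols).reshape(n, c, h, wd))

    out._backward = _bw
    return out
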