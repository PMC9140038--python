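"""Minimal reverse-mode automatic differentiation over numpy arrays.

This engine provides exactly the operations the registration network needs:
2-D convolution (stride 1 or 2, zero padding), leaky ReLU, nearest-neighbour
2x upsampling, channel concatenation, differentiable bilinear warping with
clamp-to-edge sampling, box filtering, elementwise arithmetic and reductions,
plus an Adam optimizer.  Tensors wrap numpy arrays; gradients are accumulated
by a topologically sorted backward pass.

The engine is dtype-agnostic: it computes in whatever float dtype the input
arrays carry (float32 for training speed, float64 for gradient checks).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "Adam"]


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self):
        """Run reverse-mode accumulation from this (scalar) tensor."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- elementwise arithmetic ------------------------------------------

    def __add__(self, other):
        other = _wrap(other, self)
        out = _node(self.data + other.data, (self, other))

        def bwd(g):
            _send(self, g)
            _send(other, g)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __sub__(self, other):
        other = _wrap(other, self)
        out = _node(self.data - other.data, (self, other))

        def bwd(g):
            _send(self, g)
            _send(other, -g)

        out._backward = bwd
        return out

    def __neg__(self):
        out = _node(-self.data, (self,))
        out._backward = lambda g: _send(self, -g)
        return out

    def __mul__(self, other):
        other = _wrap(other, self)
        out = _node(self.data * other.data, (self, other))

        def bwd(g):
            _send(self, g * other.data)
            _send(other, g * self.data)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other, self)
        out = _node(self.data / other.data, (self, other))

        def bwd(g):
            _send(self, g / other.data)
            _send(other, -g * self.data / (other.data ** 2))

        out._backward = bwd
        return out

    def square(self):
        out = _node(self.data ** 2, (self,))
        out._backward = lambda g: _send(self, 2.0 * g * self.data)
        return out

    def sqrt(self):
        root = np.sqrt(self.data)
        out = _node(root, (self,))
        out._backward = lambda g: _send(self, 0.5 * g / np.maximum(root, 1e-30))
        return out

    def mean(self):
        out = _node(np.asarray(self.data.mean()), (self,))
        n = self.data.size

        def bwd(g):
            _send(self, np.full_like(self.data, float(g) / n))

        out._backward = bwd
        return out

    def sum(self):
        out = _node(np.asarray(self.data.sum()), (self,))

        def bwd(g):
            _send(self, np.full_like(self.data, float(g)))

        out._backward = bwd
        return out


def _node(data, parents):
    t = Tensor(data)
    t._parents = tuple(p for p in parents if isinstance(p, Tensor))
    return t


def _wrap(x, like):
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=like.data.dtype))


def _send(t, g):
    """Propagate gradient g into tensor t (handles broadcast of scalars)."""
    if not isinstance(t, Tensor):
        return
    if t._backward is None and not t.requires_grad and not t._parents:
        return
    g = np.asarray(g)
    if g.shape != t.data.shape:
        # reduce broadcast dimensions (only scalar broadcast is used here)
        g = np.broadcast_to(g, np.broadcast_shapes(g.shape, t.data.shape))
        if g.shape != t.data.shape:
            g = g.sum()
        else:
            g = g.copy()
        g = np.asarray(np.sum(g)) if t.data.shape == () else np.asarray(g)
    t._accumulate(np.asarray(g, dtype=t.data.dtype))


# -- neural-network operations -----------------------------------------


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    mask = x.data > 0
    out = _node(np.where(mask, x.data, slope * x.data), (x,))
    out._backward = lambda g: _send(x, np.where(mask, g, slope * g))
    return out


def _im2col(x, k, stride, pad):
    """(C,H,W) -> (C*k*k, Ho*Wo) column matrix."""
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::stride, ::stride]
    C, Ho, Wo = win.shape[:3]
    return (
        win.transpose(0, 3, 4, 1, 2).reshape(C * k * k, Ho * Wo),
        (Ho, Wo),
    )


def _col2im(cols, x_shape, k, stride, pad, out_hw):
    """Adjoint of _im2col: scatter-add columns back to (C,H,W)."""
    C, H, W = x_shape
    Ho, Wo = out_hw
    xp = np.zeros((C, H + 2 * pad, W + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(C, k, k, Ho, Wo)
    for i in range(k):
        for j in range(k):
            xp[:, i : i + Ho * stride : stride, j : j + Wo * stride : stride] += cols[
                :, i, j
            ]
    if pad:
        return xp[:, pad:-pad, pad:-pad]
    return xp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1) -> Tensor:
    """3x3 (or kxk) convolution with zero padding k//2; x is (C,H,W)."""
    Cout, Cin, k, _ = weight.data.shape
    pad = k // 2
    cols, (Ho, Wo) = _im2col(x.data, k, stride, pad)
    Wm = weight.data.reshape(Cout, -1)
    y = (Wm @ cols).reshape(Cout, Ho, Wo) + bias.data[:, None, None]
    out = _node(y, (x, weight, bias))

    def bwd(g):
        gf = g.reshape(Cout, -1)
        _send(weight, (gf @ cols.T).reshape(weight.data.shape))
        _send(bias, g.sum(axis=(1, 2)))
        dcols = Wm.T @ gf
        _send(x, _col2im(dcols, x.data.shape, k, stride, pad, (Ho, Wo)))

    out._backward = bwd
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling of (C,H,W)."""
    out = _node(x.data.repeat(2, axis=1).repeat(2, axis=2), (x,))

    def bwd(g):
        C, H2, W2 = g.shape
        _send(x, g.reshape(C, H2 // 2, 2, W2 // 2, 2).sum(axis=(2, 4)))

    out._backward = bwd
    return out


def concat(tensors) -> Tensor:
    """Concatenate (C,H,W) tensors along the channel axis."""
    tensors = list(tensors)
    out = _node(np.concatenate([t.data for t in tensors], axis=0), tensors)
    sizes = [t.data.shape[0] for t in tensors]

    def bwd(g):
        ofs = 0
        for t, c in zip(tensors, sizes):
            _send(t, g[ofs : ofs + c])
            ofs += c

    out._backward = bwd
    return out


def crop2d(x: Tensor, margin: int) -> Tensor:
    """Drop a border of `margin` pixels on every side of (...,H,W)."""
    m = margin
    out = _node(x.data[..., m:-m, m:-m], (x,))

    def bwd(g):
        full = np.zeros_like(x.data)
        full[..., m:-m, m:-m] = g
        _send(x, full)

    out._backward = bwd
    return out


def spatial_diff(x: Tensor, axis: int) -> Tensor:
    """Forward difference along a spatial axis of (...,H,W)."""
    sl_hi = [slice(None)] * x.data.ndim
    sl_lo = [slice(None)] * x.data.ndim
    sl_hi[axis] = slice(1, None)
    sl_lo[axis] = slice(None, -1)
    sl_hi, sl_lo = tuple(sl_hi), tuple(sl_lo)
    out = _node(x.data[sl_hi] - x.data[sl_lo], (x,))

    def bwd(g):
        full = np.zeros_like(x.data)
        full[sl_hi] += g
        full[sl_lo] -= g
        _send(x, full)

    out._backward = bwd
    return out


def box_filter(x: Tensor, window: int) -> Tensor:
    """Mean filter over window x window neighbourhoods, zero padding.

    Self-adjoint under zero padding, so the backward pass reuses the
    forward operator.
    """
    from scipy.ndimage import uniform_filter

    axes = (-2, -1)

    def f(a):
        return uniform_filter(a, size=window, mode="constant", cval=0.0, axes=axes)

    out = _node(f(x.data), (x,))
    out._backward = lambda g: _send(x, f(g))
    return out


def bilinear_warp_forward(image, field):
    """Backward-warp a (H,W) array by a (2,H,W) (dy,dx) field, clamped.

    Returns (warped, cache) where cache carries what the gradient needs.
    Pure numpy; shared by the autodiff op and the inference-time warper.
    """
    H, W = image.shape
    dy, dx = field[0], field[1]
    rr, cc = np.meshgrid(
        np.arange(H, dtype=image.dtype), np.arange(W, dtype=image.dtype), indexing="ij"
    )
    r = rr + dy
    c = cc + dx
    in_r = (r > 0) & (r < H - 1)  # clamp mask: gradient flows only inside
    in_c = (c > 0) & (c < W - 1)
    r = np.clip(r, 0, H - 1)
    c = np.clip(c, 0, W - 1)
    r0 = np.floor(r).astype(np.intp)
    c0 = np.floor(c).astype(np.intp)
    r0 = np.minimum(r0, H - 2) if H > 1 else r0
    c0 = np.minimum(c0, W - 2) if W > 1 else c0
    r1 = np.minimum(r0 + 1, H - 1)
    c1 = np.minimum(c0 + 1, W - 1)
    fr = r - r0
    fc = c - c0
    Ia = image[r0, c0]
    Ib = image[r0, c1]
    Ic = image[r1, c0]
    Id = image[r1, c1]
    wa = (1 - fr) * (1 - fc)
    wb = (1 - fr) * fc
    wc = fr * (1 - fc)
    wd = fr * fc
    warped = wa * Ia + wb * Ib + wc * Ic + wd * Id
    cache = (r0, c0, r1, c1, fr, fc, Ia, Ib, Ic, Id, wa, wb, wc, wd, in_r, in_c)
    return warped, cache


def warp(image: Tensor, field: Tensor) -> Tensor:
    """Differentiable bilinear backward warp; gradients w.r.t. both inputs."""
    warped, cache = bilinear_warp_forward(image.data, field.data)
    r0, c0, r1, c1, fr, fc, Ia, Ib, Ic, Id, wa, wb, wc, wd, in_r, in_c = cache
    H, W = image.data.shape
    out = _node(warped, (image, field))

    def bwd(g):
        if image.requires_grad or image._parents or image._backward:
            gi = np.zeros_like(image.data)
            np.add.at(gi, (r0, c0), g * wa)
            np.add.at(gi, (r0, c1), g * wb)
            np.add.at(gi, (r1, c0), g * wc)
            np.add.at(gi, (r1, c1), g * wd)
            _send(image, gi)
        d_dr = (1 - fc) * (Ic - Ia) + fc * (Id - Ib)
        d_dc = (1 - fr) * (Ib - Ia) + fr * (Id - Ic)
        gf = np.stack([g * d_dr * in_r, g * d_dc * in_c])
        _send(field, gf)

    out._backward = bwd
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bias1
            vhat = self.v[i] / bias2
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.data.dtype
            )
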