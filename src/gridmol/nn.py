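"""Minimal reverse-mode autodiff over numpy for 3D convolutional models.

This is a deliberately small engine: ndarray-valued nodes, a tape built by
the forward pass, and hand-derived backward rules for exactly the operations
the density-grid CVAE needs — 3D convolution (im2col + matmul), average
pooling, nearest-neighbor upsampling, dense layers, leaky ReLU, exp/softplus,
concatenation and reductions.  Spectral normalization of weights is provided
via one power iteration per forward pass, with the gradient flowing through
the normalized weight.  The optimizer is RMSprop.

Shapes follow the channels-first convention: grids are (B, C, D, H, W).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "Parameter", "Dense", "Conv3d", "ConvBlock", "RMSprop"]


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "_backward", "_prev", "requires_grad")

    def __init__(self, data, prev=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._prev = tuple(prev)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in prev)

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if not self.requires_grad:
            return
        self.grad = g if self.grad is None else self.grad + g

    # -- elementwise / linear algebra ------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, (self, other))

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, (self, other))

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    def __rmul__(self, other):
        return self * other

    def __radd__(self, other):
        return self + other

    def __sub__(self, other):
        return self + (_as_tensor(other) * (-1.0))

    def __matmul__(self, other):
        out = Tensor(self.data @ other.data, (self, other))

        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        out._backward = bw
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def sum(self):
        out = Tensor(self.data.sum(), (self,))
        out._backward = lambda g: self._accum(np.broadcast_to(g, self.data.shape).copy())
        return out

    def sum_axis(self, axis, keepdims=True):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _unbroadcast(g, shape):
    """Sum gradient over broadcast dimensions back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def leaky_relu(x: Tensor, slope: float = 0.1) -> Tensor:
    mask = np.where(x.data > 0, 1.0, slope)
    out = Tensor(x.data * mask, (x,))
    out._backward = lambda g: x._accum(g * mask)
    return out


def exp(x: Tensor) -> Tensor:
    val = np.exp(x.data)
    out = Tensor(val, (x,))
    out._backward = lambda g: x._accum(g * val)
    return out


def softplus(x: Tensor) -> Tensor:
    val = np.logaddexp(0.0, x.data)
    out = Tensor(val, (x,))
    sig = 1.0 / (1.0 + np.exp(-x.data))
    out._backward = lambda g: x._accum(g * sig)
    return out


def concat(tensors, axis: int) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = bw
    return out


def scale_inv(a: Tensor, s: Tensor) -> Tensor:
    """a / s for scalar s, with gradients to both."""
    sval = float(s.data)
    out = Tensor(a.data / sval, (a, s))

    def bw(g):
        a._accum(g / sval)
        s._accum(np.array(-np.sum(g * a.data) / sval**2).reshape(s.data.shape))

    out._backward = bw
    return out


# -- spatial ops ---------------------------------------------------------

def conv3d(x: Tensor, w: Tensor, b: Tensor, pad: int = 1) -> Tensor:
    """'Same'-padded stride-1 3D convolution (cross-correlation).

    x: (B, C, D, H, W); w: (F, C, k, k, k); b: (F,).
    """
    B, C, D, H, W = x.data.shape
    F, _, k, _, _ = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))  # (B,C,D,H,W,k,k,k)
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(B, D * H * W, C * k**3)
    wmat = w.data.reshape(F, C * k**3)
    y = cols @ wmat.T + b.data  # (B, P, F)
    out = Tensor(y.transpose(0, 2, 1).reshape(B, F, D, H, W), (x, w, b))

    def bw(g):
        gmat = g.reshape(B, F, D * H * W).transpose(0, 2, 1)  # (B,P,F)
        w._accum(np.einsum("bpf,bpi->fi", gmat, cols).reshape(w.data.shape))
        b._accum(gmat.sum(axis=(0, 1)))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(B, D, H, W, C, k, k, k)
            dxp = np.zeros_like(xp)
            for di in range(k):
                for dj in range(k):
                    for dk in range(k):
                        dxp[:, :, di : di + D, dj : dj + H, dk : dk + W] += (
                            dcols[..., di, dj, dk].transpose(0, 4, 1, 2, 3)
                        )
            x._accum(dxp[:, :, pad : pad + D, pad : pad + H, pad : pad + W])

    out._backward = bw
    return out


def avg_pool2(x: Tensor) -> Tensor:
    B, C, D, H, W = x.data.shape
    v = x.data.reshape(B, C, D // 2, 2, H // 2, 2, W // 2, 2)
    out = Tensor(v.mean(axis=(3, 5, 7)), (x,))

    def bw(g):
        gx = np.repeat(np.repeat(np.repeat(g, 2, axis=2), 2, axis=3), 2, axis=4) / 8.0
        x._accum(gx)

    out._backward = bw
    return out


def upsample2(x: Tensor) -> Tensor:
    out_data = np.repeat(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), 2, axis=4)
    out = Tensor(out_data, (x,))
    B, C, D, H, W = x.data.shape

    def bw(g):
        x._accum(g.reshape(B, C, D, 2, H, 2, W, 2).sum(axis=(3, 5, 7)))

    out._backward = bw
    return out


# -- layers --------------------------------------------------------------

class Module:
    def parameters(self):
        params = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_arrays(self, prefix=""):
        out = {}
        for name, v in vars(self).items():
            if isinstance(v, Parameter):
                out[prefix + name] = v.data
            elif isinstance(v, Module):
                out.update(v.state_arrays(prefix + name + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.state_arrays(f"{prefix}{name}.{i}."))
        return out

    def load_state_arrays(self, arrays, prefix=""):
        for name, v in vars(self).items():
            if isinstance(v, Parameter):
                v.data = np.asarray(arrays[prefix + name], dtype=np.float64)
            elif isinstance(v, Module):
                v.load_state_arrays(arrays, prefix + name + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_arrays(arrays, f"{prefix}{name}.{i}.")


_UPDATE_POWER_ITERATION = True


class frozen_power_iteration:
    """Context manager stopping spectral-norm power-iteration buffer updates
    (used for deterministic inference and finite-difference checks)."""

    def __enter__(self):
        global _UPDATE_POWER_ITERATION
        self._saved = _UPDATE_POWER_ITERATION
        _UPDATE_POWER_ITERATION = False

    def __exit__(self, *exc):
        global _UPDATE_POWER_ITERATION
        _UPDATE_POWER_ITERATION = self._saved


def _spectral_normalize(w: Parameter, u: np.ndarray):
    """One power iteration; returns (normalized weight tensor, updated u)."""
    wmat = w.data.reshape(w.data.shape[0], -1)
    v = wmat.T @ u
    v /= np.linalg.norm(v) + 1e-12
    u_new = wmat @ v
    u_new /= np.linalg.norm(u_new) + 1e-12
    if not _UPDATE_POWER_ITERATION:
        u_new = u
    # sigma = u^T W v as a graph node (u, v treated as constants)
    ut = Tensor(u_new[None, :])
    vt = Tensor(v[:, None])
    w2d = w.reshape(w.data.shape[0], -1)
    sigma = (ut @ w2d @ vt).reshape(())
    return scale_inv(w, sigma), u_new


class Dense(Module):
    def __init__(self, n_in, n_out, rng, spectral_norm=False):
        scale = np.sqrt(2.0 / n_in)
        self.w = Parameter(rng.normal(0.0, scale, size=(n_out, n_in)))
        self.b = Parameter(np.zeros(n_out))
        self.spectral_norm = spectral_norm
        self._u = rng.normal(size=n_out)
        self._u /= np.linalg.norm(self._u)

    def __call__(self, x: Tensor) -> Tensor:
        w = self.w
        if self.spectral_norm:
            w, self._u = _spectral_normalize(self.w, self._u)
        return x @ w.reshape(*self.w.data.shape).T_() + self.b


# Tensor transpose helper for 2D weights
def _t2(self):
    out = Tensor(self.data.T, (self,))
    out._backward = lambda g: self._accum(g.T)
    return out


Tensor.T_ = _t2


class Conv3d(Module):
    def __init__(self, c_in, c_out, rng, k=3, spectral_norm=False):
        scale = np.sqrt(2.0 / (c_in * k**3))
        self.w = Parameter(rng.normal(0.0, scale, size=(c_out, c_in, k, k, k)))
        self.b = Parameter(np.zeros(c_out))
        self.pad = k // 2
        self.spectral_norm = spectral_norm
        self._u = rng.normal(size=c_out)
        self._u /= np.linalg.norm(self._u)

    def __call__(self, x: Tensor) -> Tensor:
        w = self.w
        if self.spectral_norm:
            w, self._u = _spectral_normalize(self.w, self._u)
            w = w.reshape(*self.w.data.shape)
        return conv3d(x, w, self.b, pad=self.pad)


class ConvBlock(Module):
    """conv -> leaky ReLU, with an identity residual when channels match."""

    def __init__(self, c_in, c_out, rng, spectral_norm=False):
        self.conv = Conv3d(c_in, c_out, rng, spectral_norm=spectral_norm)
        self.residual = c_in == c_out

    def __call__(self, x: Tensor) -> Tensor:
        out = leaky_relu(self.conv(x))
        if self.residual:
            out = out + x
        return out


class RMSprop:
    def __init__(self, params, lr=1e-5, alpha=0.99, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self.cache = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, c in zip(self.params, self.cache):
            if p.grad is None:
                continue
            c *= self.alpha
            c += (1.0 - self.alpha) * p.grad**2
            p.data -= self.lr * p.grad / (np.sqrt(c) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
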