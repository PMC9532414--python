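"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: each operation records its parents
and a closure that maps the output gradient onto parent gradients.  All
arrays are float32; shapes follow the NCHW convention used by the network
layers built on top of this module.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


class no_grad:
    """Context manager that disables graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # ------------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of `self` w.r.t. every upstream tensor."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float32)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)
        # free the tape
        for t in topo:
            t._parents = ()
            t._backward = None

    # ------------------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __truediv__(self, other):
        other = _as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_as_tensor(other), power(self, -1.0))

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    g = g.astype(np.float32, copy=False)
    if t.grad is None:
        t.grad = g.copy() if g.base is not None else g
    else:
        t.grad = t.grad + g


# ----------------------------------------------------------------------
# elementwise / reduction primitives
# ----------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), bwd)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def bwd(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), bwd)


def power(a, exponent: float) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data ** np.float32(exponent)

    def bwd(g):
        _accum(a, g * exponent * a.data ** np.float32(exponent - 1))

    return _make(out_data, (a,), bwd)


def log(a) -> Tensor:
    a = _as_tensor(a)

    def bwd(g):
        _accum(a, g / a.data)

    return _make(np.log(a.data), (a,), bwd)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes through only inside the interval."""
    a = _as_tensor(a)
    inside = (a.data >= lo) & (a.data <= hi)

    def bwd(g):
        _accum(a, g * inside)

    return _make(np.clip(a.data, lo, hi), (a,), bwd)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0

    def bwd(g):
        _accum(a, g * mask)

    return _make(a.data * mask, (a,), bwd)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    # numerically stable logistic
    s = np.empty_like(a.data)
    pos = a.data >= 0
    s[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    ex = np.exp(a.data[~pos])
    s[~pos] = ex / (1.0 + ex)

    def bwd(g):
        _accum(a, g * s * (1.0 - s))

    return _make(s, (a,), bwd)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)

    def bwd(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g, a.data.shape))

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in np.atleast_1d(axis)])
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    old = a.data.shape

    def bwd(g):
        _accum(a, g.reshape(old))

    return _make(a.data.reshape(shape), (a,), bwd)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), bwd)


# ----------------------------------------------------------------------
# spatial primitives (NCHW)
# ----------------------------------------------------------------------

def conv2d(x, w, b=None, padding: int = 1) -> Tensor:
    """2D convolution, stride 1, zero padding (``same`` for odd kernels)."""
    x, w = _as_tensor(x), _as_tensor(w)
    n, c, h, wd = x.data.shape
    f, cw, kh, kw = w.data.shape
    if cw != c:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    ho, wo = win.shape[2], win.shape[3]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n, ho * wo, c * kh * kw)
    w2d = w.data.reshape(f, -1)
    out = cols @ w2d.T                       # (n, ho*wo, f)
    out = out.transpose(0, 2, 1).reshape(n, f, ho, wo)
    if b is not None:
        b = _as_tensor(b)
        out = out + b.data.reshape(1, f, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gm = g.reshape(n, f, ho * wo).transpose(0, 2, 1)   # (n, p, f)
        if w.requires_grad:
            dw = np.tensordot(gm, cols, axes=([0, 1], [0, 1]))  # (f, c*kh*kw)
            _accum(w, dw.reshape(w.data.shape))
        if x.requires_grad:
            dcols = gm @ w2d                                # (n, p, c*kh*kw)
            dcols = dcols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + ho, j:j + wo] += dcols[:, :, i, j]
            _accum(x, dxp[:, :, padding:padding + h, padding:padding + wd])
        if b is not None:
            _accum(b, g.sum(axis=(0, 2, 3)))

    return _make(out, parents, bwd)


def conv_transpose2d(x, w, b=None) -> Tensor:
    """Transpose convolution, kernel 2x2, stride 2 (exact x2 upsampling).

    Weight layout (c_in, c_out, 2, 2); input blocks do not overlap in the
    output, so forward and backward are plain tensor contractions.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    n, c, h, wd = x.data.shape
    cw, f, kh, kw = w.data.shape
    if cw != c:
        raise ValueError(f"conv_transpose2d: input {c} channels, weight expects {cw}")
    x2 = np.ascontiguousarray(x.data.transpose(0, 2, 3, 1)).reshape(n * h * wd, c)
    w2 = w.data.reshape(c, f * kh * kw)
    blocks = (x2 @ w2).reshape(n, h, wd, f, kh, kw)
    out = np.ascontiguousarray(blocks.transpose(0, 3, 1, 4, 2, 5)).reshape(
        n, f, h * kh, wd * kw)
    if b is not None:
        b = _as_tensor(b)
        out = out + b.data.reshape(1, f, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gb = g.reshape(n, f, h, kh, wd, kw)
        g2 = np.ascontiguousarray(gb.transpose(0, 2, 4, 1, 3, 5)).reshape(
            n * h * wd, f * kh * kw)
        if x.requires_grad:
            dx = (g2 @ w2.T).reshape(n, h, wd, c).transpose(0, 3, 1, 2)
            _accum(x, np.ascontiguousarray(dx))
        if w.requires_grad:
            _accum(w, (x2.T @ g2).reshape(w.data.shape))
        if b is not None:
            _accum(b, g.sum(axis=(0, 2, 3)))

    return _make(out, parents, bwd)


def max_pool2d(x) -> Tensor:
    """2x2 max pooling, stride 2; spatial dims must be even."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2d: spatial dims must be even, got {h}x{w}")
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    flat = r.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[..., None], g[..., None], axis=-1)
        dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        _accum(x, dx.reshape(n, c, h, w))

    return _make(out, (x,), bwd)


def batch_norm(x, gamma, beta, running_mean, running_var,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (N, H, W).

    `running_mean`/`running_var` are plain numpy arrays owned by the layer
    and updated in place in training mode.
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    n, c, h, w = x.data.shape
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def bwd(g):
        if gamma.requires_grad:
            _accum(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            _accum(beta, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gx = g * gamma.data[None, :, None, None]
            if training:
                mean_g = gx.mean(axis=(0, 2, 3))
                mean_gx = (gx * xhat).mean(axis=(0, 2, 3))
                dx = (gx - mean_g[None, :, None, None]
                      - xhat * mean_gx[None, :, None, None]) * inv[None, :, None, None]
            else:
                dx = gx * inv[None, :, None, None]
            _accum(x, dx)

    return _make(out, (x, gamma, beta), bwd)
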