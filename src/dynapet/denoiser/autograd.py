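"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the convolutional denoising networks in this
package: tensors carrying a gradient, a dynamic tape, 2D convolution via
sliding windows and BLAS, pooling, bilinear upsampling, activations, and
an Adam optimizer.  Gradients are validated against central differences
in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "add", "sub", "mul", "div", "pow_", "sqrt", "mean", "relu",
    "prelu", "sigmoid", "conv2d", "maxpool2", "upsample_bilinear2",
    "concat", "narrow_channels", "mse", "Adam", "set_dtype",
]

#: Compute dtype; float32 keeps CPU training fast, float64 is used by the
#: gradient-check tests.
DTYPE = np.float32


def set_dtype(dtype) -> None:
    global DTYPE
    DTYPE = np.dtype(dtype).type
    _upsample_cache.clear()


class Tensor:
    """Array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
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
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # convenience operators
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return sub(self, other)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = True
    return out


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum gradient over axes that were broadcast to reach g.shape."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def bw(g):
        a._accum(_unbroadcast(g, a.shape))
        b._accum(_unbroadcast(g, b.shape))

    return _node(a.data + b.data, (a, b), bw)


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def bw(g):
        a._accum(_unbroadcast(g, a.shape))
        b._accum(_unbroadcast(-g, b.shape))

    return _node(a.data - b.data, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def bw(g):
        a._accum(_unbroadcast(g * b.data, a.shape))
        b._accum(_unbroadcast(g * a.data, b.shape))

    return _node(a.data * b.data, (a, b), bw)


def div(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def bw(g):
        a._accum(_unbroadcast(g / b.data, a.shape))
        b._accum(_unbroadcast(-g * a.data / b.data**2, b.shape))

    return _node(a.data / b.data, (a, b), bw)


def pow_(a, exponent: float) -> Tensor:
    a = _as_tensor(a)

    def bw(g):
        a._accum(g * exponent * a.data ** (exponent - 1))

    return _node(a.data**exponent, (a,), bw)


def sqrt(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.sqrt(a.data)

    def bw(g):
        a._accum(g * 0.5 / out_data)

    return _node(out_data, (a,), bw)


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.mean(axis=axis, keepdims=keepdims)
    count = a.data.size / out_data.size

    def bw(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.shape) / count)

    return _node(out_data, (a,), bw)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    pos = a.data > 0

    def bw(g):
        a._accum(g * pos)

    return _node(a.data * pos, (a,), bw)


def prelu(a, slope: Tensor) -> Tensor:
    """Parametric rectifier with a per-channel slope (axis 1 of NCHW)."""
    a = _as_tensor(a)
    s = slope.data.reshape(1, -1, 1, 1)
    pos = a.data > 0
    out_data = np.where(pos, a.data, s * a.data)

    def bw(g):
        a._accum(g * np.where(pos, 1.0, s))
        slope._accum((g * np.where(pos, 0.0, a.data)).sum(axis=(0, 2, 3)))

    return _node(out_data, (a, slope), bw)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    # evaluated on the negative half-axis to avoid overflow in exp
    e = np.exp(-np.abs(a.data))
    out_data = np.where(a.data >= 0, 1.0 / (1.0 + e), e / (1.0 + e))

    def bw(g):
        a._accum(g * out_data * (1 - out_data))

    return _node(out_data, (a,), bw)


def conv2d(x, w, b=None, pad: int = 1) -> Tensor:
    """2D convolution (cross-correlation), stride 1, NCHW layout.

    ``w`` has shape (F, C, kh, kw); same-padding for 3x3 when pad=1.
    Implemented as im2col + BLAS matmul.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    F, C, kh, kw = w.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    N = xp.shape[0]
    H, W = view.shape[2], view.shape[3]
    # (N, H, W, C, kh, kw) contiguous -> (N*H*W, C*kh*kw)
    cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)).reshape(N * H * W, C * kh * kw)
    wmat = w.data.reshape(F, C * kh * kw)
    out = cols @ wmat.T  # (N*H*W, F)
    if b is not None:
        out += b.data
    out_data = np.ascontiguousarray(out.reshape(N, H, W, F).transpose(0, 3, 1, 2))

    def bw(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * H * W, F)
        w._accum((gmat.T @ cols).reshape(F, C, kh, kw))
        if b is not None:
            b._accum(gmat.sum(axis=0))
        dview = (gmat @ wmat).reshape(N, H, W, C, kh, kw)
        dxp = np.zeros_like(xp)
        for di in range(kh):
            for dj in range(kw):
                dxp[:, :, di:di + H, dj:dj + W] += dview[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        if pad:
            dxp = dxp[:, :, pad:-pad, pad:-pad]
        x._accum(dxp)

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, bw)


def maxpool2(x) -> Tensor:
    """2x2 max pooling, stride 2; ties route to the first maximum."""
    x = _as_tensor(x)
    N, C, H, W = x.shape
    xr = x.data.reshape(N, C, H // 2, 2, W // 2, 2)
    windows = xr.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H // 2, W // 2, 4)
    idx = windows.argmax(axis=-1)
    out_data = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        dwin = np.zeros((N, C, H // 2, W // 2, 4))
        np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
        dx = dwin.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accum(dx.reshape(N, C, H, W))

    return _node(out_data, (x,), bw)


_upsample_cache: dict[int, np.ndarray] = {}


def _upsample_matrix(n: int) -> np.ndarray:
    """Dense (2n, n) bilinear x2 interpolation matrix (half-pixel centers)."""
    if n not in _upsample_cache:
        M = np.zeros((2 * n, n), dtype=DTYPE)
        for o in range(2 * n):
            src = (o + 0.5) / 2.0 - 0.5
            i0 = int(np.floor(src))
            frac = src - i0
            i0c = min(max(i0, 0), n - 1)
            i1c = min(max(i0 + 1, 0), n - 1)
            M[o, i0c] += 1 - frac
            M[o, i1c] += frac
        _upsample_cache[n] = M
    return _upsample_cache[n]


def upsample_bilinear2(x) -> Tensor:
    """Bilinear x2 upsampling (separable, half-pixel alignment)."""
    x = _as_tensor(x)
    N, C, H, W = x.shape
    Mr, Mc = _upsample_matrix(H), _upsample_matrix(W)
    out_data = Mr @ x.data @ Mc.T

    def bw(g):
        x._accum(Mr.T @ g @ Mc)

    return _node(out_data, (x,), bw)


def concat(a, b, axis: int = 1) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    na = a.shape[axis]

    def bw(g):
        ga, gb = np.split(g, [na], axis=axis)
        a._accum(ga)
        b._accum(gb)

    return _node(np.concatenate([a.data, b.data], axis=axis), (a, b), bw)


def narrow_channels(x, start: int, stop: int) -> Tensor:
    x = _as_tensor(x)

    def bw(g):
        gx = np.zeros_like(x.data)
        gx[:, start:stop] = g
        x._accum(gx)

    return _node(x.data[:, start:stop], (x,), bw)


def mse(pred, target) -> Tensor:
    """Mean squared error; target is treated as a constant."""
    pred = _as_tensor(pred)
    t = target.data if isinstance(target, Tensor) else np.asarray(target, float)
    diff = pred.data - t

    def bw(g):
        pred._accum(g * 2.0 * diff / diff.size)

    return _node(np.mean(diff**2), (pred,), bw)


class Adam:
    """Adaptive-moment optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
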