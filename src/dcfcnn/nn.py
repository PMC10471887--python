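"""Minimal convolutional-network layers with explicit backpropagation.

All layers operate on ``(N, C, H, W)`` float arrays. Convolutions are lowered
to matrix multiplications via im2col so the heavy lifting runs through BLAS.
Each layer implements ``forward`` / ``backward`` plus symbolic ``out_shape``
so network shapes and parameter counts can be derived without touching pixel
data. Everything is deterministic: randomness enters only through the
``numpy.random.Generator`` handed to ``initialize``.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ConfigError

__all__ = [
    "Parameter",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "SGD",
    "softmax",
    "cross_entropy_with_grad",
]


class Parameter:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = data
        self.grad = np.zeros_like(data)

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Parameter({self.name}, shape={self.data.shape})"


class Module:
    """Base class: children and parameters are registered explicitly."""

    def __init__(self):
        self._params: list[Parameter] = []
        self._children: list[Module] = []

    def register(self, child: "Module") -> "Module":
        self._children.append(child)
        return child

    def add_param(self, name: str, data: np.ndarray) -> Parameter:
        p = Parameter(name, data)
        self._params.append(p)
        return p

    def parameters(self) -> list[Parameter]:
        out = list(self._params)
        for c in self._children:
            out.extend(c.parameters())
        return out

    def param_count(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def initialize(self, rng: np.random.Generator) -> None:
        self._init_own(rng)
        for c in self._children:
            c.initialize(rng)

    def _init_own(self, rng: np.random.Generator) -> None:  # noqa: D401
        pass

    # subclasses implement forward(x, training=..., update_stats=...) and
    # backward(dout); shapes are (C, H, W) tuples for out_shape.
    def out_shape(self, in_shape):
        raise NotImplementedError


def _pair(v):
    return (v, v) if np.isscalar(v) else tuple(v)


def _conv_out(h, k, s, p):
    return (h + 2 * p - k) // s + 1


def im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """Lower ``(N,C,H,W)`` into ``(C*kh*kw, N*OH*OW)`` patch columns.

    The column-major-in-batch layout lets the convolution run as one large
    GEMM over every spatial position of every batch element.
    """
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = _conv_out(h, kh, stride, pad)
    ow = _conv_out(w, kw, stride, pad)
    cols6 = np.empty((c, kh, kw, n, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            view = x[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
            cols6[:, i, j] = view.transpose(1, 0, 2, 3)
    return cols6.reshape(c * kh * kw, n * oh * ow), oh, ow


def col2im(dcols, x_shape, kh, kw, stride, pad):
    """Adjoint of :func:`im2col`: scatter-add columns back onto the image."""
    n, c, h, w = x_shape
    oh = _conv_out(h, kh, stride, pad)
    ow = _conv_out(w, kw, stride, pad)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d6 = dcols.reshape(c, kh, kw, n, oh, ow)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += \
                d6[:, i, j].transpose(1, 0, 2, 3)
    if pad:
        return dxp[:, :, pad : pad + h, pad : pad + w]
    return dxp


class Conv2d(Module):
    """2-D convolution (cross-correlation) with optional bias."""

    def __init__(self, in_channels, out_channels, kernel_size, stride=1, padding=0,
                 bias=True, dtype=np.float32):
        super().__init__()
        if in_channels < 1 or out_channels < 1:
            raise ConfigError("channel counts must be >= 1")
        self.cin, self.cout = in_channels, out_channels
        self.k = int(kernel_size)
        self.stride, self.pad = int(stride), int(padding)
        self.w = self.add_param(
            "weight", np.zeros((out_channels, in_channels, self.k, self.k), dtype=dtype)
        )
        self.b = self.add_param("bias", np.zeros(out_channels, dtype=dtype)) if bias else None
        self._cache = None

    def _init_own(self, rng):
        fan_out = self.cout * self.k * self.k
        std = np.sqrt(2.0 / fan_out)
        self.w.data[...] = rng.normal(0.0, std, self.w.data.shape)

    def out_shape(self, in_shape):
        c, h, w = in_shape
        if c != self.cin:
            raise ConfigError(f"expected {self.cin} input channels, got {c}")
        return (self.cout, _conv_out(h, self.k, self.stride, self.pad),
                _conv_out(w, self.k, self.stride, self.pad))

    def forward(self, x, training=False, update_stats=True):
        n = x.shape[0]
        cols, oh, ow = im2col(x, self.k, self.k, self.stride, self.pad)
        wmat = self.w.data.reshape(self.cout, -1)
        out = wmat @ cols  # (cout, N*OH*OW) -- one large GEMM
        if self.b is not None:
            out += self.b.data[:, None]
        if training:
            self._cache = (x.shape, cols)
        return np.ascontiguousarray(
            out.reshape(self.cout, n, oh, ow).transpose(1, 0, 2, 3))

    def backward(self, dout):
        x_shape, cols = self._cache
        n, cout = dout.shape[:2]
        dflat = np.ascontiguousarray(dout.transpose(1, 0, 2, 3)).reshape(cout, -1)
        self.w.grad += (dflat @ cols.T).reshape(self.w.data.shape)
        if self.b is not None:
            self.b.grad += dflat.sum(axis=1)
        wmat = self.w.data.reshape(cout, -1)
        dcols = wmat.T @ dflat  # (C*k*k, N*OH*OW)
        self._cache = None
        return col2im(dcols, x_shape, self.k, self.k, self.stride, self.pad)


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, channels, eps=1e-5, momentum=0.1, dtype=np.float32):
        super().__init__()
        self.c = channels
        self.eps, self.momentum = eps, momentum
        self.gamma = self.add_param("gamma", np.ones(channels, dtype=dtype))
        self.beta = self.add_param("beta", np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, training=False, update_stats=True):
        if training:
            m = x.mean(axis=(0, 2, 3))
            v = x.var(axis=(0, 2, 3))
            if update_stats:
                mom = self.momentum
                n = x.shape[0] * x.shape[2] * x.shape[3]
                bessel = v * (n / max(n - 1, 1))
                self.running_mean += mom * (m - self.running_mean)
                self.running_var += mom * (bessel - self.running_var)
        else:
            m, v = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(v + self.eps)
        xhat = (x - m[None, :, None, None]) * inv[None, :, None, None]
        out = self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]
        if training:
            self._cache = (xhat, inv)
        return out

    def backward(self, dout):
        xhat, inv = self._cache
        self._cache = None
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None]
        dxhat = dout * g
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (dxhat - s1 / n - xhat * s2 / n) * inv[None, :, None, None]


class ReLU(Module):
    def __init__(self):
        super().__init__()
        self._mask = None

    def out_shape(self, in_shape):
        return in_shape

    def forward(self, x, training=False, update_stats=True):
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, dout):
        mask, self._mask = self._mask, None
        return dout * mask


class MaxPool2d(Module):
    def __init__(self, kernel_size, stride, padding=0):
        super().__init__()
        self.k, self.stride, self.pad = kernel_size, stride, padding
        self._cache = None

    def out_shape(self, in_shape):
        c, h, w = in_shape
        return (c, _conv_out(h, self.k, self.stride, self.pad),
                _conv_out(w, self.k, self.stride, self.pad))

    def forward(self, x, training=False, update_stats=True):
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf) if p else x
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (N,C,OH,OW,k,k)
        flat = win.reshape(*win.shape[:4], k * k)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (x.shape, arg)
        return out

    def backward(self, dout):
        (x_shape, arg), self._cache = self._cache, None
        k, s, p = self.k, self.stride, self.pad
        n, c, h, w = x_shape
        oh, ow = dout.shape[2], dout.shape[3]
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dout.dtype)
        for idx in range(k * k):
            i, j = divmod(idx, k)
            contrib = np.where(arg == idx, dout, 0.0)
            dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += contrib
        if p:
            return dxp[:, :, p : p + h, p : p + w]
        return dxp


class GlobalAvgPool(Module):
    """Adaptive average pooling to 1x1, returned flattened as (N, C)."""

    def __init__(self):
        super().__init__()
        self._hw = None

    def out_shape(self, in_shape):
        c, _, _ = in_shape
        return (c,)

    def forward(self, x, training=False, update_stats=True):
        if training:
            self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        h, w = self._hw
        self._hw = None
        return np.broadcast_to(dout[:, :, None, None] / (h * w),
                               (*dout.shape, h, w)).copy()


class Linear(Module):
    def __init__(self, in_features, out_features, dtype=np.float32):
        super().__init__()
        self.fin, self.fout = in_features, out_features
        self.w = self.add_param("weight", np.zeros((out_features, in_features), dtype=dtype))
        self.b = self.add_param("bias", np.zeros(out_features, dtype=dtype))
        self._x = None

    def _init_own(self, rng):
        bound = 1.0 / np.sqrt(self.fin)
        self.w.data[...] = rng.uniform(-bound, bound, self.w.data.shape)

    def out_shape(self, in_shape):
        return (self.fout,)

    def forward(self, x, training=False, update_stats=True):
        if training:
            self._x = x
        return x @ self.w.data.T + self.b.data

    def backward(self, dout):
        x, self._x = self._x, None
        self.w.grad += dout.T @ x
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.data


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = [self.register(l) for l in layers]

    def out_shape(self, in_shape):
        for l in self.layers:
            in_shape = l.out_shape(in_shape)
        return in_shape

    def forward(self, x, training=False, update_stats=True):
        for l in self.layers:
            x = l.forward(x, training=training, update_stats=update_stats)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class SGD:
    """Stochastic gradient descent with momentum and L2 weight decay.

    Update rule (momentum buffer ``v``): ``v <- mu*v + (g + wd*w)``,
    ``w <- w - lr*v`` — the convention used by mainstream deep-learning
    frameworks, applied to every trainable tensor.
    """

    def __init__(self, params, lr=1e-3, momentum=0.9, weight_decay=1e-6):
        if lr < 0 or momentum < 0 or weight_decay < 0:
            raise ConfigError("optimizer rates must be non-negative")
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._buf = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        if self.lr == 0.0:
            return
        for p, v in zip(self.params, self._buf):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_with_grad(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy over integer labels and its gradient w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = np.finfo(p.dtype).tiny
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits /= n
    return float(loss), dlogits
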