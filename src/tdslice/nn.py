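"""Minimal NumPy neural-network core: layers with explicit forward/backward
passes and an Adam optimiser.

Scope is deliberately small — exactly what the slice-stack classifier needs:
3x3 same-padding convolution (im2col), ReLU, 2x2 max/average pooling, dense
layers and a sequential container.  All layers treat the leading axis as the
batch (here: slices of one exam), cache what backward needs during forward,
and accumulate parameter gradients in ``Param.grad``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ReLU",
    "MaxPool2d",
    "AvgPool2d",
    "GlobalAvgPool",
    "VecNorm",
    "Linear",
    "Sequential",
    "Adam",
    "softmax",
]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 (or k x k) convolution with same padding, stride 1, via im2col."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (cin * k * k))  # He initialisation
        self.w = Param((rng.standard_normal((cin * k * k, cout)) * std).astype(dtype))
        self.b = Param(np.zeros(cout, dtype=dtype))
        self.cin, self.cout, self.k = cin, cout, k
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.k
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        # windows: (n, c, h, w, k, k) -> cols (n*h*w, c*k*k)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        cols = np.ascontiguousarray(cols)
        out = cols @ self.w.value + self.b.value
        self._cache = (cols, x.shape)
        return out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, c, h, w = xshape
        k, pad = self.k, self.k // 2
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.cout)
        self.w.grad += cols.T @ dflat
        self.b.grad += dflat.sum(axis=0)
        dcols = dflat @ self.w.value.T  # (n*h*w, c*k*k)
        dcols = dcols.reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dout.dtype)
        # scatter-add each of the k*k taps back onto the padded input
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di : di + h, dj : dj + w] += dcols[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, pad : pad + h, pad : pad + w]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def forward(self, x):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial dims must be divisible by 2 for pooling")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return xr.max(axis=-1)

    def backward(self, dout):
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class AvgPool2d(Layer):
    """f x f average pooling, stride f (used as a fixed downsampling stem)."""

    def __init__(self, f: int = 2):
        self.f = f

    def forward(self, x):
        n, c, h, w = x.shape
        f = self.f
        if h % f or w % f:
            raise ValueError(f"spatial dims must be divisible by {f}")
        self._shape = x.shape
        return x.reshape(n, c, h // f, f, w // f, f).mean(axis=(3, 5))

    def backward(self, dout):
        n, c, h, w = self._shape
        f = self.f
        d = np.repeat(np.repeat(dout, f, axis=2), f, axis=3) / (f * f)
        return d.astype(dout.dtype)


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) mean over the spatial axes."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class VecNorm(Layer):
    """Parameter-free layer normalisation of a single vector: centre and
    scale to unit variance.  Bounds the scale of what reaches the classifier
    head, so logits cannot run away however large the pooled features grow."""

    def __init__(self, eps: float = 1e-5):
        self.eps = eps

    def forward(self, x):
        mu = x.mean()
        xc = x - mu
        self.sigma = np.sqrt((xc * xc).mean() + self.eps)
        self.y = xc / self.sigma
        return self.y

    def backward(self, dout):
        y = self.y
        return (dout - dout.mean() - y * (dout * y).mean()) / self.sigma


class Linear(Layer):
    def __init__(self, fin: int, fout: int, rng=None, dtype=np.float32,
                 init_scale: float | None = None):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / fin) if init_scale is None else init_scale
        self.w = Param((rng.standard_normal((fin, fout)) * std).astype(dtype))
        self.b = Param(np.zeros(fout, dtype=dtype))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout):
        x = np.atleast_2d(self._x)
        d = np.atleast_2d(dout)
        self.w.grad += x.T @ d
        self.b.grad += d.sum(axis=0)
        out = d @ self.w.value.T
        return out[0] if np.ndim(self._x) == 1 else out


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class Adam:
    """Adaptive-moment-estimation optimiser with decoupled weight decay.

    Decay acts directly on the weights (AdamW convention), independent of
    the gradient scale.  Besides its usual regularising role it provides a
    restoring force out of saturated-logit states, where losses without a
    log barrier produce vanishing gradients.
    """

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            upd = self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay:
                upd = upd + self.lr * self.weight_decay * p.value
            p.value -= upd.astype(p.value.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
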