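"""Numpy layers with hand-written backward passes.

All layers operate on ``float32`` arrays in ``(N, C, H, W)`` layout.  Each
layer exposes ``forward(x, train)``, ``backward(dout)`` and ``params()``
(a list of :class:`Param` handles the optimizer updates in place).

Convolutions are stride-1 with zero padding chosen so the spatial size is
preserved; dilation spaces the kernel taps ``r`` pixels apart (atrous
convolution).  The dilated forward/backward is expressed as a sum of
shifted slices contracted with ``einsum``, which keeps the cost independent
of the (possibly very large) pad introduced by high dilation rates.
"""

from __future__ import annotations

import numpy as np

from ..netspec import LayerSpec


class Param:
    """A learnable array together with its gradient and optimizer state."""

    __slots__ = ("name", "value", "grad", "velocity", "weight_decay")

    def __init__(self, name: str, value: np.ndarray, weight_decay: bool = True):
        self.name = name
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.velocity = np.zeros_like(self.value)
        # biases / norm parameters are conventionally excluded from L2
        self.weight_decay = weight_decay


class Layer:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def layer_specs(self) -> list[LayerSpec]:
        return []


class Conv2d(Layer):
    """Stride-1 'same' 2-D convolution with dilation.

    Weights are He-initialized from the layer's fan-in.  ``kernel`` may be
    an int or ``(kh, kw)``; both kernel dimensions must be odd so the
    anchor is centered.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel=3,
                 dilation: int = 1, rng: np.random.Generator | None = None,
                 name: str = "conv"):
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("kernel dimensions must be odd")
        if dilation < 1:
            raise ValueError("dilation rate must be >= 1")
        self.in_channels, self.out_channels = int(in_channels), int(out_channels)
        self.kh, self.kw, self.dilation = kh, kw, int(dilation)
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kh * kw
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels, kh, kw))
        self.W = Param(f"{name}.W", w)
        self.b = Param(f"{name}.b", np.zeros(out_channels), weight_decay=False)
        self.name = name
        self._xp: np.ndarray | None = None

    def forward(self, x, train=True):
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"channel mismatch: input has {x.shape[1]} channels, "
                f"kernel expects {self.in_channels}")
        n, _, h, w = x.shape
        r = self.dilation
        ph, pw = (self.kh - 1) // 2 * r, (self.kw - 1) // 2 * r
        xp = np.pad(x.astype(np.float32, copy=False), ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        self._xp = xp
        self._in_shape = x.shape
        out = np.broadcast_to(
            self.b.value[None, :, None, None], (n, self.out_channels, h, w)
        ).astype(np.float32).copy()
        wv = self.W.value
        for i in range(self.kh):
            for j in range(self.kw):
                s = xp[:, :, i * r:i * r + h, j * r:j * r + w]
                out += np.einsum("nchw,oc->nohw", s, wv[:, :, i, j], optimize=True)
        return out

    def backward(self, dout):
        assert self._xp is not None, "forward must run before backward"
        n, _, h, w = self._in_shape
        r = self.dilation
        xp = self._xp
        dxp = np.zeros_like(xp)
        wv = self.W.value
        dW = self.W.grad
        dW[...] = 0.0
        for i in range(self.kh):
            for j in range(self.kw):
                s = xp[:, :, i * r:i * r + h, j * r:j * r + w]
                dW[:, :, i, j] = np.einsum("nohw,nchw->oc", dout, s, optimize=True)
                dxp[:, :, i * r:i * r + h, j * r:j * r + w] += np.einsum(
                    "nohw,oc->nchw", dout, wv[:, :, i, j], optimize=True)
        self.b.grad[...] = dout.sum(axis=(0, 2, 3))
        ph, pw = (self.kh - 1) // 2 * r, (self.kw - 1) // 2 * r
        self._xp = None
        return dxp[:, :, ph:ph + h, pw:pw + w]

    def params(self):
        return [self.W, self.b]

    def layer_specs(self):
        return [LayerSpec(kind="conv", kernel=(self.kh, self.kw),
                          in_channels=self.in_channels, out_channels=self.out_channels,
                          dilation=self.dilation, name=self.name)]


class BatchNorm2d(Layer):
    """Per-channel batch normalization with learnable scale/shift."""

    def __init__(self, n_features: int, eps: float = 1e-5, momentum: float = 0.1,
                 name: str = "bn"):
        self.n_features = int(n_features)
        self.eps, self.momentum = float(eps), float(momentum)
        self.gamma = Param(f"{name}.gamma", np.ones(n_features), weight_decay=False)
        self.beta = Param(f"{name}.beta", np.zeros(n_features), weight_decay=False)
        self.running_mean = np.zeros(n_features, dtype=np.float32)
        self.running_var = np.ones(n_features, dtype=np.float32)
        self.name = name

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return (self.gamma.value[None, :, None, None] * xhat
                + self.beta.value[None, :, None, None]).astype(np.float32)

    def backward(self, dout):
        xhat, inv, train, shape = self._cache
        n, _, h, w = shape
        m = n * h * w
        self.gamma.grad[...] = (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad[...] = dout.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not train:
            return (dout * g * inv[None, :, None, None]).astype(np.float32)
        dxhat = dout * g
        term1 = dxhat
        term2 = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        term3 = xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return ((term1 - term2 - term3) * inv[None, :, None, None]).astype(np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def layer_specs(self):
        return [LayerSpec(kind="batchnorm", n_features=self.n_features, name=self.name)]


class LeakyReLU(Layer):
    """max(x, s*x): negatives are scaled by the fixed slope ``s``."""

    def __init__(self, slope: float = 0.3, name: str = "leakyrelu"):
        self.slope = float(slope)
        self.name = name

    def forward(self, x, train=True):
        self._neg = x < 0
        out = x.copy()
        out[self._neg] *= self.slope
        return out

    def backward(self, dout):
        dx = dout.copy()
        dx[self._neg] *= self.slope
        return dx

    def layer_specs(self):
        return [LayerSpec(kind="activation", name=self.name)]


class MaxPool2d(Layer):
    """Non-overlapping max pooling (kernel == stride)."""

    def __init__(self, size: int = 2, name: str = "pool"):
        self.size = int(size)
        self.name = name

    def forward(self, x, train=True):
        k = self.size
        n, c, h, w = x.shape
        if h % k or w % k:
            raise ValueError(f"spatial size {(h, w)} not divisible by pool size {k}")
        xr = x.reshape(n, c, h // k, k, w // k, k).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // k, w // k, k * k)
        self._argmax = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return xr.max(axis=-1)

    def backward(self, dout):
        k = self.size
        n, c, h, w = self._in_shape
        dxr = np.zeros((n, c, h // k, w // k, k * k), dtype=np.float32)
        np.put_along_axis(dxr, self._argmax[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // k, w // k, k, k).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)

    def layer_specs(self):
        return [LayerSpec(kind="pool", kernel=(self.size, self.size),
                          stride=self.size, name=self.name)]


class GlobalAvgPool(Layer):
    """Average over the spatial extent; (N,C,H,W) -> (N,C)."""

    def forward(self, x, train=True):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._in_shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w), self._in_shape).astype(np.float32)

    def layer_specs(self):
        return [LayerSpec(kind="globalavgpool", name="gap")]


class Dense(Layer):
    def __init__(self, units_in: int, units_out: int,
                 rng: np.random.Generator | None = None, name: str = "dense"):
        rng = rng or np.random.default_rng(0)
        self.units_in, self.units_out = int(units_in), int(units_out)
        w = rng.normal(0.0, np.sqrt(2.0 / units_in), size=(units_in, units_out))
        self.W = Param(f"{name}.W", w)
        self.b = Param(f"{name}.b", np.zeros(units_out), weight_decay=False)
        self.name = name

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad[...] = self._x.T @ dout
        self.b.grad[...] = dout.sum(axis=0)
        return dout @ self.W.value.T

    def params(self):
        return [self.W, self.b]

    def layer_specs(self):
        return [LayerSpec(kind="dense", units_in=self.units_in,
                          units_out=self.units_out, name=self.name)]
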