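"""Minimal neural-network layers on numpy arrays with hand-written backprop.

All activations use channel-last layout ``(N, H, W, C)`` so that the public
``H x W x K`` response-map convention is the native one and convolutions reduce
to contiguous matrix products.  Every layer caches what its backward pass needs
during ``forward(..., train=True)``; ``backward`` accumulates parameter
gradients in ``Param.grad`` and returns the gradient w.r.t. its input.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "ChannelSoftmax",
    "Sequential",
]


class Param:
    """A learnable tensor with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = data
        self.grad = np.zeros_like(data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.forward(x, train=train)


def he_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d(Layer):
    """k x k convolution, stride 1, 'same' zero padding (k odd) or no padding (k=1)."""

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int = 3, *,
                 rng: np.random.Generator, dtype=np.float32):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        k = kernel_size
        self.k = k
        self.pad = k // 2
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.w = Param(he_init(rng, (k, k, in_ch, out_ch), fan_in=k * k * in_ch, dtype=dtype), "conv.w")
        self.b = Param(np.zeros(out_ch, dtype=dtype), "conv.b")
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        n, h, w_, c = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        p, k = self.pad, self.k
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        y = np.empty((n, h, w_, self.out_ch), dtype=x.dtype)
        y[...] = self.b.data
        for di in range(k):
            for dj in range(k):
                xs = xp[:, di:di + h, dj:dj + w_, :].reshape(-1, c)
                y += (xs @ self.w.data[di, dj]).reshape(n, h, w_, self.out_ch)
        if train:
            self._cache = (x.shape, xp)
        return y

    def backward(self, dy):
        x_shape, xp = self._cache
        n, h, w_, c = x_shape
        p, k = self.pad, self.k
        dyf = dy.reshape(-1, self.out_ch)
        self.b.grad += dy.sum(axis=(0, 1, 2))
        dxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                xs = xp[:, di:di + h, dj:dj + w_, :].reshape(-1, c)
                self.w.grad[di, dj] += xs.T @ dyf
                dxp[:, di:di + h, dj:dj + w_, :] += (dyf @ self.w.data[di, dj].T).reshape(n, h, w_, c)
        return dxp[:, p:p + h, p:p + w_, :] if p else dxp


class ConvTranspose2d(Layer):
    """2x2 transposed convolution with stride 2 (learnable x2 up-sampling)."""

    def __init__(self, in_ch: int, out_ch: int, *, rng: np.random.Generator, dtype=np.float32):
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.w = Param(he_init(rng, (2, 2, in_ch, out_ch), fan_in=in_ch, dtype=dtype), "upconv.w")
        self.b = Param(np.zeros(out_ch, dtype=dtype), "upconv.b")
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        n, h, w_, c = x.shape
        y = np.empty((n, 2 * h, 2 * w_, self.out_ch), dtype=x.dtype)
        xf = x.reshape(-1, c)
        for di in range(2):
            for dj in range(2):
                y[:, di::2, dj::2, :] = (xf @ self.w.data[di, dj]).reshape(n, h, w_, self.out_ch)
        y += self.b.data
        if train:
            self._cache = x
        return y

    def backward(self, dy):
        x = self._cache
        n, h, w_, c = x.shape
        xf = x.reshape(-1, c)
        self.b.grad += dy.sum(axis=(0, 1, 2))
        dx = np.zeros_like(x)
        dxf = dx.reshape(-1, c)
        for di in range(2):
            for dj in range(2):
                dys = dy[:, di::2, dj::2, :].reshape(-1, self.out_ch)
                self.w.grad[di, dj] += xf.T @ dys
                dxf += dys @ self.w.data[di, dj].T
        return dx


class BatchNorm2d(Layer):
    """Per-channel batch normalization over the (N, H, W) axes."""

    def __init__(self, ch: int, *, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Param(np.ones(ch, dtype=dtype), "bn.gamma")
        self.beta = Param(np.zeros(ch, dtype=dtype), "bn.beta")
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(x.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        y = self.gamma.data * xhat + self.beta.data
        if train:
            self._cache = (xhat, inv_std.astype(x.dtype))
        return y

    def backward(self, dy):
        xhat, inv_std = self._cache
        axes = (0, 1, 2)
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self.gamma.data
        m = dxhat.mean(axis=axes)
        mx = (dxhat * xhat).mean(axis=axes)
        return inv_std * (dxhat - m - xhat * mx)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=True):
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy):
        return dy * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; ties resolve to the first window element."""

    def forward(self, x, train=True):
        n, h, w_, c = x.shape
        if h % 2 or w_ % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w_}")
        xq = x.reshape(n, h // 2, 2, w_ // 2, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(
            n, h // 2, w_ // 2, c, 4)
        idx = xq.argmax(axis=-1)
        y = np.take_along_axis(xq, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (x.shape, idx)
        return y

    def backward(self, dy):
        (n, h, w_, c), idx = self._cache
        dxq = np.zeros((n, h // 2, w_ // 2, c, 4), dtype=dy.dtype)
        np.put_along_axis(dxq, idx[..., None], dy[..., None], axis=-1)
        return dxq.reshape(n, h // 2, w_ // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(n, h, w_, c)


class ChannelSoftmax(Layer):
    """Per-pixel softmax over the channel axis (probabilities summing to 1)."""

    def forward(self, x, train=True):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)
        if train:
            self._p = p
        return p

    def backward(self, dy):
        p = self._p
        return p * (dy - (dy * p).sum(axis=-1, keepdims=True))


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy
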