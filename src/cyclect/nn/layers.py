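"""Minimal layer zoo for the 3D cycle-GAN networks.

Layers are stateless with respect to activations: ``forward(x)`` returns
``(y, cache)`` and ``backward(dy, cache)`` returns ``dx`` while accumulating
parameter gradients in-place.  Passing caches around (rather than storing
them on the layer) lets a single generator instance participate in several
concurrent forward passes per iteration, which the cycle objective needs.
"""

from __future__ import annotations

import numpy as np

from . import functional as F

F32 = np.float32

__all__ = [
    "Parameter",
    "Layer",
    "Conv3d",
    "ConvTranspose3d",
    "ReflectionPad3d",
    "InstanceNorm3d",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "Sigmoid",
    "Residual",
    "Sequential",
]


class Parameter:
    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.ascontiguousarray(data, dtype=F32)
        self.grad = np.zeros_like(self.data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray):  # -> (y, cache)
        raise NotImplementedError

    def backward(self, dy: np.ndarray, cache):  # -> dx
        raise NotImplementedError


def _init_conv_weight(shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    # zero-mean Gaussian, sd 0.02: the vanilla cycle-GAN initialization
    return rng.normal(0.0, 0.02, size=shape).astype(F32)


class Conv3d(Layer):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng()
        self.stride, self.pad = stride, pad
        self.w = Parameter(_init_conv_weight((c_out, c_in, kernel, kernel, kernel), rng), "conv.w")
        self.b = Parameter(np.zeros(c_out), "conv.b") if bias else None

    def parameters(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x):
        y, xp = F.conv3d_forward(x, self.w.data, self.b.data if self.b else None, self.stride, self.pad)
        return y, xp

    def backward(self, dy, xp, need_dx: bool = True):
        dx, dw, db = F.conv3d_backward(dy, xp, self.w.data, self.stride, self.pad, need_dx)
        self.w.grad += dw
        if self.b is not None:
            self.b.grad += db
        return dx


class ConvTranspose3d(Layer):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int = 3,
        stride: int = 2,
        pad: int = 1,
        opad: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng()
        self.kernel, self.stride, self.pad, self.opad = kernel, stride, pad, opad
        self.w = Parameter(_init_conv_weight((c_in, c_out, kernel, kernel, kernel), rng), "convT.w")
        self.b = Parameter(np.zeros(c_out), "convT.b") if bias else None

    def parameters(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=F32)
        y = F.conv_transpose3d_forward(
            x, self.w.data, self.b.data if self.b else None, self.stride, self.pad, self.opad
        )
        return y, x

    def backward(self, dy, x):
        dx, dw, db = F.conv_transpose3d_backward(dy, x, self.w.data, self.stride, self.pad, self.opad)
        self.w.grad += dw
        if self.b is not None:
            self.b.grad += db
        return dx


class ReflectionPad3d(Layer):
    def __init__(self, pad: int) -> None:
        self.padn = pad

    def forward(self, x):
        return F.reflection_pad3d(x, self.padn), None

    def backward(self, dy, cache):
        return F.reflection_pad3d_backward(dy, self.padn)


class InstanceNorm3d(Layer):
    """Per-channel normalization over the spatial grid (no affine terms)."""

    def __init__(self, eps: float = 1e-5) -> None:
        self.eps = eps

    def forward(self, x):
        c = x.shape[0]
        flat = x.reshape(c, -1)
        mu = flat.mean(axis=1, keepdims=True)
        var = flat.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        y = ((flat - mu) * inv).astype(F32).reshape(x.shape)
        return y, (y, inv.astype(F32))

    def backward(self, dy, cache):
        y, inv = cache
        c = dy.shape[0]
        dyf = dy.reshape(c, -1)
        yf = y.reshape(c, -1)
        m1 = dyf.mean(axis=1, keepdims=True)
        m2 = (dyf * yf).mean(axis=1, keepdims=True)
        dx = (dyf - m1 - yf * m2) * inv
        return dx.astype(F32).reshape(dy.shape)


class ReLU(Layer):
    def forward(self, x):
        y = np.maximum(x, 0.0)
        return y, (x > 0)

    def backward(self, dy, mask):
        return np.where(mask, dy, 0.0).astype(F32)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2) -> None:
        self.slope = slope

    def forward(self, x):
        pos = x > 0
        return np.where(pos, x, self.slope * x).astype(F32), pos

    def backward(self, dy, pos):
        return np.where(pos, dy, self.slope * dy).astype(F32)


class Tanh(Layer):
    def forward(self, x):
        y = np.tanh(x)
        return y.astype(F32), y

    def backward(self, dy, y):
        return (dy * (1.0 - y * y)).astype(F32)


class Sigmoid(Layer):
    def forward(self, x):
        y = 1.0 / (1.0 + np.exp(-x))
        return y.astype(F32), y

    def backward(self, dy, y):
        return (dy * y * (1.0 - y)).astype(F32)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def parameters(self):
        out: list[Parameter] = []
        for layer in self.layers:
            out.extend(layer.parameters())
        return out

    def forward(self, x):
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, dy, caches, need_input_grad: bool = True):
        stop = 0
        if not need_input_grad:
            # index of the deepest parameterized layer: below it nothing
            # accumulates gradients, so propagation can stop early
            while stop < len(self.layers) and not self.layers[stop].parameters():
                stop += 1
        for i in range(len(self.layers) - 1, -1, -1):
            if not need_input_grad and i < stop:
                return None
            layer, c = self.layers[i], caches[i]
            if not need_input_grad and i == stop and isinstance(layer, Conv3d):
                layer.backward(dy, c, need_dx=False)
                return None
            dy = layer.backward(dy, c)
        return dy


class Residual(Layer):
    """Residual unit: body(x) + x."""

    def __init__(self, body: Layer) -> None:
        self.body = body

    def parameters(self):
        return self.body.parameters()

    def forward(self, x):
        y, cache = self.body.forward(x)
        return (y + x).astype(F32), cache

    def backward(self, dy, cache):
        return (self.body.backward(dy, cache) + dy).astype(F32)
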