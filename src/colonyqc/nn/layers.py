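"""Layers with explicit forward/backward passes.

Convolution is im2col + matmul; its backward pass reuses the cached column
matrix for the weight gradient and scatter-adds over the k*k kernel offsets
for the input gradient.  All state needed by ``backward`` is cached on the
layer by the preceding ``forward(train=True)`` call, so each layer instance
belongs to exactly one network.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = ["Param", "Module", "Conv2d", "MaxPool2d", "ReLU", "Flatten",
           "Linear", "Sequential", "ResidualWrap", "he_uniform"]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


def he_uniform(shape: tuple[int, ...], fan_in: int,
               rng: np.random.Generator) -> np.ndarray:
    """He-uniform init: U(-sqrt(6/fan_in), +sqrt(6/fan_in)), for ReLU stacks."""
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Module:
    def parameters(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x, train=True):
        return self.forward(x, train)


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) column matrix for stride-1 convolution."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    sn, sc, sh, sw = x.strides
    view = as_strided(x, shape=(n, c, k, k, h, w), strides=(sn, sc, sh, sw, sh, sw))
    return view.reshape(n, c * k * k, h * w)


class Conv2d(Module):
    """Stride-1 'same' convolution with odd square kernels."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int,
                 rng: np.random.Generator, name: str = "conv",
                 zero_init: bool = False):
        assert ksize % 2 == 1
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, ksize
        self.pad = ksize // 2
        fan_in = in_ch * ksize * ksize
        w = (np.zeros((out_ch, fan_in)) if zero_init
             else he_uniform((out_ch, fan_in), fan_in, rng))
        self.w = Param(w, f"{name}.w")
        self.b = Param(np.zeros(out_ch), f"{name}.b")
        self._cols = None
        self._xshape = None

    def parameters(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        cols = _im2col(x, self.k, self.pad)           # (N, C*k*k, H*W)
        out = np.einsum("of,nfp->nop", self.w.value, cols, optimize=True)
        out += self.b.value[None, :, None]
        if train:
            self._cols, self._xshape = cols, x.shape
        return out.reshape(n, self.out_ch, h, w)

    def backward(self, grad):
        n, _, h, w = self._xshape
        g = grad.reshape(n, self.out_ch, h * w)       # (N, O, P)
        self.w.grad += np.einsum("nop,nfp->of", g, self._cols, optimize=True)
        self.b.grad += g.sum(axis=(0, 2))
        # input gradient: scatter the per-offset contributions back
        dcols = np.einsum("of,nop->nfp", self.w.value, g, optimize=True)
        dcols = dcols.reshape(n, self.in_ch, self.k, self.k, h, w)
        hp, wp = h + 2 * self.pad, w + 2 * self.pad
        dxp = np.zeros((n, self.in_ch, hp, wp))
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, i, j]
        self._cols = None
        if self.pad:
            return dxp[:, :, self.pad:-self.pad, self.pad:-self.pad]
        return dxp


class MaxPool2d(Module):
    """Non-overlapping k x k max pooling; requires H, W divisible by k."""

    def __init__(self, k: int):
        self.k = k
        self._argmax = None
        self._shape = None

    def forward(self, x, train=True):
        k = self.k
        n, c, h, w = x.shape
        assert h % k == 0 and w % k == 0, f"pool {k} does not divide {(h, w)}"
        v = x.reshape(n, c, h // k, k, w // k, k).transpose(0, 1, 2, 4, 3, 5)
        v = v.reshape(n, c, h // k, w // k, k * k)
        idx = v.argmax(axis=-1)
        out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
        if train:
            self._argmax, self._shape = idx, (n, c, h, w)
        return out

    def backward(self, grad):
        k = self.k
        n, c, h, w = self._shape
        dv = np.zeros((n, c, h // k, w // k, k * k))
        np.put_along_axis(dv, self._argmax[..., None], grad[..., None], axis=-1)
        dv = dv.reshape(n, c, h // k, w // k, k, k).transpose(0, 1, 2, 4, 3, 5)
        return dv.reshape(n, c, h, w)


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=True):
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class Flatten(Module):
    def __init__(self):
        self._shape = None

    def forward(self, x, train=True):
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, name: str = "fc"):
        self.w = Param(he_uniform((out_features, in_features), in_features, rng),
                       f"{name}.w")
        self.b = Param(np.zeros(out_features), f"{name}.b")
        self._x = None

    def parameters(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, grad):
        self.w.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value


class Sequential(Module):
    def __init__(self, layers: list[Module]):
        self.layers = list(layers)

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class ResidualWrap(Module):
    """y = main(x) + skip(x); gradients flow through both branches."""

    def __init__(self, main: Module, skip: Module):
        self.main = main
        self.skip = skip

    def parameters(self):
        return self.main.parameters() + self.skip.parameters()

    def forward(self, x, train=True):
        return self.main.forward(x, train) + self.skip.forward(x, train)

    def backward(self, grad):
        return self.main.backward(grad) + self.skip.backward(grad)
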