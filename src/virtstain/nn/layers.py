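"""Neural-network modules on top of the autodiff engine.

Convolutions are im2col + matmul; depthwise-separable convolution is a
per-channel spatial filter followed by a 1x1 pointwise mix, the Xception
factorization. Weight init follows the He/Kaiming fan-in recipe with a
seeded generator so builds are reproducible.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Parameter, Tensor, concat

__all__ = [
    "Module",
    "Sequential",
    "Conv2d",
    "DepthwiseConv2d",
    "SepConv2d",
    "Linear",
    "InstanceNorm2d",
    "LeakyReLU",
    "ReLU",
    "Tanh",
    "Upsample2x",
    "AvgPool2d",
    "MaxPool2d",
    "conv_out_size",
]


def conv_out_size(size: int, kernel: int, stride: int, padding: int) -> int:
    return (size + 2 * padding - kernel) // stride + 1


class Module:
    """Minimal parameter-owning container with named state."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> Iterator[Parameter]:
        yield from self._params.values()
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for k, p in self._params.items():
            yield prefix + k, p
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix + k + ".")

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data[...] = state[k]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.items = list(modules)
        for i, m in enumerate(modules):
            setattr(self, f"m{i}", m)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.items:
            x = m(x)
        return x


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_he_init(rng, (out_ch, fan_in), fan_in))
        self.bias = Parameter(np.zeros((out_ch,))) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        if C != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {C}")
        oH = conv_out_size(H, self.kernel, self.stride, self.padding)
        oW = conv_out_size(W, self.kernel, self.stride, self.padding)
        col = x.im2col(self.kernel, self.stride, self.padding)
        out = (self.weight @ col).reshape((N, self.out_ch, oH, oW))
        if self.bias is not None:
            out = out + self.bias.reshape((1, self.out_ch, 1, 1))
        return out


class DepthwiseConv2d(Module):
    """Per-channel spatial convolution (groups = channels)."""

    def __init__(self, channels: int, kernel: int, stride: int = 1, padding: int = 0,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.channels, self.kernel, self.stride, self.padding = channels, kernel, stride, padding
        fan_in = kernel * kernel
        self.weight = Parameter(_he_init(rng, (channels, kernel * kernel), fan_in))
        self.bias = Parameter(np.zeros((channels,))) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        if C != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {C}")
        oH = conv_out_size(H, self.kernel, self.stride, self.padding)
        oW = conv_out_size(W, self.kernel, self.stride, self.padding)
        col = x.im2col(self.kernel, self.stride, self.padding)
        col = col.reshape((N, C, self.kernel * self.kernel, oH * oW))
        w = self.weight.reshape((1, C, self.kernel * self.kernel, 1))
        out = (col * w).sum(axis=2).reshape((N, C, oH, oW))
        if self.bias is not None:
            out = out + self.bias.reshape((1, C, 1, 1))
        return out


class SepConv2d(Module):
    """Depthwise-separable convolution: depthwise spatial, then pointwise 1x1."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        self.depthwise = DepthwiseConv2d(in_ch, kernel, stride, padding, bias=False, rng=rng)
        self.pointwise = Conv2d(in_ch, out_ch, 1, bias=bias, rng=rng)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return self.pointwise(self.depthwise(x))


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_he_init(rng, (in_f, out_f), in_f))
        self.bias = Parameter(np.zeros((out_f,)))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class InstanceNorm2d(Module):
    """Per-sample, per-channel spatial normalization (no affine terms)."""

    def __init__(self, eps: float = 1e-5):
        super().__init__()
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        cen = x - mu
        var = (cen ** 2.0).mean(axis=(2, 3), keepdims=True)
        return cen * ((var + self.eps) ** -0.5)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class Upsample2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.upsample2x()


class AvgPool2d(Module):
    """Window == stride pooling (the only variant the networks use)."""

    def __init__(self, window: int):
        super().__init__()
        self.window = window

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        w = self.window
        if H % w or W % w:
            raise ValueError(f"spatial size {(H, W)} not divisible by window {w}")
        return x.reshape((N, C, H // w, w, W // w, w)).mean(axis=(3, 5))


class MaxPool2d(Module):
    def __init__(self, window: int = 2):
        super().__init__()
        self.window = window

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        w = self.window
        if H % w or W % w:
            raise ValueError(f"spatial size {(H, W)} not divisible by window {w}")
        x = x.reshape((N, C, H // w, w, W // w, w))
        return x.max(axis=3).max(axis=4)


def channel_concat(tensors, ) -> Tensor:
    return concat(tensors, axis=1)
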