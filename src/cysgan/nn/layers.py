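"""Module / parameter containers built on :mod:`cysgan.nn.core`.

Mirrors the familiar layer API (Conv3d, InstanceNorm3d, BatchNorm3d,
activations, Sequential) at the scale this package needs. Parameters are
float32; initialisation draws from an explicit ``numpy.random.Generator``
so that network construction is reproducible from a seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import core
from .core import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32),
                         requires_grad=True)


class Module:
    """Base class: recursive parameter discovery and state (de)serialisation."""

    def __init__(self):
        self.training = True

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield path, v
            elif isinstance(v, Module):
                yield from v.named_parameters(prefix=path + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(
                            prefix=f"{path}.{i}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        """Non-trainable state (e.g. batch-norm running statistics)."""
        for name, v in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(v, Module):
                yield from v.named_buffers(prefix=path + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(prefix=f"{path}.{i}.")
            elif isinstance(v, np.ndarray) and name.startswith("running_"):
                yield path, v

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        state.update({k: v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        missing = (set(params) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"state dict missing keys: {sorted(missing)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = state[k].astype(np.float32).copy()
        for k, b in buffers.items():
            b[...] = state[k]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv3d(Module):
    """3D convolution with He-normal weight initialisation."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int | None = None,
                 rng: np.random.Generator | None = None, bias: bool = True):
        super().__init__()
        if padding is None:
            padding = kernel_size // 2
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size**3
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(
            0.0, std, size=(out_channels, in_channels,
                            kernel_size, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return core.conv3d(x, self.weight, self.bias,
                           stride=self.stride, padding=self.padding)


class InstanceNorm3d(Module):
    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        # instance norm behaves identically in train and eval mode
        return core.instance_norm(x, self.gamma, self.beta, eps=self.eps)


class BatchNorm3d(Module):
    """Single-device batch norm with running statistics for eval mode."""

    def __init__(self, channels: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            axes = (0, 2, 3, 4)
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            return core.batch_norm(x, self.gamma, self.beta, eps=self.eps)
        # eval: fixed per-channel affine map using the running statistics
        shape = (1, -1, 1, 1, 1)
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = (self.gamma.data * inv).reshape(shape)
        shift = (self.beta.data -
                 self.gamma.data * inv * self.running_mean).reshape(shape)
        scale_t = Tensor(np.broadcast_to(scale, x.data.shape)
                         .astype(x.data.dtype))
        shift_t = Tensor(np.broadcast_to(shift, x.data.shape)
                         .astype(x.data.dtype))
        return core.add(core.mul(x, scale_t), shift_t)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return core.leaky_relu(x, self.slope)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return core.tanh(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return core.sigmoid(x)


class UpsampleNearest2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return core.upsample_nearest2(x)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x
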