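"""Layer/module abstractions on top of the autodiff engine.

Mirrors the familiar Module/Parameter pattern: modules hold named
parameters and buffers, compose recursively, and expose ``state_dict`` /
``load_state_dict`` for checkpointing (saved as ``.npz`` by the training
engine).  Initialization is explicit: every module that owns weights takes
a ``numpy.random.Generator`` so a single master seed determines the whole
network.
"""

from __future__ import annotations

from typing import Dict, Iterator, Optional, Tuple

import numpy as np

from . import functional as F
from .tensor import DTYPE, Tensor

Triple = Tuple[int, int, int]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def kaiming(rng: np.random.Generator, shape, fan_in: int, slope: float = 0.01) -> np.ndarray:
    """He-style normal init with Leaky ReLU gain."""
    gain = np.sqrt(2.0 / (1.0 + slope ** 2))
    std = gain / np.sqrt(fan_in)
    return rng.normal(0.0, std, size=shape).astype(DTYPE)


class Module:
    def __init__(self):
        self.training = True

    # -- recursion over children ------------------------------------------

    def children(self) -> Iterator["Module"]:
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Parameter]]:
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Parameter):
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{name}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[Tuple[str, np.ndarray]]:
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, np.ndarray):
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_buffers(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{name}.{i}.")

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for c in self.children():
            c.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- (de)serialization -------------------------------------------------

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {f"param:{k}": p.data for k, p in self.named_parameters()}
        state.update({f"buffer:{k}": b for k, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for key, value in state.items():
            kind, _, name = key.partition(":")
            if kind == "param":
                if name not in params:
                    raise KeyError(f"unknown parameter {name!r} in state dict")
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name!r}")
                params[name].data = value.astype(DTYPE)
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            kind, _, name = key.partition(":")
            if kind == "buffer":
                if name not in buffers:
                    raise KeyError(f"unknown buffer {name!r} in state dict")
                buffers[name][...] = value

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class Conv3d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel: Triple,
                 stride: Triple = (1, 1, 1), padding: Optional[Triple] = None,
                 bias: bool = True, *, rng: np.random.Generator):
        super().__init__()
        kernel = tuple(kernel)
        if padding is None:  # "same" padding at stride 1 for odd kernels
            padding = tuple(k // 2 for k in kernel)
        self.stride = tuple(stride)
        self.padding = tuple(padding)
        fan_in = in_channels * int(np.prod(kernel))
        self.weight = Parameter(kaiming(rng, (out_channels, in_channels) + kernel, fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=DTYPE)) if bias else None

    @property
    def kernel(self) -> Triple:
        return self.weight.data.shape[2:]

    def forward(self, x: Tensor) -> Tensor:
        return F.conv3d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose3d(Module):
    """Upsampling transposed convolution with kernel == stride (exact tiling)."""

    def __init__(self, in_channels: int, out_channels: int, factor: Triple,
                 bias: bool = True, *, rng: np.random.Generator):
        super().__init__()
        factor = tuple(factor)
        self.factor = factor
        fan_in = in_channels
        self.weight = Parameter(kaiming(rng, (in_channels, out_channels) + factor, fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose3d(x, self.weight, self.bias, self.factor)


class BatchNorm3d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=DTYPE))
        self.beta = Parameter(np.zeros(channels, dtype=DTYPE))
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training, self.momentum, self.eps)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim, dtype=DTYPE))
        self.beta = Parameter(np.zeros(dim, dtype=DTYPE))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return F.layer_norm(x, self.gamma, self.beta, self.eps)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 *, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(kaiming(rng, (out_features, in_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.linear(x, self.weight, self.bias)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.01):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return F.leaky_relu(x, self.slope)
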