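"""Residual squeeze-and-excitation feature extraction units.

Three units are provided, each constructible in 2D or 3D mode:

* :class:`SEBlock` — squeeze-and-excitation channel attention: global
  average pool, bottleneck perceptron with hidden width C/r, sigmoid gate.
* :class:`ResSEBlockA` — the resolution/channel-changing residual unit;
  the first convolution carries the stride and channel change and the
  skip path is a strided 1x1x1 projection so shapes match at the sum.
* :class:`ResSEBlockB` — the shape-preserving residual unit with an
  identity skip.

Layout of both residual blocks: conv -> BN -> LeakyReLU -> conv -> BN ->
SE -> (+skip) -> LeakyReLU, i.e. one BN between every convolution and its
activation and the SE gate after the second BN.  In 2D mode every kernel
and stride has extent 1 along the slice (depth) axis, so the convolutional
path never mixes information across slices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .errors import ConfigError, ShapeError
from .nd import functional as F
from .nd.modules import BatchNorm3d, Conv3d, Linear, Module
from .nd.tensor import Tensor

Triple = Tuple[int, int, int]


@dataclass(frozen=True)
class BlockConfig:
    in_channels: int
    out_channels: int
    stride: Triple = (1, 1, 1)
    mode: str = "3d"  # "2d" | "3d"
    se_reduction: int = 4
    leaky_slope: float = 0.01

    def validate(self) -> None:
        if self.mode not in ("2d", "3d"):
            raise ConfigError(f"mode must be '2d' or '3d', got {self.mode!r}")
        if self.mode == "2d" and self.stride[0] != 1:
            raise ConfigError("2D mode requires depth stride 1")
        if any(s not in (1, 2) for s in self.stride):
            raise ConfigError(f"strides must be 1 or 2, got {self.stride}")
        if self.out_channels % self.se_reduction != 0:
            raise ConfigError(f"out_channels {self.out_channels} not divisible by "
                              f"se_reduction r={self.se_reduction}")

    @property
    def kernel(self) -> Triple:
        return (1, 3, 3) if self.mode == "2d" else (3, 3, 3)


def _check_even(x: Tensor, stride: Triple) -> None:
    for ax, s in enumerate(stride):
        dim = x.shape[2 + ax]
        if s > 1 and dim % s != 0:
            raise ShapeError(f"spatial dim {dim} on axis {ax} not divisible by stride {s}")


class SEBlock(Module):
    """Channel attention gate; ``bypass=True`` pins all gates to 1."""

    def __init__(self, channels: int, reduction: int = 4, slope: float = 0.01,
                 *, rng: np.random.Generator):
        super().__init__()
        if channels % reduction != 0:
            raise ConfigError(f"channels {channels} not divisible by r={reduction}")
        self.fc1 = Linear(channels, channels // reduction, rng=rng)
        self.fc2 = Linear(channels // reduction, channels, rng=rng)
        self.slope = slope
        self.bypass = False

    def channel_weights(self, x: Tensor) -> Tensor:
        squeezed = F.global_avg_pool(x)  # (N, C)
        hidden = F.leaky_relu(self.fc1(squeezed), self.slope)
        return F.sigmoid(self.fc2(hidden))

    def forward(self, x: Tensor) -> Tensor:
        if self.bypass:
            return x
        w = self.channel_weights(x)
        n, c = w.shape
        return F.mul(x, w.reshape(n, c, 1, 1, 1))


class ResSEBlockB(Module):
    """Shape-preserving Res-SE unit (identity skip)."""

    def __init__(self, channels: int, mode: str = "3d", reduction: int = 4,
                 slope: float = 0.01, *, rng: np.random.Generator):
        super().__init__()
        cfg = BlockConfig(channels, channels, (1, 1, 1), mode, reduction, slope)
        cfg.validate()
        self.conv1 = Conv3d(channels, channels, cfg.kernel, rng=rng)
        self.bn1 = BatchNorm3d(channels)
        self.conv2 = Conv3d(channels, channels, cfg.kernel, rng=rng)
        self.bn2 = BatchNorm3d(channels)
        self.se = SEBlock(channels, reduction, slope, rng=rng)
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        y = F.leaky_relu(self.bn1(self.conv1(x)), self.slope)
        y = self.se(self.bn2(self.conv2(y)))
        return F.leaky_relu(F.add(y, x), self.slope)


class ResSEBlockA(Module):
    """Resolution/channel-changing Res-SE unit (projection skip)."""

    def __init__(self, cfg: BlockConfig, *, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        self.conv1 = Conv3d(cfg.in_channels, cfg.out_channels, cfg.kernel,
                            stride=cfg.stride, rng=rng)
        self.bn1 = BatchNorm3d(cfg.out_channels)
        self.conv2 = Conv3d(cfg.out_channels, cfg.out_channels, cfg.kernel, rng=rng)
        self.bn2 = BatchNorm3d(cfg.out_channels)
        self.se = SEBlock(cfg.out_channels, cfg.se_reduction, cfg.leaky_slope, rng=rng)
        self.skip_conv = Conv3d(cfg.in_channels, cfg.out_channels, (1, 1, 1),
                                stride=cfg.stride, padding=(0, 0, 0), rng=rng)
        self.skip_bn = BatchNorm3d(cfg.out_channels)

    def forward(self, x: Tensor) -> Tensor:
        _check_even(x, self.cfg.stride)
        y = F.leaky_relu(self.bn1(self.conv1(x)), self.cfg.leaky_slope)
        y = self.se(self.bn2(self.conv2(y)))
        skip = self.skip_bn(self.skip_conv(x))
        return F.leaky_relu(F.add(y, skip), self.cfg.leaky_slope)


class PlainConvBlock(Module):
    """Two conv + BN + LeakyReLU modules (the plain U-Net unit, no SE).

    The first convolution carries the stride and channel change.
    """

    def __init__(self, cfg: BlockConfig, *, rng: np.random.Generator):
        super().__init__()
        if cfg.mode not in ("2d", "3d"):
            raise ConfigError(f"mode must be '2d' or '3d', got {cfg.mode!r}")
        if cfg.mode == "2d" and cfg.stride[0] != 1:
            raise ConfigError("2D mode requires depth stride 1")
        self.cfg = cfg
        self.conv1 = Conv3d(cfg.in_channels, cfg.out_channels, cfg.kernel,
                            stride=cfg.stride, rng=rng)
        self.bn1 = BatchNorm3d(cfg.out_channels)
        self.conv2 = Conv3d(cfg.out_channels, cfg.out_channels, cfg.kernel, rng=rng)
        self.bn2 = BatchNorm3d(cfg.out_channels)

    def forward(self, x: Tensor) -> Tensor:
        _check_even(x, self.cfg.stride)
        y = F.leaky_relu(self.bn1(self.conv1(x)), self.cfg.leaky_slope)
        return F.leaky_relu(self.bn2(self.conv2(y)), self.cfg.leaky_slope)
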