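"""Five-stage encoder-decoder assembly and sliding-window inference.

Six variants are supported:

===================  ==========================  =====================
variant              stages 1-2                  stages 3-5
===================  ==========================  =====================
unet2d               plain conv, 2D              plain conv, 2D
unet25d              plain conv, 2D              plain conv, 3D
unet3d               plain conv, 3D              plain conv, 3D
resseunet3d          Res-SE, 3D                  Res-SE, 3D
resseunet25d         Res-SE, 2D                  Res-SE, 3D
transresseunet25d    Res-SE, 2D                  Res-SE 3D; stage 5 is
                                                 the Res-Dual-Attention
                                                 bottleneck
===================  ==========================  =====================

2D mode means every convolution kernel and stride has extent 1 along the
slice axis, so depth resolution is preserved through those stages.  The
default stage plan for a 32x256x256 patch is channels (16,32,64,128,256)
with strides ((1,1,1),(1,2,2),(2,2,2),(2,2,2),(2,2,2)), giving a stage-5
grid of 4x16x16 = 1024 bottleneck tokens.  unet2d and unet25d appear in
the comparison table of the source study without construction details;
the layouts here (all-2D, and 2D/3D split at stage 3, plain conv units)
are this package's declared reconstruction.

The decoder mirrors the encoder: transpose-convolution upsampling (kernel
= stride, so even dims are restored exactly), skip concatenation with the
same-stage encoder output, a 1x1x1 fusion convolution back to the stage
channel count, and one shape-preserving block.  The head is a 1x1x1
convolution to two channels followed by a channel softmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple

import numpy as np

from .blocks import BlockConfig, PlainConvBlock, ResSEBlockA, ResSEBlockB
from .errors import ConfigError, ShapeError
from .nd import functional as F
from .nd.modules import BatchNorm3d, Conv3d, ConvTranspose3d, Module
from .nd.tensor import Tensor
from .preprocess import _pad_to
from .transformer import ResDualAttention, TransformerConfig
from .volume import IntensityDomain, Mask, Volume

Triple = Tuple[int, int, int]

AXIS_NAMES = ("depth", "height", "width")

_VARIANTS = {
    "unet2d": dict(modes=("2d",) * 5, se=False, transformer=False),
    "unet25d": dict(modes=("2d", "2d", "3d", "3d", "3d"), se=False, transformer=False),
    "unet3d": dict(modes=("3d",) * 5, se=False, transformer=False),
    "resseunet3d": dict(modes=("3d",) * 5, se=True, transformer=False),
    "resseunet25d": dict(modes=("2d", "2d", "3d", "3d", "3d"), se=True, transformer=False),
    "transresseunet25d": dict(modes=("2d", "2d", "3d", "3d", "3d"), se=True, transformer=True),
}

#: in-plane stride plan shared by all variants; depth strides apply only
#: where the stage runs in 3D mode.
_BASE_STRIDES = ((1, 1, 1), (1, 2, 2), (2, 2, 2), (2, 2, 2), (2, 2, 2))


@dataclass(frozen=True)
class NetworkConfig:
    variant: str = "transresseunet25d"
    stage_channels: Tuple[int, int, int, int, int] = (16, 32, 64, 128, 256)
    n_classes: int = 2
    input_patch: Triple = (32, 256, 256)
    se_reduction: int = 4
    leaky_slope: float = 0.01
    transformer: TransformerConfig = field(default_factory=TransformerConfig)

    def validate(self) -> None:
        if self.variant not in _VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}; "
                              f"choose from {sorted(_VARIANTS)}")
        if len(self.stage_channels) != 5:
            raise ConfigError("stage_channels must list 5 stages")
        if self.transformer.C2 != self.stage_channels[4]:
            raise ConfigError(f"transformer C2={self.transformer.C2} must equal "
                              f"stage_channels[4]={self.stage_channels[4]}")
        for ax in range(3):
            total = int(np.prod([s[ax] for s in self.stage_strides]))
            if self.input_patch[ax] % total != 0:
                raise ConfigError(
                    f"input patch {self.input_patch[ax]} on the {AXIS_NAMES[ax]} axis "
                    f"is not divisible by the cumulative stride {total}")

    @property
    def modes(self) -> Tuple[str, ...]:
        return _VARIANTS[self.variant]["modes"]

    @property
    def stage_strides(self) -> Tuple[Triple, ...]:
        strides = []
        for mode, base in zip(self.modes, _BASE_STRIDES):
            strides.append((1 if mode == "2d" else base[0], base[1], base[2]))
        return tuple(strides)

    def stage_dims(self, stage: int) -> Triple:
        """Spatial dims of the output of encoder stage ``stage`` (1-based)."""
        dims = list(self.input_patch)
        for s in self.stage_strides[:stage]:
            dims = [d // st for d, st in zip(dims, s)]
        return tuple(dims)


def _encoder_stage(cfg: NetworkConfig, stage: int, rng: np.random.Generator) -> Module:
    """Stage index is 1-based; input channels for stage 1 is the image channel."""
    spec = _VARIANTS[cfg.variant]
    in_ch = 1 if stage == 1 else cfg.stage_channels[stage - 2]
    out_ch = cfg.stage_channels[stage - 1]
    mode = cfg.modes[stage - 1]
    stride = cfg.stage_strides[stage - 1]
    if stage == 5 and spec["transformer"]:
        return ResDualAttention(in_ch, cfg.transformer, cfg.stage_dims(5),
                                stride, cfg.se_reduction, cfg.leaky_slope, rng=rng)
    bc = BlockConfig(in_ch, out_ch, stride, mode, cfg.se_reduction, cfg.leaky_slope)
    if spec["se"]:
        return _ResSEStage(bc, rng=rng)
    return PlainConvBlock(bc, rng=rng)


class _ResSEStage(Module):
    """Block-A (stride/channel change) followed by one Block-B."""

    def __init__(self, bc: BlockConfig, *, rng: np.random.Generator):
        super().__init__()
        self.block_a = ResSEBlockA(bc, rng=rng)
        self.block_b = ResSEBlockB(bc.out_channels, bc.mode, bc.se_reduction,
                                   bc.leaky_slope, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.block_b(self.block_a(x))


class _DecoderStage(Module):
    """Upsample deeper features, fuse with the encoder skip, refine."""

    def __init__(self, cfg: NetworkConfig, stage: int, *, rng: np.random.Generator):
        super().__init__()
        spec = _VARIANTS[cfg.variant]
        deep_ch = cfg.stage_channels[stage]      # channels arriving from below
        ch = cfg.stage_channels[stage - 1]
        mode = cfg.modes[stage - 1]
        factor = cfg.stage_strides[stage]        # stride of the stage below
        self.up = ConvTranspose3d(deep_ch, ch, factor, rng=rng)
        self.fuse = Conv3d(2 * ch, ch, (1, 1, 1), padding=(0, 0, 0), rng=rng)
        self.fuse_bn = BatchNorm3d(ch)
        self.slope = cfg.leaky_slope
        if spec["se"]:
            self.block = ResSEBlockB(ch, mode, cfg.se_reduction, cfg.leaky_slope, rng=rng)
        else:
            self.block = PlainConvBlock(
                BlockConfig(ch, ch, (1, 1, 1), mode, cfg.se_reduction, cfg.leaky_slope),
                rng=rng)

    def forward(self, deep: Tensor, skip: Tensor) -> Tensor:
        up = self.up(deep)
        if up.shape != skip.shape:
            raise ShapeError(f"decoder shape mismatch: upsampled {up.shape} vs "
                             f"skip {skip.shape}")
        fused = F.leaky_relu(self.fuse_bn(self.fuse(F.concat([up, skip], axis=1))),
                             self.slope)
        return self.block(fused)


class SegNetwork(Module):
    """Full five-stage encoder-decoder with softmax head."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        super().__init__()
        cfg.validate()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.enc = [_encoder_stage(cfg, s, rng) for s in range(1, 6)]
        self.dec = [_DecoderStage(cfg, s, rng=rng) for s in range(4, 0, -1)]
        self.head = Conv3d(cfg.stage_channels[0], cfg.n_classes, (1, 1, 1),
                           padding=(0, 0, 0), rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        """(N,1,D,H,W) normalized patch -> (N,n_classes,D,H,W) probabilities."""
        if x.shape[2:] != tuple(self.cfg.input_patch):
            raise ShapeError(f"patch shape {x.shape[2:]} != configured input "
                             f"{self.cfg.input_patch}")
        skips = []
        h = x
        for stage in self.enc:
            h = stage(h)
            skips.append(h)
        h = skips[-1]
        for dec_stage, skip in zip(self.dec, reversed(skips[:-1])):
            h = dec_stage(h, skip)
        return F.softmax(self.head(h), axis=1)


def build_network(cfg: NetworkConfig, seed: int = 0) -> SegNetwork:
    """Construct a variant with deterministic seeded initialization."""
    return SegNetwork(cfg, seed)


# ---------------------------------------------------------------------------
# full-volume inference
# ---------------------------------------------------------------------------

def tile_starts(length: int, window: int, step: int) -> List[int]:
    """Start indices of overlapping windows covering [0, length)."""
    if length <= window:
        return [0]
    starts = list(range(0, length - window + 1, step))
    if starts[-1] + window < length:
        starts.append(length - window)
    return starts


def predict_volume(net: SegNetwork, volume: Volume, overlap: float = 0.5,
                   threshold: float = 0.5) -> Mask:
    """Sliding-window inference over a preprocessed (normalized) volume.

    Windows of the configured input patch overlap by ``overlap``; softmax
    probabilities are averaged over all windows covering a voxel and the
    target channel is thresholded (ties go to background).
    """
    if volume.intensity_domain != IntensityDomain.NORMALIZED_0_1:
        raise ConfigError("predict_volume expects a windowed, normalized volume")
    patch = tuple(net.cfg.input_patch)
    padded = _pad_to(volume.data, patch)
    pads = [( (p - d) // 2 if p > d else 0) for d, p in zip(volume.shape, patch)]
    steps = [max(1, int(round(p * (1.0 - overlap)))) for p in patch]
    prob = np.zeros(padded.shape, dtype=np.float64)
    count = np.zeros(padded.shape, dtype=np.float64)
    net.eval()
    for sd in tile_starts(padded.shape[0], patch[0], steps[0]):
        for sh in tile_starts(padded.shape[1], patch[1], steps[1]):
            for sw in tile_starts(padded.shape[2], patch[2], steps[2]):
                sl = (slice(sd, sd + patch[0]), slice(sh, sh + patch[1]),
                      slice(sw, sw + patch[2]))
                tile = padded[sl][None, None]
                probs = net(Tensor(tile)).data[0, 1]  # target-class channel
                prob[sl] += probs
                count[sl] += 1.0
    avg = prob / count
    core = tuple(slice(p, p + d) for p, d in zip(pads, volume.shape))
    return Mask((avg[core] > threshold).astype(np.uint8), volume.spacing_mm)
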