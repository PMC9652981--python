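"""The residual dual-attention bottleneck (stage 5).

Combines channel attention (the SE gates inside Res-SE Block-A) with
global self-attention: the downsampled feature map is linearly mapped to
C3 channels by a 1x1x1 convolution, flattened over space into P = D2*H2*W2
tokens (depth-major, then height, then width raster order), summed with a
learnable position embedding (z0 = f + PE), passed through M pre-norm
Transformer layers

    z*_m = MSA(LN(z_{m-1})) + z_{m-1}
    z_m  = MLP(LN(z*_m)) + z*_m

and unflattened in the same raster order; a second 1x1x1 convolution maps
back to C2 channels and the result is added to the bottleneck input to
form a residual structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .blocks import BlockConfig, ResSEBlockA
from .errors import ConfigError, ShapeError
from .nd import functional as F
from .nd.modules import Conv3d, LayerNorm, Linear, Module, Parameter
from .nd.tensor import DTYPE, Tensor

Triple = Tuple[int, int, int]


@dataclass(frozen=True)
class TransformerConfig:
    """Bottleneck hyperparameters; the full-size defaults are M=4, H=8,
    h=4096, C3=512 with C2=256 deserialized channels."""

    M: int = 4
    H: int = 8
    h: int = 4096
    C3: int = 512
    C2: int = 256

    def validate(self) -> None:
        if self.M < 1:
            raise ConfigError("M must be >= 1")
        if self.C3 % self.H != 0:
            raise ConfigError(f"C3={self.C3} must be divisible by H={self.H}")


class Serializer(Module):
    """1x1x1 conv C2 -> C3, then flatten (D,H,W) into P tokens."""

    def __init__(self, c2: int, c3: int, *, rng: np.random.Generator):
        super().__init__()
        self.proj = Conv3d(c2, c3, (1, 1, 1), padding=(0, 0, 0), rng=rng)

    def forward(self, x: Tensor) -> Tuple[Tensor, Triple]:
        n, _, d, h, w = x.shape
        f = self.proj(x)
        c3 = f.shape[1]
        tokens = f.reshape(n, c3, d * h * w).transpose(0, 2, 1)  # (N, P, C3)
        return tokens, (d, h, w)


class Deserializer(Module):
    """Unflatten P tokens back to (D,H,W), 1x1x1 conv C3 -> C2, add input."""

    def __init__(self, c3: int, c2: int, *, rng: np.random.Generator):
        super().__init__()
        self.proj = Conv3d(c3, c2, (1, 1, 1), padding=(0, 0, 0), rng=rng)

    def forward(self, tokens: Tensor, x_in: Tensor) -> Tensor:
        n, p, c3 = tokens.shape
        d, h, w = x_in.shape[2:]
        if p != d * h * w:
            raise ShapeError(f"token count {p} does not match provenance dims "
                             f"{d}x{h}x{w} = {d * h * w}")
        grid = tokens.transpose(0, 2, 1).reshape(n, c3, d, h, w)
        return F.add(self.proj(grid), x_in)


class PositionEmbedding(Module):
    """Learnable per-token embedding, added elementwise (z0 = f + PE)."""

    def __init__(self, n_tokens: int, dim: int, *, rng: np.random.Generator):
        super().__init__()
        self.pe = Parameter(rng.normal(0.0, 0.02, size=(n_tokens, dim)).astype(DTYPE))

    def forward(self, tokens: Tensor) -> Tensor:
        if tokens.shape[1:] != self.pe.shape:
            raise ConfigError(f"position embedding shape {self.pe.shape} does not match "
                              f"token shape {tokens.shape[1:]}; P is fixed at build time")
        return F.add(tokens, self.pe)


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, heads: int, *, rng: np.random.Generator):
        super().__init__()
        if dim % heads != 0:
            raise ConfigError(f"dim {dim} not divisible by heads {heads}")
        self.heads = heads
        self.head_dim = dim // heads
        self.wq = Linear(dim, dim, rng=rng)
        self.wk = Linear(dim, dim, rng=rng)
        self.wv = Linear(dim, dim, rng=rng)
        self.wo = Linear(dim, dim, rng=rng)

    def forward(self, z: Tensor, return_attention: bool = False):
        n, p, c = z.shape
        hd = self.head_dim

        def split(t: Tensor) -> Tensor:  # (N,P,C) -> (N,H,P,hd)
            return t.reshape(n, p, self.heads, hd).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(z)), split(self.wk(z)), split(self.wv(z))
        scores = F.scale(F.matmul(q, k.transpose(0, 1, 3, 2)), 1.0 / np.sqrt(hd))
        attn = F.softmax(scores, axis=-1)  # rows sum to 1 per query per head
        mixed = F.matmul(attn, v).transpose(0, 2, 1, 3).reshape(n, p, c)
        out = self.wo(mixed)
        if return_attention:
            return out, attn
        return out


class TransformerLayer(Module):
    """Pre-norm residual layer: MSA then a one-hidden-layer perceptron.

    The perceptron is input -> h -> C3 (two weight matrices, LeakyReLU in
    between); the "three layers" are counted as input/hidden/output.
    """

    def __init__(self, cfg: TransformerConfig, *, rng: np.random.Generator):
        super().__init__()
        self.ln1 = LayerNorm(cfg.C3)
        self.msa = MultiHeadSelfAttention(cfg.C3, cfg.H, rng=rng)
        self.ln2 = LayerNorm(cfg.C3)
        self.fc1 = Linear(cfg.C3, cfg.h, rng=rng)
        self.fc2 = Linear(cfg.h, cfg.C3, rng=rng)
        self.slope = 0.01

    def mlp(self, z: Tensor) -> Tensor:
        return self.fc2(F.leaky_relu(self.fc1(z), self.slope))

    def forward(self, z_prev: Tensor) -> Tensor:
        z_star = F.add(self.msa(self.ln1(z_prev)), z_prev)
        return F.add(self.mlp(self.ln2(z_star)), z_star)


class ResTransBlock(Module):
    """Serialize -> +PE -> M Transformer layers -> deserialize (+residual)."""

    def __init__(self, cfg: TransformerConfig, n_tokens: int,
                 *, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        self.serializer = Serializer(cfg.C2, cfg.C3, rng=rng)
        self.pos = PositionEmbedding(n_tokens, cfg.C3, rng=rng)
        self.layers = [TransformerLayer(cfg, rng=rng) for _ in range(cfg.M)]
        self.deserializer = Deserializer(cfg.C3, cfg.C2, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        tokens, dims = self.serializer(x)
        z = self.pos(tokens)
        for layer in self.layers:
            z = layer(z)
        return self.deserializer(z, x)


class ResDualAttention(Module):
    """Stage-5 bottleneck: Block-A (stride 2, -> C2) then Res-Trans Block."""

    def __init__(self, in_channels: int, cfg: TransformerConfig,
                 stage5_dims: Triple, stride: Triple = (2, 2, 2),
                 se_reduction: int = 4, slope: float = 0.01,
                 *, rng: np.random.Generator):
        super().__init__()
        self.block_a = ResSEBlockA(
            BlockConfig(in_channels, cfg.C2, stride, "3d", se_reduction, slope), rng=rng)
        n_tokens = int(np.prod(stage5_dims))
        self.res_trans = ResTransBlock(cfg, n_tokens, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.res_trans(self.block_a(x))
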