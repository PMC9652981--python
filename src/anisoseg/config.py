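"""YAML run configuration with strict schema validation.

``load_config`` fills every omitted key with the study defaults (soft
tissue window 400/40, SE reduction r=4, LeakyReLU slope 0.01, transformer
M=4 / H=8 / h=4096 / C3=512, Adam lr 1e-3 with weight decay 1e-4,
polynomial decay power 0.9, batch 4, patch 32x256x256, 500 epochs) and
rejects unknown or misspelled keys.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import List, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import ConfigError
from .phantom import PhantomSpec
from .preprocess import AugmentConfig
from .training import TrainConfig
from .transformer import TransformerConfig
from .models import NetworkConfig


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PreprocessSettings(_Strict):
    window_width: float = 400.0
    window_level: float = 40.0


class AugmentSettings(_Strict):
    p_mirror: Tuple[float, float, float] = (0.5, 0.5, 0.5)
    rotation_deg_max: float = 15.0
    scale_range: Tuple[float, float] = (0.9, 1.1)
    translate_frac_max: float = 0.1
    noise_sd: float = 0.02
    enable_mirror: bool = True
    enable_rotation: bool = True
    enable_scale: bool = True
    enable_translate: bool = True
    enable_noise: bool = True

    def to_dataclass(self) -> AugmentConfig:
        cfg = AugmentConfig(**self.model_dump())
        cfg.validate()
        return cfg


class TransformerSettings(_Strict):
    M: int = 4
    H: int = 8
    h: int = 4096
    C3: int = 512

    def to_dataclass(self, c2: int) -> TransformerConfig:
        return TransformerConfig(M=self.M, H=self.H, h=self.h, C3=self.C3, C2=c2)


class NetworkSettings(_Strict):
    variant: str = "transresseunet25d"
    stage_channels: Tuple[int, int, int, int, int] = (16, 32, 64, 128, 256)
    n_classes: int = 2
    input_patch: Tuple[int, int, int] = (32, 256, 256)
    se_reduction: int = 4
    leaky_slope: float = 0.01


class TrainSettings(_Strict):
    batch_size: int = 4
    lr0: float = 1e-3
    weight_decay: float = 1e-4
    poly_power: float = 0.9
    epochs: int = 500
    crops_per_case: int = 1
    decoupled_weight_decay: bool = False


class PhantomSettings(_Strict):
    shape_voxels: Tuple[int, int, int] = (32, 96, 96)
    spacing_mm: Tuple[float, float, float] = (5.0, 1.0, 1.0)
    lesion_kind: str = "ellipsoid"
    lesion_semiaxes_mm: Tuple[float, float, float] = (12.0, 15.0, 15.0)
    lesion_center_frac: Tuple[float, float, float] = (0.5, 0.5, 0.5)
    lesion_hu: float = 40.0
    background_hu: float = -800.0
    noise_sd_hu: float = 20.0
    n_lobes: int = 3

    def to_dataclass(self) -> PhantomSpec:
        return PhantomSpec(**self.model_dump())


class RunConfig(_Strict):
    seed: int = 0
    preprocess: PreprocessSettings = PreprocessSettings()
    augment: AugmentSettings = AugmentSettings()
    network: NetworkSettings = NetworkSettings()
    transformer: TransformerSettings = TransformerSettings()
    train: TrainSettings = TrainSettings()
    phantom: PhantomSettings = PhantomSettings()

    def network_config(self) -> NetworkConfig:
        c2 = self.network.stage_channels[4]
        return NetworkConfig(
            variant=self.network.variant,
            stage_channels=tuple(self.network.stage_channels),
            n_classes=self.network.n_classes,
            input_patch=tuple(self.network.input_patch),
            se_reduction=self.network.se_reduction,
            leaky_slope=self.network.leaky_slope,
            transformer=self.transformer.to_dataclass(c2),
        )

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            batch_size=self.train.batch_size, lr0=self.train.lr0,
            weight_decay=self.train.weight_decay, poly_power=self.train.poly_power,
            epochs=self.train.epochs, patch=tuple(self.network.input_patch),
            seed=self.seed, crops_per_case=self.train.crops_per_case,
            augment=self.augment.to_dataclass(),
            decoupled_weight_decay=self.train.decoupled_weight_decay,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def load_config(path: Optional[str | Path] = None) -> RunConfig:
    """Load a YAML config; missing file section defaults apply; unknown keys fail."""
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
    try:
        return RunConfig(**raw)
    except ValidationError as err:
        keys = sorted({".".join(str(p) for p in e["loc"]) for e in err.errors()})
        raise ConfigError(f"invalid configuration keys: {', '.join(keys)}") from err
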