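"""CT intensity windowing, patch cropping, and training augmentations.

The preprocessing chain mirrors clinical practice for soft-tissue targets:
HU values are windowed (width 400 / level 40) onto 0-255, rescaled to
[0, 1], and training samples are random crops while validation samples are
crops centered on the reference target volume.  Geometric augmentations
are strictly in-plane (about the slice axis): with ~5 mm slices,
through-plane rotation or scaling would destroy the anisotropic structure
the 2.5D architecture is designed around.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .errors import ConfigError, DomainError, EmptyMaskError
from .volume import IntensityDomain, Mask, Volume, check_aligned

Triple = Tuple[int, int, int]


# ---------------------------------------------------------------------------
# intensity
# ---------------------------------------------------------------------------

def window_ct(volume: Volume, width: float = 400.0, level: float = 40.0) -> Volume:
    """Linear window/level mapping of HU onto [0, 255].

    ``out = clip((hu - (level - width/2)) / width, 0, 1) * 255``; with the
    soft-tissue defaults, -160 HU maps to 0, 40 HU to 127.5 and 240 HU to 255.
    """
    if width <= 0:
        raise ConfigError(f"window width must be positive, got {width}")
    if volume.intensity_domain != IntensityDomain.HU:
        raise DomainError(f"window_ct expects HU input, got {volume.intensity_domain.value}")
    lo = level - width / 2.0
    out = np.clip((volume.data - lo) / width, 0.0, 1.0) * 255.0
    return volume.with_data(out.astype(np.float32), IntensityDomain.MAPPED_0_255)


def normalize(volume: Volume) -> Volume:
    """Rescale a 0-255 mapped volume to [0, 1]."""
    if volume.intensity_domain != IntensityDomain.MAPPED_0_255:
        raise DomainError(f"normalize expects mapped_0_255 input, got "
                          f"{volume.intensity_domain.value}")
    return volume.with_data((volume.data / 255.0).astype(np.float32),
                            IntensityDomain.NORMALIZED_0_1)


# ---------------------------------------------------------------------------
# cropping
# ---------------------------------------------------------------------------

def _pad_to(data: np.ndarray, size: Triple, value: float = 0.0) -> np.ndarray:
    """Symmetric padding up to ``size`` (extra voxel goes to the trailing side)."""
    pads = []
    for dim, target in zip(data.shape, size):
        missing = max(0, target - dim)
        pads.append((missing // 2, missing - missing // 2))
    if any(p != (0, 0) for p in pads):
        data = np.pad(data, pads, constant_values=value)
    return data


def _padded_pair(volume: Volume, mask: Mask, size: Triple) -> Tuple[np.ndarray, np.ndarray]:
    check_aligned(volume, mask)
    return _pad_to(volume.data, size), _pad_to(mask.data, size)


def random_crop(volume: Volume, mask: Mask, size: Triple = (32, 256, 256),
                seed: int = 0) -> Tuple[Volume, Mask]:
    """Aligned random crop; undersized axes are zero-padded symmetrically first."""
    vol, msk = _padded_pair(volume, mask, size)
    rng = np.random.default_rng(seed)
    starts = [int(rng.integers(0, dim - s + 1)) for dim, s in zip(vol.shape, size)]
    sl = tuple(slice(st, st + s) for st, s in zip(starts, size))
    return (volume.with_data(vol[sl]), mask.with_data(msk[sl]))


def center_crop_on_gtv(volume: Volume, mask: Mask,
                       size: Triple = (32, 256, 256)) -> Tuple[Volume, Mask]:
    """Deterministic crop centered on the foreground centroid.

    The centroid (mean foreground index, rounded toward zero) is taken in
    the padded volume; crop offsets are clamped so the patch stays inside.
    """
    if mask.data.sum() == 0:
        raise EmptyMaskError("cannot center a crop on an empty mask (no GTV)")
    vol, msk = _padded_pair(volume, mask, size)
    centroid = [int(c) for c in np.argwhere(msk).mean(axis=0)]
    starts = [min(max(c - s // 2, 0), dim - s)
              for c, s, dim in zip(centroid, size, vol.shape)]
    sl = tuple(slice(st, st + s) for st, s in zip(starts, size))
    return (volume.with_data(vol[sl]), mask.with_data(msk[sl]))


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentConfig:
    """Stochastic augmentation policy (magnitudes are package defaults)."""

    p_mirror: Tuple[float, float, float] = (0.5, 0.5, 0.5)
    rotation_deg_max: float = 15.0
    scale_range: Tuple[float, float] = (0.9, 1.1)
    translate_frac_max: float = 0.1
    noise_sd: float = 0.02  # in normalized intensity units
    enable_mirror: bool = True
    enable_rotation: bool = True
    enable_scale: bool = True
    enable_translate: bool = True
    enable_noise: bool = True

    def validate(self) -> None:
        if not all(0.0 <= p <= 1.0 for p in self.p_mirror):
            raise ConfigError(f"mirror probabilities must lie in [0,1], got {self.p_mirror}")
        if self.rotation_deg_max < 0:
            raise ConfigError("rotation_deg_max must be nonnegative")
        lo, hi = self.scale_range
        if not (0.0 < lo <= hi < 2.0):
            raise ConfigError(f"scale_range must be well-ordered within (0,2), got {self.scale_range}")
        if not (0.0 <= self.translate_frac_max < 0.5):
            raise ConfigError("translate_frac_max must lie in [0, 0.5)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")


IDENTITY = dict(mirror_axes=(), rotation_deg=0.0, scale=1.0, translate=(0.0, 0.0, 0.0))


def apply_spatial(volume: Volume, mask: Mask, mirror_axes: Sequence[int] = (),
                  rotation_deg: float = 0.0, scale: float = 1.0,
                  translate: Tuple[float, float, float] = (0.0, 0.0, 0.0),
                  ) -> Tuple[Volume, Mask]:
    """Apply one forced geometric transform identically to volume and mask.

    Mirrors are exact flips; rotation (about the slice axis) + in-plane
    scale + translation are composed into a single affine resample (linear
    interpolation for the volume, nearest-neighbor for the mask).  The
    identity transform returns the inputs bit-for-bit.
    """
    check_aligned(volume, mask)
    vol, msk = volume.data, mask.data
    for ax in mirror_axes:
        vol = np.flip(vol, axis=ax)
        msk = np.flip(msk, axis=ax)
    if rotation_deg != 0.0 or scale != 1.0 or any(t != 0.0 for t in translate):
        theta = np.deg2rad(rotation_deg)
        c, s = np.cos(theta), np.sin(theta)
        # forward map: y = A (x - center) + center + t, with in-plane
        # rotation/scale acting on (height, width); affine_transform wants
        # the inverse map.
        fwd = np.array([[1.0, 0.0, 0.0],
                        [0.0, scale * c, -scale * s],
                        [0.0, scale * s, scale * c]])
        inv = np.linalg.inv(fwd)
        center = (np.asarray(vol.shape) - 1) / 2.0
        offset = center - inv @ (center + np.asarray(translate))
        vol = ndimage.affine_transform(vol, inv, offset=offset, order=1,
                                       mode="constant", cval=0.0)
        msk = ndimage.affine_transform(msk, inv, offset=offset, order=0,
                                       mode="constant", cval=0)
    return volume.with_data(np.ascontiguousarray(vol)), mask.with_data(np.ascontiguousarray(msk))


def augment(volume: Volume, mask: Mask, config: AugmentConfig | None = None,
            seed: int = 0) -> Tuple[Volume, Mask]:
    """Sample and apply the augmentation suite; deterministic for fixed seed."""
    config = AugmentConfig() if config is None else config
    config.validate()
    rng = np.random.default_rng(seed)
    mirror_axes = tuple(ax for ax in range(3)
                        if config.enable_mirror and rng.random() < config.p_mirror[ax])
    rotation = (rng.uniform(-config.rotation_deg_max, config.rotation_deg_max)
                if config.enable_rotation and config.rotation_deg_max > 0 else 0.0)
    scale = (rng.uniform(*config.scale_range) if config.enable_scale else 1.0)
    if config.enable_translate and config.translate_frac_max > 0:
        translate = tuple(rng.uniform(-config.translate_frac_max, config.translate_frac_max) * dim
                          for dim in volume.shape)
    else:
        translate = (0.0, 0.0, 0.0)
    out_vol, out_msk = apply_spatial(volume, mask, mirror_axes, rotation, scale, translate)
    if config.enable_noise and config.noise_sd > 0:
        noisy = out_vol.data + config.noise_sd * rng.standard_normal(out_vol.shape).astype(np.float32)
        out_vol = out_vol.with_data(noisy.astype(np.float32))
    return out_vol, out_msk
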