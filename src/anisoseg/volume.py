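"""Core in-memory containers: anisotropic volumes and binary masks.

Axis convention everywhere in this package: arrays are indexed
``(depth, height, width)`` with 0-based voxel indices, and ``spacing_mm``
is the matching ``(slice, row, col)`` triple.  Thick-slice CT therefore has
``spacing_mm[0]`` several times larger than the in-plane spacings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Tuple

import numpy as np

from .errors import ShapeError


class IntensityDomain(str, Enum):
    HU = "HU"
    MAPPED_0_255 = "mapped_0_255"
    NORMALIZED_0_1 = "normalized_0_1"


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing metadata."""

    data: np.ndarray
    spacing_mm: Tuple[float, float, float]
    intensity_domain: IntensityDomain = IntensityDomain.HU

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ShapeError(f"Volume requires a 3D array, got ndim={self.data.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ShapeError(f"spacing_mm must be 3 positive reals, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.data)):
            raise ShapeError("Volume data must be finite")
        self.intensity_domain = IntensityDomain(self.intensity_domain)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, domain: IntensityDomain | None = None) -> "Volume":
        return Volume(data, self.spacing_mm,
                      self.intensity_domain if domain is None else domain)


@dataclass
class Mask:
    """A binary label volume aligned voxel-for-voxel with a :class:`Volume`."""

    data: np.ndarray
    spacing_mm: Tuple[float, float, float]

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ShapeError(f"Mask requires a 3D array, got ndim={arr.ndim}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ShapeError(f"Mask values must be binary, found {uniq[:5]}")
        self.data = arr.astype(np.uint8)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ShapeError(f"spacing_mm must be 3 positive reals, got {self.spacing_mm}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Mask":
        return Mask(data, self.spacing_mm)


def check_aligned(volume: Volume, mask: Mask) -> None:
    if volume.shape != mask.shape:
        raise ShapeError(f"volume shape {volume.shape} != mask shape {mask.shape}")
    if not np.allclose(volume.spacing_mm, mask.spacing_mm):
        raise ShapeError(f"volume spacing {volume.spacing_mm} != mask spacing {mask.spacing_mm}")
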