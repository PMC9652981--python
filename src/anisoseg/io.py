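"""NIfTI input/output for volumes and masks.

Volumes are stored with array axes (depth, height, width) and a diagonal
affine carrying the (slice, row, col) spacing in mm, so a write-then-read
round trip preserves the data bitwise and the spacing to well below
1e-6 mm.  Masks are stored as unsigned 8-bit labels {0, 1}.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ShapeError
from .volume import IntensityDomain, Mask, Volume


def _affine(spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def _load(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ShapeError(f"{path.name}: expected a 3D image, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ShapeError(f"{path.name}: non-positive voxel spacing {spacing}")
    return data, spacing


def read_volume(path: str | Path,
                domain: IntensityDomain = IntensityDomain.HU) -> Volume:
    data, spacing = _load(path)
    return Volume(data.astype(np.float32), spacing, domain)


def write_volume(volume: Volume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.data, _affine(volume.spacing_mm))
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> Mask:
    data, spacing = _load(path)
    return Mask(data, spacing)


def write_mask(mask: Mask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.spacing_mm))
    img.header.set_zooms(mask.spacing_mm)
    nib.save(img, str(path))
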