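"""Synthetic anisotropic CT phantoms with exact analytic lesion masks.

The generator emulates the imaging regime of thick-slice radiotherapy
planning CT: slice thickness ~5x the in-plane pixel spacing, a single
soft-tissue lesion (~40 HU) embedded in lung-like background (~-800 HU),
plus additive Gaussian noise.  Lesions are ellipsoids, or "lobulated"
unions of jittered overlapping ellipsoids that mimic irregular tumor
margins.  Masks are decided analytically at voxel centers in physical mm
coordinates, with no partial-volume antialiasing, so every mask is exactly
checkable against the generating inequality.

Seeding: one integer master seed spawns named child streams (geometry,
noise), so changing noise parameters never moves the lesion.  Dataset
generation derives an independent sub-seed per case, making any case
reproducible without generating the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .errors import ConfigError, PlacementError
from .volume import IntensityDomain, Mask, Volume

AXIS_NAMES = ("depth", "height", "width")

#: Parameter ranges used by :func:`generate_dataset` when no jitter is given.
#: Semiaxes span small-to-medium lesions (8-16 mm), centers stay away from
#: the borders, and lesion attenuation varies over a soft-tissue band.
DEFAULT_JITTER: Dict[str, Tuple[float, float]] = {
    "lesion_semiaxes_mm": (8.0, 16.0),
    "lesion_center_frac": (0.35, 0.65),
    "lesion_hu": (20.0, 60.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of one phantom case."""

    shape_voxels: Tuple[int, int, int] = (32, 96, 96)
    spacing_mm: Tuple[float, float, float] = (5.0, 1.0, 1.0)
    lesion_kind: str = "ellipsoid"  # "ellipsoid" | "lobulated"
    lesion_semiaxes_mm: Tuple[float, float, float] = (12.0, 15.0, 15.0)
    lesion_center_frac: Tuple[float, float, float] = (0.5, 0.5, 0.5)
    lesion_hu: float = 40.0
    background_hu: float = -800.0
    noise_sd_hu: float = 20.0
    n_lobes: int = 3

    def validate(self) -> None:
        if any(int(n) < 1 for n in self.shape_voxels):
            raise ConfigError(f"all voxel counts must be >= 1, got {self.shape_voxels}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ConfigError(f"spacing must be positive, got {self.spacing_mm}")
        if self.lesion_kind not in ("ellipsoid", "lobulated"):
            raise ConfigError(f"unknown lesion kind {self.lesion_kind!r}")
        if any(a <= 0 for a in self.lesion_semiaxes_mm):
            raise ConfigError(f"semiaxes must be positive, got {self.lesion_semiaxes_mm}")
        if not all(0.0 < f < 1.0 for f in self.lesion_center_frac):
            raise ConfigError(f"center fractions must lie in (0,1), got {self.lesion_center_frac}")
        if self.noise_sd_hu < 0:
            raise ConfigError("noise_sd_hu must be nonnegative")
        if self.n_lobes < 1:
            raise ConfigError("n_lobes must be >= 1")
        # lobulated lobes are jittered by up to 0.5 semiaxis and have
        # 0.6-semiaxis size, so the union reaches at most 1.1 * semiaxis.
        reach = 1.0 if self.lesion_kind == "ellipsoid" else 1.1
        extent = self.extent_mm
        center = self.center_mm
        for ax in range(3):
            r = reach * self.lesion_semiaxes_mm[ax]
            if center[ax] - r < 0 or center[ax] + r > extent[ax]:
                raise PlacementError(
                    f"lesion exceeds the volume along the {AXIS_NAMES[ax]} axis: "
                    f"center {center[ax]:.1f} mm, reach {r:.1f} mm, extent {extent[ax]:.1f} mm")

    @property
    def extent_mm(self) -> Tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape_voxels, self.spacing_mm))

    @property
    def center_mm(self) -> Tuple[float, float, float]:
        return tuple(f * e for f, e in zip(self.lesion_center_frac, self.extent_mm))


@dataclass
class PhantomCase:
    volume: Volume
    mask: Mask
    spec: PhantomSpec
    seed: int
    case_id: str = "case"


def _voxel_centers_mm(spec: PhantomSpec) -> List[np.ndarray]:
    """Per-axis physical coordinates of voxel centers: (i + 0.5) * spacing."""
    return [(np.arange(n) + 0.5) * s for n, s in zip(spec.shape_voxels, spec.spacing_mm)]


def _ellipsoid_mask(spec: PhantomSpec, center: Sequence[float],
                    semiaxes: Sequence[float]) -> np.ndarray:
    d, h, w = _voxel_centers_mm(spec)
    q = (((d - center[0]) / semiaxes[0]) ** 2)[:, None, None] \
        + (((h - center[1]) / semiaxes[1]) ** 2)[None, :, None] \
        + (((w - center[2]) / semiaxes[2]) ** 2)[None, None, :]
    return q <= 1.0


def lesion_mask(spec: PhantomSpec, geometry_rng: np.random.Generator) -> np.ndarray:
    """Analytic lesion support at voxel centers (bool array)."""
    if spec.lesion_kind == "ellipsoid":
        return _ellipsoid_mask(spec, spec.center_mm, spec.lesion_semiaxes_mm)
    # lobulated: union of n_lobes overlapping ellipsoids with jittered centers
    center = np.asarray(spec.center_mm)
    semi = np.asarray(spec.lesion_semiaxes_mm)
    mask = _ellipsoid_mask(spec, center, 0.8 * semi)
    for _ in range(spec.n_lobes - 1):
        offset = geometry_rng.uniform(-0.5, 0.5, size=3) * semi
        mask |= _ellipsoid_mask(spec, center + offset, 0.6 * semi)
    return mask


def _child_rngs(seed: int) -> Tuple[np.random.Generator, np.random.Generator]:
    """Named child streams: geometry first, noise second."""
    geometry = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    noise = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    return geometry, noise


def generate_phantom(spec: PhantomSpec, seed: int, case_id: str = "case") -> PhantomCase:
    """Generate one phantom; deterministic for fixed ``(spec, seed)``."""
    spec.validate()
    geometry_rng, noise_rng = _child_rngs(seed)
    support = lesion_mask(spec, geometry_rng)
    if not support.any():
        raise PlacementError("lesion support contains no voxel centers; "
                             "semiaxes too small for this grid")
    hu = np.full(spec.shape_voxels, spec.background_hu, dtype=np.float32)
    hu[support] = spec.lesion_hu
    if spec.noise_sd_hu > 0:
        hu += spec.noise_sd_hu * noise_rng.standard_normal(spec.shape_voxels).astype(np.float32)
    volume = Volume(hu, spec.spacing_mm, IntensityDomain.HU)
    mask = Mask(support.astype(np.uint8), spec.spacing_mm)
    return PhantomCase(volume, mask, spec, int(seed), case_id)


def _jittered_spec(template: PhantomSpec, jitter: Dict[str, Tuple[float, float]],
                   rng: np.random.Generator) -> PhantomSpec:
    updates = {}
    for name in sorted(jitter):  # sorted for draw-order determinism
        lo, hi = jitter[name]
        if not hasattr(template, name):
            raise ConfigError(f"unknown jitter field {name!r}")
        if lo > hi:
            raise ConfigError(f"empty jitter range for {name!r}: ({lo}, {hi})")
        current = getattr(template, name)
        if isinstance(current, tuple):
            updates[name] = tuple(float(v) for v in rng.uniform(lo, hi, size=len(current)))
        else:
            updates[name] = float(rng.uniform(lo, hi))
    return replace(template, **updates)


def case_seed(master_seed: int, index: int) -> int:
    """Sub-seed for case ``index``; independent of the dataset size."""
    return int(np.random.SeedSequence([int(master_seed), 2, int(index)]).generate_state(1)[0]
               % (2 ** 31))


def generate_case(spec_template: PhantomSpec, jitter: Dict[str, Tuple[float, float]] | None,
                  master_seed: int, index: int) -> PhantomCase:
    """Generate case ``index`` of the dataset seeded by ``master_seed``."""
    jitter = DEFAULT_JITTER if jitter is None else jitter
    sub = case_seed(master_seed, index)
    jitter_rng = np.random.default_rng(np.random.SeedSequence([sub, 2]))
    spec = _jittered_spec(spec_template, jitter, jitter_rng)
    return generate_phantom(spec, sub, case_id=f"case_{index:03d}")


def generate_dataset(n_cases: int, spec_template: PhantomSpec | None = None,
                     jitter: Dict[str, Tuple[float, float]] | None = None,
                     seed: int = 0) -> List[PhantomCase]:
    """Generate ``n_cases`` phantoms with per-case jittered parameters."""
    if n_cases < 1:
        raise ConfigError("n_cases must be >= 1")
    spec_template = PhantomSpec() if spec_template is None else spec_template
    return [generate_case(spec_template, jitter, seed, i) for i in range(n_cases)]
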