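"""Shared fixtures: small phantoms and CPU-scale network configurations."""

import numpy as np
import pytest

from anisoseg.models import NetworkConfig
from anisoseg.phantom import PhantomSpec, generate_phantom
from anisoseg.transformer import TransformerConfig


@pytest.fixture(scope="session")
def noiseless_case():
    """Small ellipsoid phantom with zero noise (exact two-phase image)."""
    spec = PhantomSpec(shape_voxels=(16, 48, 48), spacing_mm=(5.0, 1.0, 1.0),
                       lesion_semiaxes_mm=(10.0, 12.0, 12.0), noise_sd_hu=0.0)
    return generate_phantom(spec, seed=42)


@pytest.fixture(scope="session")
def noisy_case():
    spec = PhantomSpec(shape_voxels=(16, 48, 48), spacing_mm=(5.0, 1.0, 1.0),
                       lesion_semiaxes_mm=(10.0, 12.0, 12.0), noise_sd_hu=20.0)
    return generate_phantom(spec, seed=42)


def tiny_network_config(variant: str = "transresseunet25d") -> NetworkConfig:
    """Smallest structurally complete configuration (patch 8x32x32)."""
    return NetworkConfig(variant=variant, stage_channels=(4, 8, 16, 32, 64),
                         input_patch=(8, 32, 32),
                         transformer=TransformerConfig(M=1, H=2, h=32, C3=32, C2=64))


def toy_network_config(variant: str = "transresseunet25d") -> NetworkConfig:
    """The scaled-down training profile (patch 16x64x64)."""
    return NetworkConfig(variant=variant, stage_channels=(8, 16, 32, 64, 128),
                         input_patch=(16, 64, 64),
                         transformer=TransformerConfig(M=2, H=4, h=256, C3=128, C2=128))
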