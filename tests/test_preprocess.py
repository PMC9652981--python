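"""Windowing, cropping and augmentation contracts."""

import numpy as np
import pytest

from anisoseg.errors import ConfigError, DomainError, EmptyMaskError
from anisoseg.metrics import dsc
from anisoseg.preprocess import (AugmentConfig, apply_spatial, augment,
                                 center_crop_on_gtv, normalize, random_crop,
                                 window_ct)
from anisoseg.volume import IntensityDomain, Mask, Volume


def _vol(data, spacing=(5.0, 1.0, 1.0), domain=IntensityDomain.HU):
    return Volume(np.asarray(data, dtype=np.float32), spacing, domain)


class TestWindowing:
    @pytest.mark.parametrize("hu,expected", [(-160.0, 0.0), (40.0, 127.5),
                                             (240.0, 255.0), (-1000.0, 0.0),
                                             (500.0, 255.0)])
    def test_soft_tissue_window_mapping(self, hu, expected):
        out = window_ct(_vol(np.full((2, 2, 2), hu)))
        assert out.intensity_domain == IntensityDomain.MAPPED_0_255
        np.testing.assert_allclose(out.data, expected, atol=1e-4)

    def test_monotone_in_input(self):
        ramp = np.linspace(-1200, 1200, 97).reshape(1, 1, -1)
        out = window_ct(_vol(ramp)).data.ravel()
        assert np.all(np.diff(out) >= 0)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ConfigError):
            window_ct(_vol(np.zeros((2, 2, 2))), width=0.0)

    def test_wrong_domain_rejected(self):
        mapped = window_ct(_vol(np.zeros((2, 2, 2))))
        with pytest.raises(DomainError):
            window_ct(mapped)


class TestNormalize:
    def test_endpoints_and_roundtrip(self):
        v = _vol(np.array([[[0.0, 127.5, 255.0]]]), domain=IntensityDomain.MAPPED_0_255)
        out = normalize(v)
        np.testing.assert_allclose(out.data, [[[0.0, 0.5, 1.0]]])
        np.testing.assert_allclose(out.data * 255.0, v.data)

    def test_requires_mapped_domain(self):
        with pytest.raises(DomainError):
            normalize(_vol(np.zeros((2, 2, 2))))


class TestCropping:
    def _pair(self, shape, fg_slices=None):
        vol = _vol(np.random.default_rng(0).random(shape))
        m = np.zeros(shape, dtype=np.uint8)
        if fg_slices is not None:
            m[fg_slices] = 1
        return vol, Mask(m, vol.spacing_mm)

    def test_random_crop_shape_contract(self):
        vol, mask = self._pair((40, 70, 70), np.s_[10:14, 30:40, 30:40])
        v, m = random_crop(vol, mask, size=(32, 64, 64), seed=4)
        assert v.data.shape == (32, 64, 64) and m.data.shape == (32, 64, 64)
        assert v.spacing_mm == vol.spacing_mm

    def test_identity_crop_when_sizes_match(self):
        vol, mask = self._pair((8, 16, 16), np.s_[3:5, 6:9, 6:9])
        v, m = random_crop(vol, mask, size=(8, 16, 16), seed=0)
        assert np.array_equal(v.data, vol.data)
        assert np.array_equal(m.data, mask.data)

    def test_undersized_depth_padded_six_and_six(self):
        vol, mask = self._pair((20, 16, 16), np.s_[8:12, 4:10, 4:10])
        v, m = random_crop(vol, mask, size=(32, 16, 16), seed=1)
        assert v.data.shape == (32, 16, 16)
        # 12 missing slices split 6/6: original content sits at [6:26)
        assert np.allclose(v.data[:6], 0) and np.allclose(v.data[26:], 0)
        assert np.array_equal(v.data[6:26], vol.data)

    def test_center_crop_centers_on_centroid(self):
        vol, mask = self._pair((20, 40, 40), np.s_[9:12, 18:23, 18:23])
        v, m = center_crop_on_gtv(vol, mask, size=(8, 16, 16))
        centroid = np.argwhere(mask.data).mean(axis=0).astype(int)
        expected = tuple(slice(c - s // 2, c - s // 2 + s)
                         for c, s in zip(centroid, (8, 16, 16)))
        assert np.array_equal(v.data, vol.data[expected])

    def test_center_crop_clamps_at_border(self):
        """GTV touching slice 0: the crop starts at slice 0 and keeps full size."""
        vol, mask = self._pair((20, 40, 40), np.s_[0:2, 18:23, 18:23])
        v, m = center_crop_on_gtv(vol, mask, size=(8, 16, 16))
        assert v.data.shape == (8, 16, 16)
        # centroid is (0, 20, 20): depth start clamps to 0, rows/cols start at 12
        assert np.array_equal(v.data, vol.data[0:8, 12:28, 12:28])

    def test_center_crop_empty_mask_raises(self):
        vol, mask = self._pair((8, 16, 16))
        with pytest.raises(EmptyMaskError):
            center_crop_on_gtv(vol, mask, size=(4, 8, 8))


class TestAugment:
    def _pair(self):
        rng = np.random.default_rng(7)
        vol = _vol(rng.random((12, 40, 40)))
        m = np.zeros((12, 40, 40), dtype=np.uint8)
        m[4:8, 12:30, 12:30] = 1
        return vol, Mask(m, vol.spacing_mm)

    def test_all_disabled_is_exact_identity(self):
        vol, mask = self._pair()
        cfg = AugmentConfig(enable_mirror=False, enable_rotation=False,
                            enable_scale=False, enable_translate=False,
                            enable_noise=False)
        v, m = augment(vol, mask, cfg, seed=3)
        assert np.array_equal(v.data, vol.data)
        assert np.array_equal(m.data, mask.data)

    def test_mirror_is_an_involution(self):
        vol, mask = self._pair()
        v1, m1 = apply_spatial(vol, mask, mirror_axes=(2,))
        v2, m2 = apply_spatial(v1, m1, mirror_axes=(2,))
        assert np.array_equal(v2.data, vol.data)
        assert np.array_equal(m2.data, mask.data)

    def test_rotation_roundtrip_preserves_smooth_mask(self, noiseless_case):
        """+10 deg then -10 deg on a large ellipsoid: DSC >= 0.98."""
        vol = _vol(noiseless_case.volume.data, noiseless_case.volume.spacing_mm)
        mask = noiseless_case.mask
        v1, m1 = apply_spatial(vol, mask, rotation_deg=10.0)
        v2, m2 = apply_spatial(v1, m1, rotation_deg=-10.0)
        assert dsc(m2.data, mask.data) >= 0.98

    def test_mask_stays_binary_under_geometric_transforms(self):
        vol, mask = self._pair()
        v, m = augment(vol, mask, AugmentConfig(noise_sd=0.0), seed=11)
        assert set(np.unique(m.data)).issubset({0, 1})
        assert v.data.shape == vol.data.shape

    def test_deterministic_for_fixed_seed(self):
        vol, mask = self._pair()
        a = augment(vol, mask, AugmentConfig(), seed=5)
        b = augment(vol, mask, AugmentConfig(), seed=5)
        assert np.array_equal(a[0].data, b[0].data)
        assert np.array_equal(a[1].data, b[1].data)

    def test_invalid_scale_range_rejected(self):
        with pytest.raises(ConfigError):
            AugmentConfig(scale_range=(1.2, 0.8)).validate()
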