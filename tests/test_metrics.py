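"""DSC / HD95 against brute-force oracles; loss function contracts."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from anisoseg.errors import EmptyMaskError, ShapeError
from anisoseg.metrics import (cross_entropy_loss, dice_loss, dsc, evaluate_cases,
                              extract_surface, hd95, total_loss)
from anisoseg.nd.tensor import Tensor
from anisoseg.volume import Mask

RNG = np.random.default_rng(77)


def brute_force_hd95(a, b, spacing):
    """O(n^2) oracle: pairwise mm distances between surface voxel centers."""
    sa = np.argwhere(extract_surface(a)) * np.asarray(spacing)
    sb = np.argwhere(extract_surface(b)) * np.asarray(spacing)
    d = cdist(sb, sa)
    fwd = np.percentile(d.min(axis=1), 95.0)   # from S_B to S_A
    bwd = np.percentile(d.min(axis=0), 95.0)   # from S_A to S_B
    return 0.5 * (fwd + bwd)


def random_blob(shape, rng, max_fg=1000):
    """Random union of 1-2 ellipsoids with <= max_fg foreground voxels."""
    while True:
        m = np.zeros(shape, dtype=bool)
        for _ in range(rng.integers(1, 3)):
            c = rng.uniform(0.25, 0.75, 3) * shape
            ax = rng.uniform(1.5, 0.4 * min(shape), 3)
            grid = np.indices(shape).astype(float)
            q = sum(((grid[i] - c[i]) / ax[i]) ** 2 for i in range(3))
            m |= q <= 1.0
        if 0 < m.sum() <= max_fg:
            return m.astype(np.uint8)


class TestDSC:
    def test_identical_masks_give_one(self):
        m = random_blob((8, 12, 12), RNG)
        assert dsc(m, m) == 1.0

    def test_disjoint_masks_give_zero(self):
        a = np.zeros((4, 4, 4), np.uint8)
        b = np.zeros((4, 4, 4), np.uint8)
        a[0, 0, 0] = 1
        b[3, 3, 3] = 1
        assert dsc(a, b) == 0.0

    def test_counting_example(self):
        """|A|=6, |B|=4, |A n B|=3 -> 2*3/10 = 0.6."""
        a = np.zeros((1, 2, 6), np.uint8)
        b = np.zeros((1, 2, 6), np.uint8)
        a[0, 0, :6] = 1
        b[0, 0, 2:6] = 1
        b[0, 0, 5] = 0
        b[0, 1, 0] = 1
        assert abs(a.sum() - 6) == 0 and b.sum() == 4
        assert np.logical_and(a, b).sum() == 3
        assert dsc(a, b) == pytest.approx(0.6)

    def test_both_empty_raises_one_empty_zero(self):
        z = np.zeros((3, 3, 3), np.uint8)
        m = z.copy()
        m[1, 1, 1] = 1
        with pytest.raises(EmptyMaskError):
            dsc(z, z)
        assert dsc(z, m) == 0.0 and dsc(m, z) == 0.0

    def test_symmetric(self):
        a, b = random_blob((8, 10, 10), RNG), random_blob((8, 10, 10), RNG)
        assert dsc(a, b) == dsc(b, a)


class TestSurface:
    def test_single_voxel_is_its_own_surface(self):
        m = np.zeros((3, 3, 3), np.uint8)
        m[1, 1, 1] = 1
        assert np.array_equal(extract_surface(m), m.astype(bool))

    def test_solid_cube_surface_count(self):
        """4x4x4 cube inside a larger grid: 4^3 - 2^3 = 56 surface voxels."""
        m = np.zeros((8, 8, 8), np.uint8)
        m[2:6, 2:6, 2:6] = 1
        assert extract_surface(m).sum() == 56

    def test_all_foreground_volume_has_boundary_face_surface(self):
        """Out-of-bounds counts as background, so border voxels are surface."""
        m = np.ones((4, 5, 6), np.uint8)
        surf = extract_surface(m)
        interior = np.zeros_like(m, dtype=bool)
        interior[1:-1, 1:-1, 1:-1] = True
        assert np.array_equal(surf, ~interior)


class TestHD95:
    def test_identical_masks_give_zero(self):
        m = random_blob((8, 10, 10), RNG)
        assert hd95(m, m, (5.0, 1.0, 1.0)) == 0.0

    def test_two_single_voxels_ten_apart(self):
        a = np.zeros((1, 1, 16), np.uint8)
        b = a.copy()
        a[0, 0, 2] = 1
        b[0, 0, 12] = 1
        assert hd95(a, b, (1.0, 1.0, 1.0)) == pytest.approx(10.0)

    def test_shifted_cube_matches_brute_force_with_thick_slices(self):
        a = np.zeros((12, 8, 8), np.uint8)
        a[2:6, 2:6, 2:6] = 1
        b = np.zeros_like(a)
        b[4:8, 2:6, 2:6] = 1  # shifted 2 slices at 5 mm spacing
        spacing = (5.0, 1.0, 1.0)
        assert hd95(a, b, spacing) == pytest.approx(
            brute_force_hd95(a, b, spacing), abs=1e-9)

    def test_symmetry_and_spacing_linearity(self):
        a, b = random_blob((8, 10, 10), RNG), random_blob((8, 10, 10), RNG)
        s = (5.0, 1.0, 1.0)
        assert hd95(a, b, s) == pytest.approx(hd95(b, a, s), abs=1e-12)
        assert hd95(a, b, (10.0, 2.0, 2.0)) == pytest.approx(2 * hd95(a, b, s), rel=1e-9)

    def test_empty_mask_raises_with_case_id(self):
        m = random_blob((6, 6, 6), RNG)
        with pytest.raises(EmptyMaskError, match="case_x"):
            hd95(m, np.zeros_like(m), (1, 1, 1), case_id="case_x")


class TestLosses:
    def _probs(self, p_target, shape=(1, 4, 4, 4)):
        p = np.empty((shape[0], 2) + shape[1:], np.float32)
        p[:, 1] = p_target
        p[:, 0] = 1.0 - p_target
        return Tensor(p)

    def test_perfect_prediction_near_zero(self):
        t = (RNG.random((1, 4, 4, 4)) > 0.5).astype(np.uint8)
        probs = self._probs(t.astype(np.float32))
        assert total_loss(probs, t).item() < 1e-3

    def test_uniform_probs_cross_entropy_is_ln2(self):
        t = (RNG.random((1, 4, 4, 4)) > 0.5).astype(np.uint8)
        probs = self._probs(np.full((1, 4, 4, 4), 0.5, np.float32))
        assert cross_entropy_loss(probs, t).item() == pytest.approx(np.log(2), rel=1e-5)

    def test_uniform_probs_dice_matches_direct_formula(self):
        """Half-foreground target, p=0.5 everywhere: both classes give
        (2*0.5*n/2)/(0.5*n + n/2) = 1/2, so loss = 1 - 1/2."""
        t = np.zeros((1, 4, 4, 4), np.uint8)
        t[0, :2] = 1
        probs = self._probs(np.full((1, 4, 4, 4), 0.5, np.float32))
        n = t.size
        expected_dice = (2 * 0.5 * (n / 2)) / (0.5 * n + n / 2)
        assert dice_loss(probs, t).item() == pytest.approx(1 - expected_dice, rel=1e-4)

    def test_total_is_sum_of_parts(self):
        t = (RNG.random((2, 4, 4, 4)) > 0.7).astype(np.uint8)
        p = self._probs(RNG.random((2, 4, 4, 4)).astype(np.float32), shape=(2, 4, 4, 4))
        total = total_loss(p, t).item()
        parts = dice_loss(p, t).item() + cross_entropy_loss(p, t).item()
        assert total == pytest.approx(parts, rel=1e-6)

    def test_dice_loss_decreases_along_negative_gradient(self):
        t = np.array([[[[[0]]], [[[1]]]]], np.uint8).reshape(1, 1, 1, 2)
        logits = Tensor(np.zeros((1, 2, 1, 1, 2), np.float32))
        logits.requires_grad = True
        from anisoseg.nd import functional as F
        loss0 = dice_loss(F.softmax(logits, axis=1), t)
        loss0.backward()
        stepped = Tensor(logits.data - 1.0 * logits.grad)
        loss1 = dice_loss(F.softmax(stepped, axis=1), t)
        assert loss1.item() < loss0.item()


class TestEvaluateCases:
    def _mask(self, arr):
        return Mask(arr, (5.0, 1.0, 1.0))

    def test_single_case_sd_zero_convention(self):
        m = self._mask(random_blob((8, 10, 10), RNG))
        s = evaluate_cases([m], [m])
        assert s.dsc_mean == 1.0 and s.dsc_sd == 0.0 and s.hd95_mean == 0.0

    def test_aggregation_matches_spreadsheet_oracle(self):
        preds, refs = [], []
        for _ in range(5):
            preds.append(self._mask(random_blob((8, 10, 10), RNG)))
            refs.append(self._mask(random_blob((8, 10, 10), RNG)))
        s = evaluate_cases(preds, refs)
        d = [dsc(p.data, r.data) for p, r in zip(preds, refs)]
        h = [hd95(p.data, r.data, (5.0, 1.0, 1.0)) for p, r in zip(preds, refs)]
        assert s.dsc_mean == pytest.approx(np.mean(d))
        assert s.dsc_sd == pytest.approx(np.std(d, ddof=1))
        assert s.hd95_mean == pytest.approx(np.mean(h))
        assert s.hd95_sd == pytest.approx(np.std(h, ddof=1))

    def test_length_mismatch_rejected(self):
        m = self._mask(random_blob((6, 6, 6), RNG))
        with pytest.raises(ShapeError):
            evaluate_cases([m], [m, m])
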