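"""GLCM construction and features against brute-force enumeration oracles."""

import math

import numpy as np
import pytest

from ctradiomics.glcm import (
    GlcmMatrix,
    OFFSETS_ALL13,
    OFFSETS_AXIAL3,
    build_glcm,
    glcm_features,
    quantize,
)

from conftest import make_mask, make_volume


def brute_force_glcm(levels, mask, offsets, distance, G):
    """Exhaustive double loop over all voxel pairs at each offset."""
    p = np.zeros((G, G))
    nx, ny, nz = levels.shape
    for off in offsets:
        dx, dy, dz = (o * distance for o in off)
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    ni, nj, nk = i + dx, j + dy, k + dz
                    if not (0 <= ni < nx and 0 <= nj < ny and 0 <= nk < nz):
                        continue
                    if mask[i, j, k] and mask[ni, nj, nk]:
                        a, b = levels[i, j, k], levels[ni, nj, nk]
                        p[a, b] += 1
                        p[b, a] += 1
    total = p.sum()
    return p / total if total else p


class TestQuantize:
    def test_constant_roi_maps_to_level_zero(self):
        vol = make_volume(np.full((3, 3, 3), 7.0))
        q = quantize(vol, make_mask(np.ones((3, 3, 3))), G=16)
        assert np.all(q.levels[q.mask] == 0)

    def test_full_range_hits_extreme_levels(self):
        data = np.zeros((1, 1, 2))
        data[0, 0, 1] = 255.0
        q = quantize(make_volume(data), make_mask(np.ones((1, 1, 2))), G=256)
        assert sorted(q.levels.ravel().tolist()) == [0, 255]

    def test_levels_match_per_voxel_floor_formula(self, rng):
        data = rng.normal(0, 100, size=(4, 4, 4))
        mask = rng.random((4, 4, 4)) > 0.3
        mask[0, 0, 0] = mask[1, 1, 1] = True
        G = 32
        q = quantize(make_volume(data), make_mask(mask), G=G)
        vmin, vmax = data[mask].min(), data[mask].max()
        for idx in zip(*np.nonzero(mask)):
            expected = min(int((data[idx] - vmin) / (vmax - vmin) * G), G - 1)
            assert q.levels[idx] == expected

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            quantize(make_volume(np.zeros((2, 2, 2))), make_mask(np.zeros((2, 2, 2))))


class TestBuildGlcm:
    def test_constant_roi_concentrates_at_origin(self):
        vol = make_volume(np.full((2, 2, 2), 3.0))
        q = quantize(vol, make_mask(np.ones((2, 2, 2))), G=8)
        m = build_glcm(q)
        assert m.p[0, 0] == pytest.approx(1.0)
        assert glcm_features(m).contrast == 0.0

    def test_two_voxel_axial_pair(self):
        data = np.zeros((1, 1, 2))
        data[0, 0, 1] = 1.0
        q = quantize(make_volume(data), make_mask(np.ones((1, 1, 2))), G=2)
        m = build_glcm(q, distance=1, directions="axial3")
        assert m.p[0, 1] == pytest.approx(0.5)
        assert m.p[1, 0] == pytest.approx(0.5)
        assert m.pair_count == 2

    @pytest.mark.parametrize("directions,offsets", [
        ("all13", OFFSETS_ALL13), ("axial3", OFFSETS_AXIAL3),
    ])
    def test_matches_brute_force_enumeration(self, rng, directions, offsets):
        data = rng.normal(size=(4, 4, 4))
        mask = rng.random((4, 4, 4)) > 0.25
        mask[0, 0, 0] = mask[0, 0, 1] = True
        q = quantize(make_volume(data), make_mask(mask), G=8)
        m = build_glcm(q, distance=1, directions=directions)
        expected = brute_force_glcm(q.levels, mask, offsets, 1, 8)
        np.testing.assert_allclose(m.p, expected, atol=1e-12)

    def test_distance_two_matches_brute_force(self, rng):
        data = rng.normal(size=(5, 5, 5))
        mask = np.ones((5, 5, 5), dtype=bool)
        q = quantize(make_volume(data), make_mask(mask), G=4)
        m = build_glcm(q, distance=2, directions="all13")
        expected = brute_force_glcm(q.levels, mask, OFFSETS_ALL13, 2, 4)
        np.testing.assert_allclose(m.p, expected, atol=1e-12)

    def test_single_voxel_mask_has_no_pairs(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        q = quantize(make_volume(np.zeros((3, 3, 3))), make_mask(mask), G=4)
        with pytest.raises(ValueError, match="no co-occurring pairs"):
            build_glcm(q)

    def test_out_of_mask_voxels_never_contribute(self, rng):
        # poison out-of-mask voxels: matrix must not change
        data = rng.normal(size=(4, 4, 4))
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        q1 = quantize(make_volume(data), make_mask(mask), G=8)
        poisoned = data.copy()
        poisoned[~mask] = 1e9
        data2 = poisoned
        q2 = quantize(make_volume(data2), make_mask(mask), G=8)
        np.testing.assert_allclose(build_glcm(q1).p, build_glcm(q2).p)


class TestGlcmFeatures:
    def test_diagonal_concentrated_matrix(self):
        p = np.zeros((4, 4))
        p[2, 2] = 1.0
        f = glcm_features(GlcmMatrix(p=p))
        assert (f.contrast, f.idm, f.entropy, f.moments) == (0.0, 1.0, 0.0, 1.0)

    def test_uniform_2x2_closed_form(self):
        f = glcm_features(GlcmMatrix(p=np.full((2, 2), 0.25)))
        assert f.contrast == pytest.approx(0.5)
        assert f.idm == pytest.approx(0.75)
        assert f.entropy == pytest.approx(math.log(4.0))
        assert f.moments == pytest.approx(0.25)

    def test_random_matrix_elementwise_sum_oracle(self, rng):
        p = rng.random((16, 16))
        p = (p + p.T) / 2.0
        p /= p.sum()
        f = glcm_features(GlcmMatrix(p=p))
        contrast = idm = entropy = asm = 0.0
        for i in range(16):
            for j in range(16):
                contrast += (i - j) ** 2 * p[i, j]
                idm += p[i, j] / (1 + (i - j) ** 2)
                if p[i, j] > 0:
                    entropy -= p[i, j] * math.log(p[i, j])
                asm += p[i, j] ** 2
        assert f.contrast == pytest.approx(contrast, abs=1e-12)
        assert f.idm == pytest.approx(idm, abs=1e-12)
        assert f.entropy == pytest.approx(entropy, abs=1e-12)
        assert f.moments == pytest.approx(asm, abs=1e-12)

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            glcm_features(GlcmMatrix(p=np.ones((3, 3))))


class TestInvariances:
    def _random_quantized(self, rng, G=8):
        data = rng.normal(size=(5, 5, 5))
        mask = rng.random((5, 5, 5)) > 0.2
        mask[2, 2, 2] = mask[2, 2, 3] = True
        return quantize(make_volume(data), make_mask(mask), G=G)

    def test_matrix_is_symmetric_and_normalized(self, rng):
        m = build_glcm(self._random_quantized(rng))
        np.testing.assert_allclose(m.p, m.p.T, atol=1e-15)
        assert m.p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_gray_level_reversal_preserves_features(self, rng):
        from ctradiomics.glcm import QuantizedRoi

        q = self._random_quantized(rng)
        reversed_q = QuantizedRoi(
            levels=(q.G - 1 - q.levels) * q.mask, mask=q.mask, G=q.G,
            calibration=q.calibration,
        )
        f0 = glcm_features(build_glcm(q))
        f1 = glcm_features(build_glcm(reversed_q))
        assert f1.contrast == pytest.approx(f0.contrast, abs=1e-12)
        assert f1.idm == pytest.approx(f0.idm, abs=1e-12)
        assert f1.entropy == pytest.approx(f0.entropy, abs=1e-12)
        assert f1.moments == pytest.approx(f0.moments, abs=1e-12)

    def test_added_noise_raises_contrast_lowers_idm(self, rng):
        # smooth ramp ROI vs the same ROI with independent voxel noise
        x = np.linspace(0, 400, 12)
        data = np.broadcast_to(x[:, None, None], (12, 8, 8)).copy()
        mask = make_mask(np.ones((12, 8, 8)))
        q_smooth = quantize(make_volume(data), mask, G=64)
        f_smooth = glcm_features(build_glcm(q_smooth))
        noisy = data + rng.normal(0, 60, size=data.shape)
        q_noisy = quantize(make_volume(noisy), mask, G=64)
        f_noisy = glcm_features(build_glcm(q_noisy))
        assert f_noisy.contrast > f_smooth.contrast
        assert f_noisy.idm < f_smooth.idm
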