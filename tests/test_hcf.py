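"""Handcrafted descriptors: segmentation, the four groups, the RF screen."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytofuse.datatypes import FeatureMatrix, ImageRecord
from cytofuse.hcf import (
    CellMask,
    GLCM_ANGLES,
    GLCM_LEVELS,
    box_counts,
    color_features,
    extract_hcf,
    fractal_features,
    fuse_handcrafted,
    rf_group_select,
    segment_leukocyte,
    shape_features,
    texture_features,
)
from oracles import ellipse_pixel_count, glcm_bruteforce, boxcount_bruteforce


def img_from_gray(gray):
    return ImageRecord(pixels=np.stack([gray] * 3, axis=-1).astype(np.uint8), label="x")


def mask_of(arr):
    arr = np.asarray(arr, dtype=bool)
    rows, cols = np.nonzero(arr)
    return CellMask(mask=arr, area_px=int(arr.sum()), centroid=(rows.mean(), cols.mean()))


class TestSegmentation:
    def test_dark_ellipse_area_matches_raster_oracle(self):
        gray = np.full((64, 64), 220, np.uint8)
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        inside = ((xx - 32) / 20) ** 2 + ((yy - 32) / 10) ** 2 <= 1
        gray[inside] = 60
        mask = segment_leukocyte(img_from_gray(gray))
        expected = ellipse_pixel_count(64, 64, 32, 32, 20, 10)
        assert mask.area_px == pytest.approx(expected, rel=0.05)

    def test_constant_image_raises(self):
        with pytest.raises(ValueError, match="no object"):
            segment_leukocyte(img_from_gray(np.full((32, 32), 100, np.uint8)))

    def test_largest_component_wins(self):
        gray = np.full((64, 64), 230, np.uint8)
        gray[5:10, 5:15] = 40  # 50 px blob
        gray[25:50, 20:40] = 40  # 500 px blob
        mask = segment_leukocyte(img_from_gray(gray))
        assert mask.mask[30, 30] and not mask.mask[7, 7]
        assert mask.area_px == 500


class TestShape:
    def test_filled_square(self):
        m = np.zeros((32, 32), bool)
        m[10:20, 10:20] = True
        area, l1, l2, sol = shape_features(mask_of(m))
        assert area == 100 and sol == pytest.approx(1.0)
        assert l1 >= l2 > 0

    def test_ellipse_axis_ratio(self):
        yy, xx = np.mgrid[0:96, 0:96].astype(float)
        m = ((xx - 48) / 20) ** 2 + ((yy - 48) / 10) ** 2 <= 1
        _, l1, l2, _ = shape_features(mask_of(m))
        assert l1 / l2 == pytest.approx(2.0, rel=0.05)

    def test_non_convex_solidity_below_one(self):
        m = np.zeros((32, 32), bool)
        m[14:18, 4:28] = True
        m[4:28, 14:18] = True  # plus sign
        assert shape_features(mask_of(m))[3] < 1.0

    def test_tiny_mask_rejected(self):
        m = np.zeros((32, 32), bool)
        m[5, 5] = True
        with pytest.raises(ValueError):
            shape_features(mask_of(m))


class TestColor:
    def test_uniform_image_zero_spreads(self):
        f = color_features(img_from_gray(np.full((32, 32), 120, np.uint8)))
        r_std, _, h_std, _, s_std, _ = f
        assert r_std == pytest.approx(0, abs=1e-12)
        assert h_std == pytest.approx(0, abs=1e-12)
        assert s_std == pytest.approx(0, abs=1e-12)

    def test_pure_red(self):
        px = np.zeros((32, 32, 3), np.uint8)
        px[:, :, 0] = 255
        f = color_features(ImageRecord(pixels=px, label="x"))
        assert f[1] == pytest.approx(0.0)  # hue of red is 0
        assert f[3] == pytest.approx(1.0)  # fully saturated

    def test_gray_is_lab_neutral(self):
        f = color_features(img_from_gray(np.full((32, 32), 128, np.uint8)))
        assert abs(f[5]) < 0.5  # Lab b* ~ 0 for achromatic input


class TestTexture:
    def test_uniform_image_conventions(self):
        f = texture_features(img_from_gray(np.full((32, 32), 77, np.uint8)))
        std, skew, kurt, ent, contrast, corr, hom = f
        assert std == 0 and skew == 0 and kurt == 0
        assert ent == 0 and contrast == 0 and corr == 0
        assert hom == pytest.approx(1.0)

    def test_two_level_histogram_skew_and_entropy(self):
        gray = np.zeros((32, 32), np.uint8)
        gray[:16] = 255
        f = texture_features(img_from_gray(gray))
        assert f[1] == pytest.approx(0.0, abs=1e-12)  # symmetric
        assert f[3] == pytest.approx(1.0)  # 1 bit

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 10**9))
    def test_glcm_terms_match_bruteforce_on_random_images(self, seed):
        """Library GLCM contrast/corr/homogeneity equal pair enumeration."""
        from skimage.feature import graycomatrix, graycoprops

        rng = np.random.default_rng(seed)
        q = rng.integers(0, 6, (6, 6)).astype(np.uint8)
        lib = graycomatrix(q, [1], list(GLCM_ANGLES), levels=6, symmetric=True, normed=True)
        for ai, ang in enumerate([0, 45, 90, 135]):
            _, (contrast, corr, hom) = glcm_bruteforce(q, ang, levels=6)
            assert graycoprops(lib, "contrast")[0, ai] == pytest.approx(contrast, abs=1e-9)
            assert graycoprops(lib, "homogeneity")[0, ai] == pytest.approx(hom, abs=1e-9)
            if not np.isnan(corr):
                assert graycoprops(lib, "correlation")[0, ai] == pytest.approx(corr, abs=1e-6)

    def test_checkerboard_contrast_matches_hand_enumeration(self):
        q = np.array([[0, 1], [0, 1]], np.uint8)
        _, (contrast, _, _) = glcm_bruteforce(q, 0, levels=2)
        assert contrast == 1.0  # both horizontal pairs differ by 1


class TestFractal:
    def test_box_counts_match_bruteforce(self, rng):
        for _ in range(50):
            m = rng.random((rng.integers(8, 20), rng.integers(8, 20))) < 0.3
            for b in (2, 4):
                assert (box_counts(m, b) > 0).sum() == boxcount_bruteforce(m, b)

    def test_filled_square_dimension_near_two(self):
        m = np.zeros((256, 256), bool)
        m[16:240, 16:240] = True
        fd, _ = fractal_features(mask_of(m))
        assert 1.85 <= fd <= 2.05

    def test_line_dimension_near_one(self):
        m = np.zeros((256, 256), bool)
        m[128, 16:240] = True
        fd, _ = fractal_features(mask_of(m))
        assert 0.9 <= fd <= 1.1

    def test_square_beats_its_boundary(self):
        m = np.zeros((256, 256), bool)
        m[16:240, 16:240] = True
        from scipy import ndimage

        ring = m & ~ndimage.binary_erosion(m)
        fd_fill, _ = fractal_features(mask_of(m))
        fd_ring, _ = fractal_features(mask_of(ring))
        assert fd_fill > fd_ring

    def test_equal_occupancy_lacunarity_zero(self):
        m = np.zeros((32, 32), bool)
        m[0:16, 0:16] = True  # every occupied 8x8 box fully filled
        _, lac = fractal_features(mask_of(m), lacunarity_box=8)
        assert lac == 0.0

    def test_single_pixel_convention(self):
        m = np.zeros((32, 32), bool)
        m[5, 5] = True
        assert fractal_features(mask_of(m)).tolist() == [0.0, 0.0]


class TestFusion:
    def test_length_19_and_slice_recovery(self):
        s, c, t, f = np.arange(4.0), np.arange(6.0) + 10, np.arange(7.0) + 20, np.arange(2.0) + 30
        v = fuse_handcrafted(s, c, t, f)
        assert v.shape == (19,)
        assert np.array_equal(v[:4], s) and np.array_equal(v[17:], f)

    def test_wrong_group_length_rejected(self):
        with pytest.raises(ValueError):
            fuse_handcrafted(np.zeros(5), np.zeros(6), np.zeros(7), np.zeros(2))

    def test_extract_hcf_always_19_and_finite(self, tiny4):
        for rec in list(tiny4)[:8]:
            v = extract_hcf(rec)
            assert v.shape == (19,) and np.isfinite(v).all()

    def test_masked_mode_runs(self, tiny4):
        v = extract_hcf(tiny4[0], masked=True)
        assert v.shape == (19,) and np.isfinite(v).all()


class TestShapePhotometricInvariance:
    def test_mild_brightness_preserves_mask(self, tiny4):
        """Shape features survive photometric changes that keep the mask."""
        from cytofuse.s3a import brightness

        img = tiny4[0]
        m0 = segment_leukocyte(img)
        m1 = segment_leukocyte(brightness(img, 1.05))
        iou = (m0.mask & m1.mask).sum() / (m0.mask | m1.mask).sum()
        assert iou >= 0.95


class TestRFGroupSelect:
    def _table(self, rng, n=60):
        labels = ["a"] * (n // 2) + ["b"] * (n - n // 2)
        enc = np.array([0] * (n // 2) + [1] * (n - n // 2), float)
        cols, names = [], []
        groups = {"g1": ["label_copy", "noise1", "const"], "g2": ["noise2", "noise3"]}
        cols = [enc, rng.normal(size=n), np.zeros(n), rng.normal(size=n), rng.normal(size=n)]
        names = ["label_copy", "noise1", "const", "noise2", "noise3"]
        return FeatureMatrix(np.column_stack(cols), labels, names), groups

    def test_label_copy_ranked_first_constant_never(self, rng):
        table, groups = self._table(rng)
        sel = rf_group_select(
            table, group_sizes={"g1": 1, "g2": 1}, groups=groups, seed=0
        )
        assert table.column_names[sel[0]] == "label_copy"
        assert "const" not in [table.column_names[j] for j in sel]

    def test_k_equals_pool_is_identity(self, rng):
        table, groups = self._table(rng)
        sel = rf_group_select(
            table, group_sizes={"g1": 3, "g2": 2}, groups=groups, seed=0
        )
        assert sorted(sel) == [0, 1, 2, 3, 4]

    def test_k_larger_than_pool_rejected(self, rng):
        table, groups = self._table(rng)
        with pytest.raises(ValueError):
            rf_group_select(table, group_sizes={"g1": 4, "g2": 1}, groups=groups)


class TestTextureGLCMDirect:
    def test_texture_feature_glcm_terms_match_bruteforce_average(self, rng):
        """The GLCM entries of the 19-dim extractor equal the brute-force
        pair-count average over the four angles on tiny images."""
        from cytofuse.hcf import GLCM_LEVELS

        for _ in range(25):
            gray = (rng.integers(0, 256, (16, 16))).astype(np.uint8)
            img = img_from_gray(gray)
            feats = texture_features(img)
            q = (gray // (256 // GLCM_LEVELS)).astype(np.uint8)
            per_angle = [glcm_bruteforce(q, a, levels=GLCM_LEVELS) for a in (0, 45, 90, 135)]
            contrast = np.mean([t[1][0] for t in per_angle])
            hom = np.mean([t[1][2] for t in per_angle])
            assert feats[4] == pytest.approx(contrast, abs=1e-9)
            assert feats[6] == pytest.approx(hom, abs=1e-9)
            corrs = [t[1][1] for t in per_angle]
            if not any(np.isnan(c) for c in corrs):
                assert feats[5] == pytest.approx(np.mean(corrs), abs=1e-6)
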