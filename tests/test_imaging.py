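"""Preprocessing chain: grayscale, filters, binarization, contour, skeleton."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage as ndi

import taxofeat as tf
from conftest import random_blob


def brute_denoise(gray, k=3):
    """Naive per-pixel mean-then-median with symmetric (reflect) padding."""
    pad = k // 2
    out = np.empty_like(gray, dtype=float)
    p = np.pad(gray.astype(float), pad, mode="symmetric")
    for r in range(gray.shape[0]):
        for c in range(gray.shape[1]):
            out[r, c] = p[r:r + k, c:c + k].mean()
    med = np.empty_like(out)
    p = np.pad(out, pad, mode="symmetric")
    for r in range(gray.shape[0]):
        for c in range(gray.shape[1]):
            med[r, c] = np.median(p[r:r + k, c:c + k])
    return med


class TestGrayscale:
    @pytest.mark.parametrize("rgb, expected", [
        ((255, 255, 255), 255.0),
        ((0, 0, 0), 0.0),
        ((255, 0, 0), 76.245),
    ])
    def test_luminance_weighting(self, rgb, expected):
        img = np.full((2, 2, 3), rgb, np.uint8)
        assert tf.to_grayscale(img)[0, 0] == pytest.approx(expected, abs=0.01)

    def test_gray_input_unchanged(self, rng):
        gray = rng.integers(0, 256, (5, 7))
        assert np.array_equal(tf.to_grayscale(gray), gray)

    def test_wrong_channel_count(self):
        with pytest.raises(ValueError):
            tf.to_grayscale(np.zeros((4, 4, 2)))


class TestDenoise:
    def test_constant_is_fixed_point(self):
        img = np.full((9, 9), 42.0)
        assert np.array_equal(tf.denoise(img), img)

    def test_salt_pixel_removed(self):
        img = np.zeros((9, 9))
        img[4, 4] = 255.0
        out = tf.denoise(img)
        # the mean stage spreads the spike, the median stage kills it
        assert out.max() < 255 / 9 + 1e-9
        assert out[4, 4] < 255 / 9 + 1e-9

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(5):
            img = rng.uniform(0, 255, (16, 16))
            np.testing.assert_allclose(tf.denoise(img), brute_denoise(img),
                                       atol=1e-9)


class TestBinarize:
    def test_bimodal_interior_patch_is_foreground(self):
        img = np.full((20, 20), 40.0)
        img[5:15, 5:15] = 200.0
        fg = tf.binarize(img)
        assert fg[10, 10] and not fg[0, 0]
        assert fg.sum() == 100

    def test_idempotent_on_binary_input(self):
        img = np.zeros((12, 12))
        img[3:9, 3:9] = 255.0
        fg = tf.binarize(img)
        assert np.array_equal(fg, img > 0)
        assert np.array_equal(tf.binarize(fg.astype(float) * 255), fg)

    def test_dark_interior_specimen(self):
        img = np.full((20, 20), 220.0)
        img[6:14, 6:14] = 30.0
        fg = tf.binarize(img)
        assert fg[10, 10] and fg.sum() == 64

    def test_constant_image_errors(self):
        with pytest.raises(ValueError, match="threshold"):
            tf.binarize(np.full((8, 8), 7.0))


class TestContour:
    def test_filled_square_boundary_count(self):
        mask = np.zeros((14, 14), bool)
        mask[2:12, 2:12] = True
        assert tf.extract_contour(mask).sum() == 36

    def test_single_pixel_is_its_own_contour(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        assert np.array_equal(tf.extract_contour(mask), mask)

    def test_thin_line_is_all_contour(self):
        mask = np.zeros((5, 9), bool)
        mask[2, 1:8] = True
        assert np.array_equal(tf.extract_contour(mask), mask)

    def test_frame_border_counts_as_background(self):
        mask = np.ones((4, 4), bool)
        contour = tf.extract_contour(mask)
        assert contour.sum() == 12  # interior 2x2 survives erosion

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            tf.extract_contour(np.zeros((4, 4), bool))


class TestSkeletonize:
    def test_bar_thins_to_horizontal_line(self):
        mask = np.zeros((7, 25), bool)
        mask[2:5, 2:23] = True
        sk = tf.skeletonize(mask)
        rows = np.unique(np.nonzero(sk)[0])
        assert rows.size == 1  # a single 1-px-high line
        assert sk.sum() >= 17

    def test_single_pixel_survives(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        assert np.array_equal(tf.skeletonize(mask), mask)

    def test_idempotent(self, rng):
        for _ in range(5):
            sk = tf.skeletonize(random_blob(rng))
            assert np.array_equal(tf.skeletonize(sk), sk)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            tf.skeletonize(np.zeros((3, 3), bool))


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_contour_and_skeleton_are_subsets_preserving_components(seed):
    """contour(m) and skeleton(m) are subsets of m; thinning preserves the
    8-connected component count."""
    blob = random_blob(np.random.default_rng(seed))
    contour = tf.extract_contour(blob)
    skel = tf.skeletonize(blob)
    assert not (contour & ~blob).any()
    assert not (skel & ~blob).any()
    eight = np.ones((3, 3), int)
    assert ndi.label(skel, eight)[1] == ndi.label(blob, eight)[1]


class TestRemoveBackground:
    def test_ellipse_on_uniform_background(self, rng):
        yy, xx = np.mgrid[0:60, 0:60]
        truth = ((xx - 30) / 18.0) ** 2 + ((yy - 30) / 11.0) ** 2 <= 1
        img = np.where(truth, 90.0, 200.0) + rng.normal(0, 2, (60, 60))
        _, mask = tf.remove_background(img)
        assert abs(int(mask.sum()) - int(truth.sum())) <= 0.03 * truth.sum()

    def test_mask_bypass_returns_input_unchanged(self, rng):
        img = rng.integers(0, 256, (10, 10)).astype(np.uint8)
        mask = np.zeros((10, 10), bool)
        mask[4:7, 4:7] = True
        out, m = tf.remove_background(img, mask=mask)
        assert np.array_equal(out, img)
        assert np.array_equal(m, mask)

    def test_empty_image_errors(self):
        with pytest.raises(ValueError):
            tf.remove_background(np.zeros((0, 0)))

    def test_featureless_image_errors(self):
        with pytest.raises(ValueError, match="empty foreground"):
            tf.remove_background(np.full((30, 30), 128.0))

    def test_rect_outside_bounds_errors(self):
        with pytest.raises(ValueError, match="rect"):
            tf.remove_background(np.zeros((10, 10)), rect=(0, 0, 20, 20))


class TestPreprocess:
    def test_output_shapes_and_nesting(self):
        ds = tf.generate_dataset(tf.default_specs(2), 2, seed=3)
        res = tf.preprocess(ds.images[0])
        for arr in (res.gray, res.mask, res.contour, res.skeleton):
            assert arr.shape == ds.images[0].shape
        assert not (res.contour & ~res.mask).any()
        assert not (res.skeleton & ~res.mask).any()

    def test_contour_pixels_touch_background(self):
        ds = tf.generate_dataset(tf.default_specs(2), 2, seed=3)
        res = tf.preprocess(ds.images[1])
        dilated_bg = ndi.binary_dilation(~res.mask, np.ones((3, 3), bool))
        assert (res.contour <= dilated_bg).all()
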