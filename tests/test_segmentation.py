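"""Gradient-magnitude computation and the binarization pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scratchquant import (
    BinaryMask,
    GreyImage,
    SegmentationParams,
    ValidationError,
    binarize,
    gradient_magnitude,
)
from scratchquant.segmentation import clean_mask, threshold_gradient


def brute_force_gradient_magnitude(px):
    """Independent central-difference gradient magnitude (one-sided borders)."""
    h, w = px.shape
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            if 0 < r < h - 1:
                gy = (px[r + 1, c] - px[r - 1, c]) / 2
            elif r == 0:
                gy = px[1, c] - px[0, c] if h > 1 else 0.0
            else:
                gy = px[r, c] - px[r - 1, c]
            if 0 < c < w - 1:
                gx = (px[r, c + 1] - px[r, c - 1]) / 2
            elif c == 0:
                gx = px[r, 1] - px[r, 0] if w > 1 else 0.0
            else:
                gx = px[r, c] - px[r, c - 1]
            out[r, c] = np.sqrt(gx * gx + gy * gy)
    return out


class TestGradientMagnitude:
    def test_constant_image_zero_everywhere(self):
        g = gradient_magnitude(GreyImage(np.full((20, 30), 0.5)), smoothing_sigma=1.0)
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_vertical_step_concentrated_at_edge(self):
        px = np.zeros((10, 40))
        px[:, 20:] = 1.0
        g = gradient_magnitude(GreyImage(px), smoothing_sigma=0.0)
        # central differences put all response on the two columns beside the step
        assert np.all(g[:, [19, 20]] == 0.5)
        assert np.all(g[:, :18] == 0)
        assert np.all(g[:, 22:] == 0)

    def test_matches_brute_force_on_random_textures(self, rng):
        for _ in range(5):
            px = rng.random((12, 15))
            g = gradient_magnitude(GreyImage(px), smoothing_sigma=0.0)
            np.testing.assert_allclose(g, brute_force_gradient_magnitude(px), atol=1e-9)

    def test_nonnegative_and_shape_preserving(self, rng):
        px = rng.random((33, 21))
        g = gradient_magnitude(GreyImage(px), smoothing_sigma=2.0)
        assert g.shape == px.shape
        assert np.all(g >= 0)


def brute_force_components(mask):
    """4-connected component count via flood fill (independent oracle)."""
    mask = mask.copy()
    h, w = mask.shape
    count = 0
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0]:
                continue
            count += 1
            stack = [(r0, c0)]
            mask[r0, c0] = False
            while stack:
                r, c = stack.pop()
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                        mask[rr, cc] = False
                        stack.append((rr, cc))
    return count


def textured_disk_image(rng, size=160, radius=50):
    px = np.full((size, size), 0.4)
    yy, xx = np.mgrid[:size, :size]
    d = np.hypot(yy - size / 2, xx - size / 2)
    inside = d <= radius
    px[inside] = 0.5 + 0.15 * rng.standard_normal(inside.sum())
    px[(d <= radius) & (d >= radius - 2)] = 0.8
    return GreyImage(np.clip(px, 0, 1))


class TestBinarize:
    def test_uniform_media_goes_all_black_with_warning(self):
        img = GreyImage(np.full((30, 30), 0.4))
        with pytest.warns(UserWarning, match="all-black"):
            mask = binarize(img)
        assert mask.white_count == 0

    def test_textured_disk_single_component_containing_center(self, rng):
        img = textured_disk_image(rng)
        mask = binarize(img)
        assert mask.pixels[80, 80]
        assert brute_force_components(mask.pixels) == 1

    def test_white_plus_black_is_total(self, rng):
        img = textured_disk_image(rng)
        mask = binarize(img)
        assert mask.white_count + mask.black_count == mask.height * mask.width

    def test_rejects_tiny_images(self):
        with pytest.raises(ValidationError):
            binarize(GreyImage(np.zeros((1, 5))))

    def test_dimension_preserved_through_all_stages(self, rng):
        px = rng.random((41, 57))
        params = SegmentationParams()
        g = gradient_magnitude(GreyImage(px), params.smoothing_sigma)
        raw = threshold_gradient(g, params)
        cleaned = clean_mask(raw, params)
        assert g.shape == raw.shape == cleaned.shape == px.shape

    def test_cleanup_idempotent(self, rng):
        params = SegmentationParams()
        img = textured_disk_image(rng)
        mask = binarize(img, params).pixels
        again = clean_mask(mask, params)
        np.testing.assert_array_equal(mask, again)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=0.3), st.floats(min_value=0.0, max_value=0.3))
    def test_lower_fixed_threshold_never_decreases_raw_white(self, t1, t2):
        lo, hi = sorted((t1, t2))
        rng = np.random.default_rng(5)
        g = gradient_magnitude(GreyImage(rng.random((30, 30))), 1.0)
        raw_lo = threshold_gradient(g, SegmentationParams(threshold_method="fixed", fixed_threshold=lo))
        raw_hi = threshold_gradient(g, SegmentationParams(threshold_method="fixed", fixed_threshold=hi))
        assert raw_lo.sum() >= raw_hi.sum()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            SegmentationParams(smoothing_sigma=-1)
        with pytest.raises(ValidationError):
            SegmentationParams(threshold_method="magic")


class TestBinaryMask:
    def test_bool_coercion(self):
        m = BinaryMask(np.array([[0, 1], [1, 0]]))
        assert m.pixels.dtype == bool
        assert m.white_count == 2
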