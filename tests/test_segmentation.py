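"""Tests of the lesion segmentation chain against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dermcad.preprocessing import StructuringElement, preprocess_rgb
from dermcad.segmentation import (
    NoLesionFoundError,
    SegmentationConfig,
    channel_masks,
    fuse_masks,
    iterative_median_smooth,
    mask_iou,
    morphological_open,
    open_close_filter,
    otsu_threshold,
    segment_lesion,
    size_filter,
    trace_contour,
)


def brute_force_otsu(values):
    """Exhaustive search of the between-class variance over all 255 cuts."""
    values = np.asarray(values).ravel()
    best_t, best_var = None, -1.0
    for t in range(1, 256):
        lo = values[values < t]
        hi = values[values >= t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0 = lo.size / values.size
        w1 = hi.size / values.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t


def brute_force_majority(mask, window):
    half = window // 2
    padded = np.pad(mask.astype(int), half, mode="edge")
    out = np.zeros_like(mask)
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            patch = padded[r : r + window, c : c + window]
            out[r, c] = patch.sum() * 2 > window * window
    return out


def brute_force_components(mask):
    """Flood-fill 8-connected labeling."""
    labels = np.zeros(mask.shape, int)
    nxt = 0
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if mask[r0, c0] and labels[r0, c0] == 0:
                nxt += 1
                stack = [(r0, c0)]
                labels[r0, c0] = nxt
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < mask.shape[0]
                                and 0 <= cc < mask.shape[1]
                                and mask[rr, cc]
                                and labels[rr, cc] == 0
                            ):
                                labels[rr, cc] = nxt
                                stack.append((rr, cc))
    return labels, nxt


class TestOtsu:
    def test_bimodal_split(self):
        values = np.array([10] * 50 + [200] * 50).reshape(10, 10)
        t = otsu_threshold(values)
        assert 10 < t <= 200
        assert np.array_equal(values < t, values == 10)

    def test_matches_exhaustive_search(self, rng):
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        assert otsu_threshold(img) == brute_force_otsu(img)

    def test_binary_image_recovered_exactly(self):
        img = np.array([[0, 255], [255, 0]], np.uint8)
        t = otsu_threshold(img)
        assert np.array_equal(img < t, img == 0)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full((8, 8), 7, np.uint8))


class TestChannelMasks:
    def test_noise_free_ellipse_recovered(self, clean_sample):
        masks = channel_masks(clean_sample.image)
        for m in masks:
            assert np.array_equal(m, clean_sample.mask)

    def test_identical_channels_give_identical_masks(self, rng):
        ch = rng.integers(0, 256, (20, 20)).astype(np.uint8)
        masks = channel_masks(np.stack([ch] * 3, axis=-1))
        assert np.array_equal(masks[0], masks[1])
        assert np.array_equal(masks[1], masks[2])

    def test_default_melanoma_channel_iou(self, default_melanoma):
        for m in channel_masks(default_melanoma.image):
            assert mask_iou(m, default_melanoma.mask) >= 0.7


class TestFuseMasks:
    def test_identical_masks_idempotent(self, rng):
        m = rng.random((8, 8)) > 0.5
        assert np.array_equal(fuse_masks((m, m, m)), m)

    def test_two_of_three_majority(self):
        t = np.ones((4, 4), bool)
        f = np.zeros((4, 4), bool)
        assert np.all(fuse_masks((t, t, f)))

    def test_matches_brute_force_vote(self, rng):
        masks = tuple(rng.random((8, 8)) > 0.5 for _ in range(3))
        votes = sum(m.astype(int) for m in masks)
        assert np.array_equal(fuse_masks(masks), votes >= 2)

    @settings(max_examples=20, deadline=None)
    @given(
        arrays(bool, (6, 6)), arrays(bool, (6, 6)), arrays(bool, (6, 6)),
        st.permutations([0, 1, 2]),
    )
    def test_permutation_invariant(self, a, b, c, perm):
        masks = [a, b, c]
        shuffled = tuple(masks[i] for i in perm)
        assert np.array_equal(fuse_masks((a, b, c)), fuse_masks(shuffled))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse_masks((np.ones((3, 3), bool), np.ones((3, 3), bool), np.ones((4, 4), bool)))


class TestMorphology:
    def test_disk_nearly_unchanged_by_opening(self):
        yy, xx = np.mgrid[0:30, 0:30]
        disk_mask = (yy - 15) ** 2 + (xx - 15) ** 2 <= 100
        out = morphological_open(disk_mask, StructuringElement(3))
        assert mask_iou(out, disk_mask) >= 0.95

    def test_isolated_pixel_removed(self):
        m = np.zeros((11, 11), bool)
        m[5, 5] = True
        assert not morphological_open(m, StructuringElement(2)).any()

    def test_all_true_preserved(self):
        m = np.ones((10, 10), bool)
        assert morphological_open(m, StructuringElement(2)).all()

    def test_smooth_fills_single_pixel_holes(self, rng):
        # all-true 30x30 mask with 20 punched-out pixels: the majority
        # cascade (7, 5, 3) restores the solid square
        m = np.ones((30, 30), bool)
        holes = rng.choice(30 * 30, size=20, replace=False)
        rows, cols = np.unravel_index(holes, (30, 30))
        holed = m.copy()
        holed[rows, cols] = False
        assert np.array_equal(iterative_median_smooth(holed), m)

    def test_smooth_all_true(self):
        m = np.ones((12, 12), bool)
        assert iterative_median_smooth(m).all()

    def test_smooth_matches_brute_force_cascade(self, rng):
        m = rng.random((12, 12)) > 0.5
        expected = m
        for window in (7, 5, 3):
            expected = brute_force_majority(expected, window)
        assert np.array_equal(iterative_median_smooth(m), expected)

    def test_open_close_fixed_point_stable(self):
        m = np.zeros((20, 20), bool)
        m[5:15, 5:15] = True
        stable = open_close_filter(m, StructuringElement(2))
        assert np.array_equal(open_close_filter(stable, StructuringElement(2)), stable)

    def test_open_close_removes_speck_and_fills_hole(self):
        m = np.zeros((30, 30), bool)
        m[8:22, 8:22] = True
        m[15, 15] = False  # 1-px hole
        m[2, 2] = True  # 1-px speck
        out = open_close_filter(m, StructuringElement(2))
        assert not out[2, 2]
        assert out[15, 15]

    def test_open_close_all_false(self):
        m = np.zeros((10, 10), bool)
        assert not open_close_filter(m, StructuringElement(2)).any()


class TestSizeFilter:
    def test_five_percent_cutoff(self):
        m = np.zeros((150, 150), bool)
        m[0:45, 0:25] = True  # 1125 px = 5.0% of 22500: survives
        m[100:130, 100:130] = True  # 900 px = 4.0%: removed
        out = size_filter(m, 0.05)
        assert out[10, 10]
        assert not out[110, 110]
        assert out.sum() == 1125

    def test_empty_mask(self):
        m = np.zeros((20, 20), bool)
        assert not size_filter(m).any()

    def test_matches_brute_force_labeling(self, rng):
        m = rng.random((40, 40)) > 0.7
        labels, n = brute_force_components(m)
        cutoff = 0.02 * m.size
        expected = np.zeros_like(m)
        for lab in range(1, n + 1):
            comp = labels == lab
            if comp.sum() >= cutoff:
                expected |= comp
        assert np.array_equal(size_filter(m, 0.02), expected)

    def test_idempotent(self, rng):
        m = rng.random((40, 40)) > 0.6
        once = size_filter(m, 0.03)
        assert np.array_equal(size_filter(once, 0.03), once)


class TestTraceContour:
    def test_solid_square_has_eight_boundary_points(self):
        m = np.zeros((5, 5), bool)
        m[1:4, 1:4] = True
        contour = trace_contour(m)
        assert len(contour) == 8
        assert set(contour) == {
            (1, 1), (1, 2), (1, 3), (2, 1), (2, 3), (3, 1), (3, 2), (3, 3)
        }
        # consecutive points 8-connected, closed
        pts = contour + [contour[0]]
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            assert max(abs(r0 - r1), abs(c0 - c1)) == 1

    def test_single_pixel_degenerate_contour(self):
        m = np.zeros((5, 5), bool)
        m[2, 3] = True
        assert trace_contour(m) == [(2, 3)]

    def test_disk_contour_length_near_circumference(self):
        r = 20
        yy, xx = np.mgrid[0:50, 0:50]
        m = (yy - 25) ** 2 + (xx - 25) ** 2 <= r * r
        length = len(trace_contour(m))
        assert 2 * np.pi * r * 0.8 <= length <= 2 * np.pi * r * 1.5

    def test_empty_mask_rejected(self):
        with pytest.raises(NoLesionFoundError):
            trace_contour(np.zeros((5, 5), bool))


class TestSegmentLesion:
    def test_noise_free_sample_high_iou(self, clean_sample):
        mask, contour = segment_lesion(clean_sample.image)
        assert mask_iou(mask, clean_sample.mask) >= 0.95
        assert len(contour) >= 3

    def test_preprocessed_noisy_sample_good_iou(self, default_melanoma):
        rgb, _ = preprocess_rgb(default_melanoma.image)
        mask, _ = segment_lesion(rgb)
        assert mask_iou(mask, default_melanoma.mask) >= 0.8

    def test_constant_image_raises_no_lesion(self):
        img = np.full((50, 50, 3), 128, np.uint8)
        with pytest.raises((NoLesionFoundError, ValueError)):
            segment_lesion(img)

    def test_deterministic(self, default_melanoma):
        cfg = SegmentationConfig()
        a, _ = segment_lesion(default_melanoma.image, cfg)
        b, _ = segment_lesion(default_melanoma.image, cfg)
        assert np.array_equal(a, b)
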