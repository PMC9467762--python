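"""Histogram equalization, ROAD, impulse detection and the three filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from otoseg import (ACWMConfig, NoiseSpec, acwm_filter, add_impulse_noise,
                    adaptive_median_filter, center_weighted_median,
                    detect_noise, equalize_histogram, equalize_mapping,
                    histogram, psnr, road_measure, weighted_median_filter)
from otoseg.exceptions import DomainError

small_images = hnp.arrays(np.uint8, hnp.array_shapes(min_dims=2, max_dims=2,
                                                     min_side=2, max_side=12))


class TestHistogram:
    def test_two_level_example(self):
        img = np.array([[0, 0], [255, 255]], np.uint8)
        h = histogram(img)
        assert h[0] == 2 and h[255] == 2 and h.sum() == 4

    def test_constant_image_single_bin(self):
        h = histogram(np.full((5, 7), 42, np.uint8))
        assert h[42] == 35 and (np.delete(h, 42) == 0).all()

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        h = histogram(img)
        for i in range(256):
            assert h[i] == int((img == i).sum())


class TestEqualizeHistogram:
    def test_constant_image_unchanged(self):
        img = np.full((8, 8), 99, np.uint8)
        assert (equalize_histogram(img) == img).all()

    def test_two_level_cdf_mapping(self):
        # half at 10, half at 20: CDF = 0.5, 1.0 -> levels 128 and 255
        img = np.repeat(np.array([[10], [20]], np.uint8), 8, axis=1)
        out = equalize_histogram(img)
        assert set(np.unique(out)) == {128, 255}
        assert (out[img == 10] == 128).all() and (out[img == 20] == 255).all()

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(img=small_images)
    def test_mapping_is_monotone(self, img):
        lut = equalize_mapping(img)
        assert (np.diff(lut.astype(int)) >= 0).all()

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(img=small_images)
    def test_idempotent_up_to_quantization(self, img):
        once = equalize_histogram(img)
        twice = equalize_histogram(once)
        assert np.abs(twice.astype(int) - once.astype(int)).max() <= 1


class TestRoadMeasure:
    def test_constant_image_is_zero(self):
        assert (road_measure(np.full((6, 6), 50, np.uint8)) == 0).all()

    def test_center_impulse_scores_4x255(self):
        img = np.zeros((3, 3), np.uint8)
        img[1, 1] = 255
        assert road_measure(img, k=4)[1, 1] == 1020

    def test_invariant_to_neighbor_permutation(self):
        # rank-ordered statistic: value depends on the multiset of diffs only
        rng = np.random.default_rng(1)
        nb = rng.integers(0, 256, 8)
        base = np.zeros((3, 3), np.uint8)
        vals = set()
        for perm in (nb, nb[::-1], np.roll(nb, 3)):
            img = base.copy()
            img.reshape(-1)[[0, 1, 2, 3, 5, 6, 7, 8]] = perm
            img[1, 1] = 100
            vals.add(int(road_measure(img, k=4)[1, 1]))
        assert len(vals) == 1


class TestCenterWeightedMedian:
    def test_spec_multiset_example(self):
        assert center_weighted_median(np.arange(1, 10), 5, 3) == 5

    def test_weight_one_is_plain_median(self):
        vals = np.array([9, 1, 7, 3, 5])
        assert center_weighted_median(vals, 9, 1) == 5

    def test_large_weight_returns_center(self):
        vals = np.arange(1, 10)
        assert center_weighted_median(vals, 7, 21) == 7  # weight > 2|values|

    def test_empty_values_rejected(self):
        with pytest.raises(DomainError):
            center_weighted_median(np.array([]), 5, 3)

    def test_even_weight_rejected(self):
        with pytest.raises(DomainError):
            center_weighted_median(np.array([1, 2, 3]), 2, 2)


class TestDetectNoise:
    def test_constant_image_all_clear(self):
        mask = detect_noise(np.full((32, 32), 80, np.uint8))
        assert not mask.any()

    def test_single_impulse_flagged_exactly(self):
        img = np.full((32, 32), 100, np.uint8)
        img[10, 20] = 255
        mask = detect_noise(img)
        assert mask[10, 20] and mask.sum() == 1

    def test_recall_and_fpr_on_texture_free_phantom(self, im1_phantom):
        img, _ = im1_phantom
        noisy, truth_mask = add_impulse_noise(img, NoiseSpec(0.3, "fixed", 42))
        det = detect_noise(noisy)
        recall = (det & truth_mask).sum() / truth_mask.sum()
        fpr = (det & ~truth_mask).sum() / (~truth_mask).sum()
        assert recall >= 0.95
        assert fpr <= 0.05


class TestAcwmFilter:
    def test_single_impulse_exactly_restored(self):
        img = np.full((64, 64), 100, np.uint8)
        noisy = img.copy()
        noisy[30, 31] = 255
        out, mask = acwm_filter(noisy)
        assert (out == img).all() and mask.sum() == 1

    def test_zero_noise_phantom_untouched(self, flat_phantom):
        img, _ = flat_phantom
        out, mask = acwm_filter(img)
        assert (out == img).all() and not mask.any()

    def test_zero_noise_equalized_scale_untouched(self, flat_phantom):
        img, _ = flat_phantom
        out, mask = acwm_filter(img, output_scale="equalized")
        assert (out == equalize_histogram(img)).all() and not mask.any()

    def test_never_modifies_unflagged_pixels(self, im1_phantom):
        img, _ = im1_phantom
        noisy, _ = add_impulse_noise(img, NoiseSpec(0.3, "fixed", 7))
        out, mask = acwm_filter(noisy)
        assert (out[~mask] == noisy[~mask]).all()

    def test_psnr_gain_over_noisy_at_p30(self, im1_phantom):
        img, _ = im1_phantom
        noisy, _ = add_impulse_noise(img, NoiseSpec(0.3, "fixed", 7))
        out, _ = acwm_filter(noisy)
        assert psnr(img, out) > psnr(img, noisy) + 5.0

    def test_output_range_preserved(self, im1_phantom):
        img, _ = im1_phantom
        noisy, _ = add_impulse_noise(img, NoiseSpec(0.5, "fixed", 8))
        out, _ = acwm_filter(noisy)
        assert out.dtype == np.uint8


class TestWeightedMedianFilter:
    def test_constant_image_unchanged(self):
        img = np.full((10, 10), 33, np.uint8)
        assert (weighted_median_filter(img) == img).all()

    def test_unit_weights_match_classic_median(self):
        from skimage.filters import median as sk_median
        rng = np.random.default_rng(2)
        img = rng.integers(0, 256, (20, 20)).astype(np.uint8)
        ours = weighted_median_filter(img, 3, np.ones((3, 3), np.int64))
        theirs = sk_median(img, np.ones((3, 3), bool), mode="nearest")
        assert (ours == theirs).all()

    def test_cross_weight_hand_checked_on_toy_grid(self):
        # 5x5 printed toy grid, 3x3 cross stencil, centre pixel (2, 2)
        img = np.array([[10, 20, 30, 40, 50],
                        [15, 25, 35, 45, 55],
                        [12, 22, 90, 42, 52],
                        [18, 28, 38, 48, 58],
                        [11, 21, 31, 41, 51]], np.uint8)
        w = np.array([[0, 1, 0], [1, 3, 1], [0, 1, 0]], np.int64)
        # multiset at (2,2): {35, 22, 42, 38} + 90*3 -> sorted
        # [22, 35, 38, 42, 90, 90, 90], lower median (idx 3) = 42
        out = weighted_median_filter(img, 3, w)
        assert out[2, 2] == 42

    def test_even_window_rejected(self):
        with pytest.raises(DomainError):
            weighted_median_filter(np.zeros((4, 4), np.uint8), 4)


class TestAdaptiveMedianFilter:
    def test_noise_free_ramp_unchanged(self):
        ramp = np.tile(np.arange(64, dtype=np.uint8) * 4, (16, 1))
        assert (adaptive_median_filter(ramp) == ramp).all()

    def test_single_impulse_restored(self):
        img = np.full((32, 32), 90, np.uint8)
        noisy = img.copy()
        noisy[5, 5] = 0
        assert (adaptive_median_filter(noisy) == img).all()

    def test_heavy_salt_pepper_restored_on_interior(self):
        img = np.full((128, 128), 128, np.uint8)
        noisy, _ = add_impulse_noise(img, NoiseSpec(0.4, "fixed", 13))
        out = adaptive_median_filter(noisy, max_window=9)
        assert (out[5:-5, 5:-5] == 128).all()

    def test_zero_noise_phantom_untouched(self, flat_phantom):
        img, _ = flat_phantom
        assert (adaptive_median_filter(img) == img).all()


@settings(max_examples=25, deadline=None, derandomize=True)
@given(img=small_images, p=st.sampled_from([0.1, 0.3, 0.5]),
       seed=st.integers(0, 1000))
def test_all_filters_stay_in_range(img, p, seed):
    noisy, _ = add_impulse_noise(img, NoiseSpec(p, "fixed", seed))
    for out in (weighted_median_filter(noisy),
                adaptive_median_filter(noisy),
                acwm_filter(noisy)[0]):
        assert out.dtype == np.uint8 and out.shape == img.shape
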