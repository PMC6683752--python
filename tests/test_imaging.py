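import numpy as np
import pytest
from scipy import ndimage as ndi

from rdnalinks.imaging import (
    MultiChannelImage,
    circularity,
    fill_holes,
    gaussian_blur,
    label_components,
    max_project,
    otsu_threshold,
    region_perimeter,
    region_stats,
    rolling_ball_background,
    rolling_ball_subtract,
    self_normalize,
    threshold_fraction_of_max,
)

from .conftest import crofton_perimeter_oracle


def disk_mask(shape, center, radius):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


class TestMultiChannelImage:
    def test_rejects_mismatched_shapes(self):
        with pytest.raises(ValueError, match="shape"):
            MultiChannelImage({"a": np.zeros((4, 4)), "b": np.zeros((5, 4))}, 0.1)

    def test_rejects_negative_intensities_and_bad_pixel_size(self):
        with pytest.raises(ValueError):
            MultiChannelImage({"a": -np.ones((4, 4))}, 0.1)
        with pytest.raises(ValueError):
            MultiChannelImage({"a": np.zeros((4, 4))}, 0.0)


class TestGaussianBlur:
    def test_constant_image_is_unchanged(self):
        out = gaussian_blur(np.full((32, 32), 3.5), sigma_px=2)
        assert np.allclose(out, 3.5)

    def test_interior_impulse_mass_is_preserved(self):
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        assert np.isclose(gaussian_blur(img, 2).sum(), 1.0, rtol=1e-8)

    def test_matches_dense_convolution_oracle(self, rng):
        # truncated normalized kernel + reflect padding, summed directly
        sigma = 3.0
        img = rng.random((32, 32))
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k1 = np.exp(-0.5 * (x / sigma) ** 2)
        k1 /= k1.sum()
        kernel = np.outer(k1, k1)
        padded = np.pad(img, radius, mode="symmetric")  # edge-inclusive reflection
        expected = np.zeros_like(img)
        for i in range(kernel.shape[0]):
            for j in range(kernel.shape[1]):
                expected += kernel[i, j] * padded[i : i + 32, j : j + 32]
        assert np.allclose(gaussian_blur(img, sigma), expected, rtol=1e-8, atol=1e-10)

    def test_linearity(self, rng):
        x = rng.random((24, 24))
        y = rng.random((24, 24))
        lhs = gaussian_blur(2.0 * x + 3.0 * y, 2.5)
        rhs = 2.0 * gaussian_blur(x, 2.5) + 3.0 * gaussian_blur(y, 2.5)
        assert np.allclose(lhs, rhs, rtol=1e-8)

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            gaussian_blur(np.zeros((4, 4)), 0)


class TestRollingBall:
    def test_flat_image_subtracts_to_zero(self):
        assert np.allclose(rolling_ball_subtract(np.full((40, 40), 7.0), 10), 0.0)

    def test_narrow_plateau_height_is_preserved(self):
        img = np.full((80, 80), 10.0)
        img[40:43, 40:43] += 50.0
        out = rolling_ball_subtract(img, 20)
        assert abs(out[41, 41] - 50.0) <= 1.0

    def test_wide_hill_is_background(self):
        # a hill much wider than the ball is removed almost entirely
        rr, cc = np.mgrid[:128, :128]
        hill = 100.0 * np.exp(-((rr - 64) ** 2 + (cc - 64) ** 2) / (2 * 40.0**2))
        residual = rolling_ball_subtract(hill, 8)
        assert residual.max() < 0.05 * 100.0

    def test_matches_grey_opening_oracle(self, rng):
        radius = 8.0
        img = rng.random((64, 64)) * 50
        r = int(radius)
        dys = np.arange(-r, r + 1)
        hw = np.floor(np.sqrt(radius**2 - dys.astype(float) ** 2)).astype(int)
        fp = np.zeros((len(dys), 2 * hw.max() + 1), bool)
        for i, w in enumerate(hw):
            fp[i, hw.max() - w : hw.max() + w + 1] = True
        expected = ndi.grey_opening(img, footprint=fp, mode="reflect")
        assert np.allclose(rolling_ball_background(img, radius), expected)

    @pytest.mark.parametrize("radius", [5.0, 40.0])
    def test_output_bounded_by_input(self, rng, radius):
        img = rng.random((96, 96)) * 100
        out = rolling_ball_subtract(img, radius)
        assert (out >= 0).all()
        assert (out <= img + 1e-9).all()


class TestSelfNormalize:
    def test_constant_above_floor_gives_ones(self):
        assert np.allclose(self_normalize(np.full((16, 16), 5.0), 3), 1.0)

    def test_constant_below_floor_is_unchanged(self):
        assert np.allclose(self_normalize(np.full((16, 16), 0.5), 3), 0.5)

    def test_equals_blur_division_oracle(self, rng):
        img = rng.random((32, 32)) * 4
        expected = img / np.maximum(gaussian_blur(img, 2.0), 1.0)
        assert np.allclose(self_normalize(img, 2.0), expected)


class TestThresholdFractionOfMax:
    def test_cutoff_arithmetic(self):
        img = np.array([[0.0, 29.9, 30.0], [199.0, 200.0, 15.0]])
        mask = threshold_fraction_of_max(img, 0.15)
        assert mask.tolist() == [[False, False, True], [True, True, False]]

    def test_restricted_max_comes_from_the_mask(self):
        img = np.array([[100.0, 0.0], [0.0, 10.0]])
        within = np.array([[False, True], [True, True]])
        mask = threshold_fraction_of_max(img, 0.2, within=within)
        # cutoff is 2 from the masked max of 10, not 20 from the global 100
        assert mask.tolist() == [[False, False], [False, True]]

    def test_all_zero_image_selects_everything_at_zero_cutoff(self):
        img = np.zeros((3, 3))
        img[1, 1] = 1.0
        assert threshold_fraction_of_max(img, 0.5).sum() == 1

    def test_empty_restriction_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            threshold_fraction_of_max(np.ones((3, 3)), 0.5, within=np.zeros((3, 3), bool))

    def test_mask_size_non_increasing_in_fraction(self, rng):
        img = rng.random((32, 32))
        sizes = [threshold_fraction_of_max(img, f).sum() for f in (0.1, 0.3, 0.5, 0.9, 1.0)]
        assert sizes == sorted(sizes, reverse=True)


class TestOtsu:
    def test_separates_two_classes(self):
        img = np.concatenate([np.full(50, 10.0), np.full(50, 200.0)]).reshape(10, 10)
        cutoff = otsu_threshold(img)
        assert 10 < cutoff < 200

    def test_matches_exhaustive_search_oracle(self, rng):
        # integer-valued bimodal image, 256-bin histogram
        img = np.concatenate(
            [rng.normal(60, 10, 2000), rng.normal(180, 12, 2000)]
        ).clip(0, 255).round()
        values = img
        best_var, best_cut = -1.0, None
        for cut in np.unique(values)[:-1]:
            lo, hi = values[values <= cut], values[values > cut]
            w0, w1 = len(lo) / len(values), len(hi) / len(values)
            var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
            if var > best_var:
                best_var, best_cut = var, cut
        cutoff = otsu_threshold(img.reshape(50, 80), nbins=256)
        lo = values[values <= cutoff]
        hi = values[values > cutoff]
        w0, w1 = len(lo) / len(values), len(hi) / len(values)
        impl_var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        assert impl_var >= best_var * (1 - 1e-9) or np.isclose(cutoff, best_cut, atol=1.0)

    def test_constant_image_raises(self):
        with pytest.raises(ValueError, match="constant"):
            otsu_threshold(np.full((8, 8), 3.0))


class TestLabelComponents:
    def test_empty_mask(self):
        labels, n = label_components(np.zeros((5, 5), bool))
        assert n == 0 and labels.max() == 0

    def test_diagonal_connectivity(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = mask[2, 2] = True
        assert label_components(mask, connectivity=8)[1] == 1
        assert label_components(mask, connectivity=4)[1] == 2

    def test_disjoint_disks_counted(self):
        mask = np.zeros((90, 90), bool)
        for i in range(3):
            for j in range(3):
                mask |= disk_mask(mask.shape, (15 + 30 * i, 15 + 30 * j), 5)
        assert label_components(mask)[1] == 9

    def test_labels_cover_mask_and_are_disjoint(self, rng):
        mask = rng.random((40, 40)) > 0.7
        labels, n = label_components(mask)
        assert ((labels > 0) == mask).all()
        assert set(np.unique(labels)) == set(range(n + 1)) - ({0} - set(np.unique(labels)))

    def test_count_invariant_under_translation(self, rng):
        mask = np.zeros((64, 64), bool)
        mask[10:20, 10:20] = True
        mask |= disk_mask(mask.shape, (40, 40), 6)
        n0 = label_components(mask)[1]
        assert label_components(np.roll(mask, (5, 7), axis=(0, 1)))[1] == n0


class TestFillHoles:
    def test_solid_disk_unchanged(self):
        disk = disk_mask((40, 40), (20, 20), 10)
        assert (fill_holes(disk) == disk).all()

    def test_annulus_becomes_solid(self):
        outer = disk_mask((40, 40), (20, 20), 12)
        inner = disk_mask((40, 40), (20, 20), 6)
        assert (fill_holes(outer & ~inner) == outer).all()

    def test_border_connected_background_not_filled(self):
        mask = np.ones((10, 10), bool)
        mask[:5, 4:6] = False  # channel open to the top border
        assert (fill_holes(mask) == mask).all()


class TestMaxProject:
    def test_single_plane_identity(self, rng):
        plane = rng.random((8, 8))
        assert (max_project(plane[None]) == plane).all()

    def test_disjoint_spots_both_survive(self):
        stack = np.zeros((2, 8, 8))
        stack[0, 2, 2] = 5
        stack[1, 6, 6] = 7
        out = max_project(stack)
        assert out[2, 2] == 5 and out[6, 6] == 7

    def test_equals_elementwise_max_oracle(self, rng):
        stack = rng.random((5, 12, 12))
        assert (max_project(stack) == stack.max(axis=0)).all()


class TestRegionStats:
    def test_disk_circularity_is_near_one(self):
        labels, _ = label_components(disk_mask((256, 256), (128, 128), 50))
        s = region_stats(labels, pixel_size_um=0.11)[0]
        assert abs(s.circularity - 1.0) <= 0.05

    def test_zero_area_circularity_is_zero(self):
        assert circularity(0, 10.0) == 0.0

    def test_square_perimeter_matches_intercept_count_oracle(self):
        mask = np.zeros((30, 30), bool)
        mask[5:15, 5:15] = True
        assert np.isclose(region_perimeter(mask), crofton_perimeter_oracle(mask))
        labels, _ = label_components(mask)
        s = region_stats(labels, 1.0)[0]
        expected = min(1.0, 4 * np.pi * 100 / crofton_perimeter_oracle(mask) ** 2)
        assert np.isclose(s.circularity, expected)

    def test_areas_sum_to_mask_and_unit_ratio_constant(self, rng):
        mask = rng.random((48, 48)) > 0.6
        labels, n = label_components(mask)
        stats = region_stats(labels, pixel_size_um=0.2)
        assert sum(s.area_px for s in stats) == mask.sum()
        ratios = {round(s.area_um2 / s.area_px, 12) for s in stats}
        assert ratios == {round(0.2**2, 12)}

    def test_mean_intensity_and_border_flag(self):
        labels = np.zeros((6, 6), int)
        labels[0, 0:2] = 1
        labels[3:5, 3:5] = 2
        intensity = np.arange(36, dtype=float).reshape(6, 6)
        s1, s2 = region_stats(labels, 1.0, intensity=intensity)
        assert s1.touches_border and not s2.touches_border
        assert s1.mean_intensity == intensity[0, 0:2].mean()
        assert s2.mean_intensity == intensity[3:5, 3:5].mean()

    def test_unknown_label_raises(self):
        labels = np.zeros((4, 4), int)
        labels[1, 1] = 1
        with pytest.raises(KeyError):
            region_stats(labels, 1.0, only=[2])
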