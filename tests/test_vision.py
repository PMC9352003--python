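"""Vision pipeline: preprocessing, segmentation, moments, classifiers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from applegrade.errors import (
    DegenerateInputError,
    EmptyMaskError,
    InvalidParameterError,
)
from applegrade.vision import (
    ContourPolygon,
    VisionConfig,
    aspect_ratio,
    classify_defect,
    classify_shape,
    classify_size,
    contour_centroid,
    critical_defect_ratio,
    defect_ratio,
    extract_defects,
    fit_size_calibration,
    gamma_correct,
    gaussian_smooth,
    largest_contour,
    max_cross_diameter,
    measure_appearance,
    raw_moment,
    segment_fruit,
    size_thresholds,
)

from .conftest import draw_disc, draw_ellipse, solid_image


class TestGammaCorrect:
    def test_identity_at_gamma_one(self, rng):
        img = rng.integers(0, 256, size=(20, 30, 3), dtype=np.uint8)
        assert np.array_equal(gamma_correct(img, 1.0), img)

    def test_extremes_are_fixed_points(self):
        img = solid_image((5, 5), (0, 255, 0))
        for g in (0.3, 1.0, 2.7):
            out = gamma_correct(img, g)
            assert np.array_equal(out, img)

    def test_power_law_value(self):
        # 64/255 ~ 0.251; 0.251**0.5 * 255 = 127.9 -> 128
        img = solid_image((2, 2), (64, 64, 64))
        assert np.all(gamma_correct(img, 0.5) == 128)

    @pytest.mark.parametrize("gamma", [0.0, -1.0])
    def test_rejects_nonpositive_gamma(self, gamma):
        with pytest.raises(InvalidParameterError):
            gamma_correct(solid_image((2, 2), (1, 1, 1)), gamma)


class TestGaussianSmooth:
    def test_constant_image_unchanged(self):
        img = solid_image((16, 16), (120, 80, 40))
        assert np.array_equal(gaussian_smooth(img, 2.0), img)

    def test_mass_conserved_under_reflective_boundary(self, rng):
        img = rng.integers(0, 256, size=(32, 32, 3), dtype=np.uint8)
        out = gaussian_smooth(img, 1.5)
        # rounding to uint8 costs at most 0.5 per pixel
        assert abs(int(out.sum()) - int(img.sum())) / img.sum() < 1e-3

    def test_impulse_matches_direct_convolution(self):
        img = np.zeros((21, 21, 3), dtype=np.uint8)
        img[10, 10] = 255
        sigma = 1.5
        out = gaussian_smooth(img, sigma).astype(float)
        # brute-force direct summation oracle over the full image
        yy, xx = np.mgrid[0:21, 0:21]
        kernel = np.exp(-((yy - 10.0) ** 2 + (xx - 10.0) ** 2) / (2 * sigma**2))
        kernel = 255.0 * kernel / kernel.sum()
        assert np.max(np.abs(out[..., 0] - kernel)) <= 1.0  # integer rounding

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(InvalidParameterError):
            gaussian_smooth(solid_image((4, 4), (9, 9, 9)), 0.0)


class TestSegmentFruit:
    def test_white_image_gives_empty_mask(self, config):
        assert not segment_fruit(solid_image((40, 40), (250, 250, 250)), config).any()

    def test_red_disc_area_close_to_analytic(self, config):
        img = solid_image((160, 160), (250, 250, 250))
        disc = draw_disc((160, 160), (80, 80), 60)
        img[disc] = (200, 40, 40)
        mask = segment_fruit(img, config)
        assert abs(mask.sum() - np.pi * 60**2) / (np.pi * 60**2) < 0.02

    def test_specular_hole_is_filled(self, config):
        img = solid_image((160, 160), (250, 250, 250))
        disc = draw_disc((160, 160), (80, 80), 60)
        hole = draw_disc((160, 160), (70, 75), 10)
        img[disc] = (200, 40, 40)
        img[hole & disc] = (250, 250, 250)
        mask = segment_fruit(img, config)
        assert mask[hole & disc].all()


class TestLargestContour:
    def test_square_boundary_pixel_count(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True  # 10x10 square: 4*10 - 4 boundary pixels
        contour = largest_contour(mask)
        assert len(contour.points) == 36
        xs, ys = contour.points[:, 0], contour.points[:, 1]
        assert xs.min() == 5 and xs.max() == 14 and ys.min() == 5 and ys.max() == 14

    def test_larger_of_two_discs_wins(self):
        mask = draw_disc((120, 200), (50, 60), 30) | draw_disc((120, 200), (150, 60), 10)
        contour = largest_contour(mask)
        assert contour.points[:, 0].max() < 100  # stays on the radius-30 disc

    def test_full_frame_boundary_is_border_ring(self):
        mask = np.ones((8, 11), dtype=bool)
        contour = largest_contour(mask)
        expected = 2 * 8 + 2 * 11 - 4
        assert len(contour.points) == expected

    def test_contour_is_closed_under_8_connectivity(self):
        mask = draw_disc((60, 60), (30, 30), 20)
        pts = largest_contour(mask).points
        gaps = np.abs(np.diff(np.vstack([pts, pts[:1]]), axis=0))
        assert gaps.max() <= 1

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            largest_contour(np.zeros((5, 5), dtype=bool))


class TestDefects:
    def _fruit_image(self):
        img = solid_image((120, 120), (250, 250, 250))
        disc = draw_disc((120, 120), (60, 60), 45)
        img[disc] = (200, 60, 50)
        return img, disc

    def test_uniform_fruit_has_empty_defect_mask(self, config):
        img, disc = self._fruit_image()
        assert extract_defects(img, disc, config).sum() == 0

    def test_dark_blob_pixel_count_recovered_exactly(self, config):
        img, disc = self._fruit_image()
        blob = draw_disc((120, 120), (55, 60), 6) & disc
        img[blob] = (40, 20, 15)
        defects = extract_defects(img, disc, config)
        assert defects.sum() == blob.sum()

    def test_dark_pixels_outside_fruit_excluded(self, config):
        img, disc = self._fruit_image()
        img[2:6, 2:6] = (0, 0, 0)
        defects = extract_defects(img, disc, config)
        assert not defects[~disc].any()

    def test_defect_ratio_of_rendered_spot_matches_area_ratio(self):
        # blemish/fruit diameter ratio 3:70 -> t ~ (3/70)^2; drawn at 6 px on
        # 140 px so the spot itself rasterizes faithfully
        fruit = draw_disc((200, 200), (100, 100), 70)
        spot = draw_disc((200, 200), (90, 100), 3) & fruit
        t = defect_ratio(spot, fruit)
        assert abs(t - 0.00184) / 0.00184 < 0.15

    def test_defect_ratio_zero_and_errors(self):
        fruit = draw_disc((40, 40), (20, 20), 10)
        assert defect_ratio(np.zeros_like(fruit), fruit) == 0.0
        with pytest.raises(EmptyMaskError):
            defect_ratio(np.zeros_like(fruit), np.zeros_like(fruit))
        with pytest.raises(InvalidParameterError):
            defect_ratio(~fruit, fruit)  # not a subset

    def test_critical_ratio_formula(self):
        assert critical_defect_ratio(3, 70) == pytest.approx((3 / 70) ** 2)


class TestClassifiers:
    @pytest.mark.parametrize(
        "t,label",
        [(0.0, "normal"), (0.001, "normal"), (0.0018, "defective"), (0.5, "defective")],
    )
    def test_defect_boundaries(self, t, label, config):
        assert classify_defect(t, config) == label

    def test_defect_rejects_out_of_range(self, config):
        for t in (-0.1, 1.5):
            with pytest.raises(InvalidParameterError):
                classify_defect(t, config)

    @pytest.mark.parametrize(
        "lam,label",
        [
            (1.00, "nearly_round"),
            (0.98, "nearly_round"),
            (1.05, "nearly_oval"),
            (0.97, "nearly_oval"),
            (0.50, "nearly_oval"),
        ],
    )
    def test_shape_boundaries(self, lam, label, config):
        assert classify_shape(lam, config) == label

    @pytest.mark.parametrize(
        "wp,label",
        [
            (200, "extra_large"),
            (164, "extra_large"),
            (150, "large"),
            (139, "large"),
            (127, "medium"),
            (100, "small"),
            (0, "small"),
        ],
    )
    def test_size_boundaries(self, wp, label, config):
        assert classify_size(wp, config) == label

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=50, deadline=None)
    def test_defect_labels_partition_unit_interval(self, t):
        assert classify_defect(t) in ("normal", "defective")

    @given(st.floats(min_value=1e-3, max_value=10.0))
    @settings(max_examples=50, deadline=None)
    def test_shape_labels_partition_positive_reals(self, lam):
        assert classify_shape(lam) in ("nearly_round", "nearly_oval")


class TestAspectRatio:
    def test_circle_close_to_one(self):
        lam = aspect_ratio(largest_contour(draw_disc((140, 140), (70, 70), 60)))
        assert lam == pytest.approx(1.0, abs=0.02)

    def test_ellipse_extent_ratio(self):
        mask = draw_ellipse((260, 300), (150, 130), 120, 100)
        lam = aspect_ratio(largest_contour(mask))
        assert lam == pytest.approx(1.20, abs=0.02)

    def test_square_is_exactly_one(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:25, 5:25] = True
        assert aspect_ratio(largest_contour(mask)) == 1.0


class TestMoments:
    def test_m00_is_pixel_count(self, rng):
        mask = rng.uniform(size=(17, 23)) < 0.4
        assert raw_moment(mask, 0, 0) == mask.sum()

    def test_centroid_of_centered_square(self):
        mask = np.zeros((21, 21), dtype=bool)
        mask[8:13, 8:13] = True
        assert contour_centroid(mask) == (10.0, 10.0)

    def test_matches_double_loop_on_small_masks(self, rng):
        for _ in range(5):
            mask = rng.uniform(size=(8, 9)) < 0.5
            for p, q in [(0, 0), (1, 0), (0, 1), (2, 1), (3, 2)]:
                direct = sum(
                    (x**p) * (y**q)
                    for y in range(mask.shape[0])
                    for x in range(mask.shape[1])
                    if mask[y, x]
                )
                assert raw_moment(mask, p, q) == direct

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_moment_equals_exhaustive_sum_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        h, w = int(rng.integers(1, 64)), int(rng.integers(1, 64))
        mask = rng.uniform(size=(h, w)) < 0.3
        p, q = int(rng.integers(0, 3)), int(rng.integers(0, 3))
        direct = sum(
            (x**p) * (y**q) for y in range(h) for x in range(w) if mask[y, x]
        )
        assert raw_moment(mask, p, q) == direct

    def test_centroid_of_rendered_disc(self):
        mask = draw_disc((300, 400), (200, 150), 40)
        xc, yc = contour_centroid(mask)
        assert abs(xc - 200) < 0.5 and abs(yc - 150) < 0.5

    def test_single_pixel_centroid(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[3, 7] = True
        assert contour_centroid(mask) == (7.0, 3.0)

    def test_centroid_translates_exactly(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:12, 6:15] = True
        x0, y0 = contour_centroid(mask)
        x1, y1 = contour_centroid(np.roll(np.roll(mask, 9, axis=0), 4, axis=1))
        assert (x1 - x0, y1 - y0) == (4.0, 9.0)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            contour_centroid(np.zeros((4, 4), dtype=bool))


class TestMaxCrossDiameter:
    def test_disc_diameter(self):
        contour = largest_contour(draw_disc((140, 140), (70, 70), 50))
        assert max_cross_diameter(contour) == pytest.approx(100, abs=1)

    def test_ellipse_major_axis(self):
        contour = largest_contour(draw_ellipse((160, 200), (100, 80), 80, 60))
        assert max_cross_diameter(contour) == pytest.approx(160, abs=1)

    @pytest.mark.parametrize("seed", range(4))
    def test_hull_restriction_matches_all_points_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        mask = draw_ellipse(
            (220, 220),
            (110 + rng.integers(-10, 10), 110),
            60 + rng.integers(0, 30),
            50 + rng.integers(0, 30),
        )
        contour = largest_contour(mask)
        cx, cy = contour.centroid
        brute = 2 * np.hypot(contour.points[:, 0] - cx, contour.points[:, 1] - cy).max()
        assert max_cross_diameter(contour) == pytest.approx(brute, abs=1e-9)

    def test_single_point_contour_is_zero(self):
        c = ContourPolygon(points=np.array([[3.0, 4.0]]), centroid=(3.0, 4.0))
        assert max_cross_diameter(c) == 0.0


class TestSizeCalibration:
    def test_noiseless_recovery(self):
        wp = np.linspace(100, 200, 20)
        pairs = np.column_stack([wp, 0.4052 * wp + 13.5015])
        cal = fit_size_calibration(pairs)
        assert cal.slope == pytest.approx(0.4052)
        assert cal.intercept == pytest.approx(13.5015)
        assert cal.r_squared == pytest.approx(1.0)

    def test_noisy_simulation_within_three_standard_errors(self, rng):
        n, slope, intercept, sd = 150, 0.4, 13.5, 2.0
        wp = rng.uniform(100, 200, size=n)
        wr = slope * wp + intercept + rng.normal(0, sd, size=n)
        cal = fit_size_calibration(np.column_stack([wp, wr]))
        se_slope = sd / (np.std(wp) * np.sqrt(n))
        assert abs(cal.slope - slope) < 3 * se_slope

    def test_two_points_interpolate_exactly(self):
        cal = fit_size_calibration([(100, 50), (200, 90)])
        assert cal.slope == pytest.approx(0.4)
        assert cal.r_squared == pytest.approx(1.0)

    def test_identical_wp_raises(self):
        with pytest.raises(DegenerateInputError):
            fit_size_calibration([(100, 50), (100, 60)])


class TestSizeThresholds:
    def test_reference_calibration_gives_published_pixel_cuts(self):
        from applegrade.vision import SizeCalibration

        cal = SizeCalibration(0.4052, 13.5015, 0.8462, 3.9806, 150)
        assert size_thresholds(cal, (80, 70, 65)) == (164, 139, 127)

    def test_identity_calibration(self):
        from applegrade.vision import SizeCalibration

        cal = SizeCalibration(1.0, 0.0, 1.0, 0.0, 2)
        assert size_thresholds(cal, (70,)) == (70,)


class TestTranslationInvariance:
    def test_measurements_stable_under_fruit_shift(self):
        from applegrade.synthfruit import ImageSpec, render_apple

        spec = ImageSpec(
            diameter_px=120, aspect=1.1, defect_fraction=0.008, frame=(260, 300), seed=3
        )
        img, _ = render_apple(spec)
        base = measure_appearance(img)
        shifted = np.roll(np.roll(img, 25, axis=0), -30, axis=1)
        res = measure_appearance(shifted)
        assert abs(res.diameter_px - base.diameter_px) <= 1.0
        assert abs(res.aspect_ratio - base.aspect_ratio) <= 0.02
        assert abs(res.defect_ratio - base.defect_ratio) / base.defect_ratio <= 0.05
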