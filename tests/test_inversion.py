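"""Calibration, log-ratio maps, depth inversion, and profile statistics."""

import numpy as np
import pytest

from fluordepth.inversion import (
    CalibratedImage,
    DepthMap,
    CalibrationError,
    calibrate_image,
    depth_error,
    depth_map,
    invert_linear,
    invert_semi_infinite_emission,
    log_ratio_map,
    profile_stats,
)
from fluordepth.models import (
    RatioModelSpec,
    linear_ratio_model,
    make_channel,
    ratio_semi_infinite_emission,
)
from fluordepth.optics import OpticalProperties


@pytest.fixture(scope="module")
def planar_model(channel_pair):
    spec = RatioModelSpec("dual_excitation", "semi_infinite", "planar")
    return linear_ratio_model(spec, *channel_pair)


class TestCalibrateImage:
    def test_exact_cancellation(self):
        raw = np.full((4, 4), 7.0)
        out = calibrate_image(raw, raw, np.ones((2, 2)))
        assert np.all(out.pixels == 0)

    def test_normalization_by_median(self):
        calib = np.full((3, 3), 5.0)
        raw = np.full((4, 4), 10.0)
        out = calibrate_image(raw, np.zeros((4, 4)), calib)
        assert np.all(out.pixels == pytest.approx(2.0))

    def test_median_not_mean(self):
        calib = np.array([1.0, 1.0, 1.0, 100.0])
        raw = np.full((2, 2), 3.0)
        out = calibrate_image(raw, np.zeros((2, 2)), calib)
        assert np.all(out.pixels == pytest.approx(3.0))

    def test_negative_pixels_floored(self):
        raw = np.array([[1.0, 5.0]])
        bg = np.array([[2.0, 1.0]])
        out = calibrate_image(raw, bg, np.ones(3))
        assert out.pixels[0, 0] == 0.0
        assert out.pixels[0, 1] == 4.0

    def test_nonpositive_calibration_median(self):
        with pytest.raises(CalibrationError):
            calibrate_image(np.ones((2, 2)), np.zeros((2, 2)), np.zeros(3))


class TestLogRatioMap:
    def _img(self, arr, lam=640.0):
        return CalibratedImage(np.asarray(arr, float), lam)

    def test_equal_images(self):
        a = self._img(np.full((3, 3), 2.0))
        out = log_ratio_map(a, self._img(np.full((3, 3), 2.0), 760.0))
        assert np.all(out.values[~out.mask] == 0)

    def test_factor_e(self):
        base = np.full((3, 3), 2.0)
        out = log_ratio_map(
            self._img(np.e * base), self._img(base, 760.0), calib=1.0
        )
        assert out.values[~out.mask] == pytest.approx(1.0)

    def test_zero_pixels_masked_not_infinite(self):
        a = np.array([[1.0, 1.0], [1.0, 1.0]])
        b = np.array([[1.0, 0.0], [1.0, 1.0]])
        out = log_ratio_map(self._img(a), self._img(b, 760.0),
                            noise_floor_fraction=0.0)
        assert out.mask[0, 1]
        assert np.all(np.isfinite(out.values))

    def test_noise_floor_masking(self):
        a = np.array([[100.0, 0.5]])
        b = np.array([[100.0, 100.0]])
        out = log_ratio_map(self._img(a), self._img(b, 760.0))
        assert out.mask[0, 1]  # below 1% of channel-1 max

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            log_ratio_map(self._img(np.ones((2, 2))), self._img(np.ones((3, 3))))


class TestInvertLinear:
    def test_round_trip(self, planar_model):
        lg = planar_model(10.0)
        d, clamped = invert_linear(lg, planar_model)
        assert d == pytest.approx(10.0, abs=1e-12)
        assert not clamped

    def test_intercept_maps_to_zero(self, planar_model):
        d, _ = invert_linear(planar_model.intercept, planar_model)
        assert d == 0.0

    def test_worked_example(self, channel_pair):
        """Frozen forward value from the infinite point model at 10 mm."""
        spec = RatioModelSpec("dual_excitation", "infinite", "point")
        m = linear_ratio_model(spec, *channel_pair)
        d, _ = invert_linear(m.slope * 10 + m.intercept, m)
        assert d == pytest.approx(10.0, abs=1e-2)

    def test_negative_clamped_with_flag(self, planar_model):
        sign = -1 if planar_model.slope > 0 else 1
        lg = planar_model.intercept + sign * abs(planar_model.slope)
        d, clamped = invert_linear(lg, planar_model)
        assert d == 0.0 and clamped

    def test_zero_slope_degenerate(self, channel_pair):
        spec = RatioModelSpec("dual_excitation", "infinite", "point")
        p = OpticalProperties(700, 0.03, 1.0, 1.3)
        m = linear_ratio_model(
            spec, make_channel("target", p), make_channel("reference", p)
        )
        with pytest.raises(ZeroDivisionError):
            invert_linear(0.1, m)


class TestInvertSemiInfiniteEmission:
    @pytest.mark.parametrize("d_true", [1.0, 3.0, 4.0, 7.0])
    def test_round_trip(self, channel_pair, d_true):
        t, r = channel_pair
        ratio = ratio_semi_infinite_emission(d_true, t, r)
        d = invert_semi_infinite_emission(ratio, t, r)
        assert d == pytest.approx(d_true, abs=1e-3)

    def test_out_of_range_ratio(self, channel_pair):
        t, r = channel_pair
        hi = ratio_semi_infinite_emission(1e-3, t, r)
        lo = ratio_semi_infinite_emission(50.0, t, r)
        outside = hi * 2 if hi > lo else hi / 2
        with pytest.raises(ValueError):
            invert_semi_infinite_emission(outside, t, r)


class TestDepthMap:
    def test_constant_map(self, planar_model):
        lg = np.full((5, 5), planar_model(4.0))
        lrm_img = CalibratedImage(np.exp(lg), 640.0)
        ones = CalibratedImage(np.ones((5, 5)), 760.0)
        lrm = log_ratio_map(lrm_img, ones)
        dm = depth_map(lrm, planar_model)
        assert np.allclose(dm.depths_mm[~dm.mask], 4.0)

    def test_mask_preserved(self, planar_model):
        a = np.ones((4, 4))
        b = np.ones((4, 4))
        b[1, 2] = 0.0
        lrm = log_ratio_map(
            CalibratedImage(a, 640.0), CalibratedImage(b, 760.0),
            noise_floor_fraction=0.0,
        )
        dm = depth_map(lrm, planar_model)
        assert np.array_equal(dm.mask, lrm.mask)
        assert np.isnan(dm.depths_mm[1, 2])

    def test_no_unmasked_negative_depths(self, planar_model):
        rng = np.random.default_rng(0)
        a = rng.uniform(0.5, 2.0, (16, 16))
        b = rng.uniform(0.5, 2.0, (16, 16))
        lrm = log_ratio_map(CalibratedImage(a, 640.0), CalibratedImage(b, 760.0))
        dm = depth_map(lrm, planar_model)
        assert np.all(dm.depths_mm[~dm.mask] >= 0)


class TestEndToEndIdentity:
    def test_forward_then_invert_recovers_depth(self, planar_model):
        """Images generated from the model at a per-pixel depth field invert
        back to that field to machine precision."""
        rng = np.random.default_rng(3)
        depths = rng.uniform(2.0, 10.0, (12, 12))
        i2 = rng.uniform(0.5, 2.0, (12, 12))
        i1 = i2 * np.exp(planar_model(depths))
        lrm = log_ratio_map(
            CalibratedImage(i1, 640.0), CalibratedImage(i2, 760.0),
            noise_floor_fraction=0.0,
        )
        dm = depth_map(lrm, planar_model)
        assert np.allclose(dm.depths_mm[~dm.mask], depths[~dm.mask], atol=1e-10)

    def test_calibration_invariance(self, planar_model):
        """Scaling raw and calibration images of one channel by a common
        constant leaves the depth map unchanged."""
        rng = np.random.default_rng(4)
        raw1 = rng.uniform(1, 2, (8, 8))
        raw2 = rng.uniform(1, 2, (8, 8))
        bg = np.zeros((8, 8))
        well = np.full((3, 3), 2.0)

        def pipeline(scale1):
            c1 = calibrate_image(raw1 * scale1, bg, well * scale1, 640.0)
            c2 = calibrate_image(raw2, bg, well, 760.0)
            lrm = log_ratio_map(c1, c2)
            return depth_map(lrm, planar_model).depths_mm

        assert np.allclose(pipeline(1.0), pipeline(37.5), equal_nan=True)


class TestProfileStats:
    def _dm(self, arr):
        arr = np.asarray(arr, float)
        return DepthMap(arr, np.zeros_like(arr, bool), 0.5)

    def test_constant_profile(self):
        dm = self._dm(np.full((41, 41), 5.0))
        st = profile_stats(dm, (20, 20), "x", 10.0)
        assert st.mean_mm == 5.0 and st.std_mm == 0.0

    def test_sample_count_inclusive(self):
        dm = self._dm(np.zeros((41, 41)))
        st = profile_stats(dm, (20, 20), "y", 10.0)
        assert st.n_pixels == 21  # 10 mm at 0.5 mm pixels, inclusive ends

    def test_population_std(self):
        arr = np.zeros((7, 7))
        arr[2:5, 3] = [4.0, 5.0, 6.0]
        dm = DepthMap(arr, np.zeros_like(arr, bool), 1.0)
        st = profile_stats(dm, (3, 3), "x", 2.0)
        assert st.mean_mm == pytest.approx(5.0)
        assert st.std_mm == pytest.approx(np.sqrt(2 / 3))

    def test_out_of_bounds(self):
        dm = self._dm(np.zeros((5, 5)))
        with pytest.raises(ValueError):
            profile_stats(dm, (2, 2), "x", 10.0)


class TestDepthError:
    @pytest.mark.parametrize(
        "est,true,eps,rel",
        [(10.0, 10.0, 0.0, 0.0), (13.33, 10.0, 3.33, 33.3), (8.0, 10.0, -2.0, -20.0)],
    )
    def test_values(self, est, true, eps, rel):
        e, r = depth_error(est, true)
        assert e == pytest.approx(eps)
        assert r == pytest.approx(rel, abs=0.05)

    def test_zero_true_depth(self):
        e, r = depth_error(1.0, 0.0)
        assert e == 1.0 and r is None
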