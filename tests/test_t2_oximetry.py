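"""T2 relaxometry: ROI erosion, exponential fitting, saturation calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from fetalflux.types import CalibrationModel, T2PhantomSpec, ValidationError
from fetalflux.synthetic import disk_mask, make_t2_phantom
from fetalflux.t2_oximetry import (erode_to_central_fraction, fit_t2,
                                   mean_roi_signal, so2_to_t2, t2_to_so2)

PREP_TIMES = np.array([32.0, 64.0, 96.0, 128.0, 160.0, 192.0])


class TestErosion:
    def test_fraction_one_is_identity(self):
        mask = disk_mask((31, 31), 9)
        assert np.array_equal(erode_to_central_fraction(mask, 1.0), mask)

    def test_tiny_fraction_keeps_single_deepest_pixel(self):
        mask = disk_mask((31, 31), 9)
        out = erode_to_central_fraction(mask, 1e-9)
        assert out.sum() == 1
        dist = ndimage.distance_transform_edt(mask)
        assert dist[out][0] == dist.max()

    def test_central_60_percent_of_disk(self):
        mask = disk_mask((41, 41), 10)
        out = erode_to_central_fraction(mask, 0.6)
        n, k = int(mask.sum()), int(out.sum())
        assert abs(k - 0.6 * n) <= 1
        dist = ndimage.distance_transform_edt(mask)
        kept = dist[out]
        discarded = dist[mask & ~out]
        assert kept.min() >= discarded.max() - 1e-9

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           fraction=st.floats(0.05, 1.0, allow_nan=False))
    def test_subset_and_never_grows(self, seed, fraction):
        rng = np.random.default_rng(seed)
        mask = rng.random((12, 12)) > 0.5
        if not mask.any():
            mask[5, 5] = True
        out = erode_to_central_fraction(mask, fraction)
        assert out.sum() >= 1
        assert out.sum() <= mask.sum()
        assert not np.any(out & ~mask)          # subset

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            erode_to_central_fraction(np.zeros((5, 5), bool), 0.6)


class TestMeanRoiSignal:
    def test_constant_image(self):
        spec = T2PhantomSpec(t2_ms=1e12, s0=7.0)
        series = make_t2_phantom(spec)
        roi = disk_mask(series.images.shape[1:], 5)
        assert np.allclose(mean_roi_signal(series, roi), 7.0)

    def test_single_pixel_roi(self):
        spec = T2PhantomSpec(t2_ms=120.0, s0=200.0)
        series = make_t2_phantom(spec)
        roi = np.zeros(series.images.shape[1:], bool)
        centre = series.images.shape[1] // 2
        roi[centre, centre] = True
        assert np.allclose(mean_roi_signal(series, roi),
                           series.images[:, centre, centre])

    def test_noiseless_phantom_follows_exponential(self):
        spec = T2PhantomSpec(t2_ms=120.0, s0=200.0, noise_sd=0.0)
        series = make_t2_phantom(spec)
        roi = disk_mask(series.images.shape[1:], spec.vessel_radius_px)
        expected = 200.0 * np.exp(-PREP_TIMES / 120.0)
        assert np.allclose(mean_roi_signal(series, roi), expected)


class TestFitT2:
    @pytest.mark.parametrize("method", ["loglinear", "iterative"])
    def test_noiseless_exact_recovery(self, method):
        signal = 200.0 * np.exp(-PREP_TIMES / 120.0)
        fit = fit_t2(signal, PREP_TIMES, method=method)
        assert fit.t2_ms == pytest.approx(120.0, rel=1e-9)
        assert fit.s0 == pytest.approx(200.0, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_methods_agree_on_noiseless_data(self):
        for t2 in (40.0, 90.0, 160.0, 240.0):
            signal = 150.0 * np.exp(-PREP_TIMES / t2)
            a = fit_t2(signal, PREP_TIMES, "loglinear")
            b = fit_t2(signal, PREP_TIMES, "iterative")
            assert b.t2_ms == pytest.approx(a.t2_ms, rel=1e-9)

    def test_flat_signal_hits_upper_bound(self):
        fit = fit_t2(np.full(6, 50.0), PREP_TIMES)
        assert fit.at_upper_bound

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_t2([1.0, 0.5], [32.0, 64.0])

    def test_nonpositive_signal_rejected_for_loglinear(self):
        with pytest.raises(ValidationError):
            fit_t2([5.0, 1.0, -0.1, 0.2, 0.1, 0.05], PREP_TIMES, "loglinear")

    def test_noise_recovery_monte_carlo(self, rng):
        """At SNR 50, 300 replicates: small relative RMSE and bias."""
        t2_true = 120.0
        clean = 200.0 * np.exp(-PREP_TIMES / t2_true)
        estimates = [fit_t2(clean + rng.normal(0, 4.0, 6), PREP_TIMES).t2_ms
                     for _ in range(300)]
        rel = (np.asarray(estimates) - t2_true) / t2_true
        assert np.sqrt(np.mean(rel**2)) < 0.05
        assert abs(np.mean(rel)) < 0.01


class TestCalibration:
    def test_full_saturation_gives_plateau(self, calib):
        assert so2_to_t2(1.0, calib) == pytest.approx(calib.t2_plateau_ms)
        assert t2_to_so2(calib.t2_plateau_ms, calib).y == pytest.approx(1.0)

    def test_zero_saturation(self, calib):
        expected = 1.0 / (1.0 / calib.t2_plateau_ms + calib.k_rate)
        assert so2_to_t2(0.0, calib) == pytest.approx(expected)

    def test_round_trip_identity(self, calib):
        for y in (0.0, 0.25, 0.5, 0.75, 1.0):
            back = t2_to_so2(so2_to_t2(y, calib), calib)
            assert back.y == pytest.approx(y, abs=1e-9)
            assert not back.clamped

    def test_quadratic_inversion_hand_example(self):
        # with T2_plateau=250 ms and K=2.5e-4 /ms, 1/t2 - 1/250 = K * 0.25
        # corresponds to (1-Y)^2 = 0.25, i.e. Y = 0.5
        calib = CalibrationModel(t2_plateau_ms=250.0, k_rate=2.5e-4)
        t2 = 1.0 / (1.0 / 250.0 + 2.5e-4 * 0.25)
        assert t2_to_so2(t2, calib).y == pytest.approx(0.5, abs=1e-12)

    def test_monotonicity(self, calib):
        t2s = [so2_to_t2(y, calib) for y in np.linspace(0, 1, 101)]
        assert np.all(np.diff(t2s) > 0)
        ys = [t2_to_so2(t2, calib).y for t2 in t2s]
        assert np.all(np.diff(ys) > 0)

    def test_t2_above_plateau_beyond_tolerance_rejected(self, calib):
        with pytest.raises(ValidationError):
            t2_to_so2(calib.t2_plateau_ms * 1.2, calib)

    def test_slight_overshoot_clamped_with_flag(self, calib):
        t2 = so2_to_t2(1.0, calib) + 0.005
        meas = t2_to_so2(t2, calib)
        assert meas.y == 1.0 and meas.clamped

    def test_k_zero_unidentifiable(self):
        calib = CalibrationModel(k_rate=0.0)
        assert t2_to_so2(calib.t2_plateau_ms, calib).y == 1.0
        with pytest.raises(ValidationError):
            t2_to_so2(calib.t2_plateau_ms / 2.0, calib)

    def test_out_of_range_saturation_rejected(self, calib):
        with pytest.raises(ValidationError):
            so2_to_t2(1.5, calib)


class TestEndToEnd:
    def test_noiseless_phantom_chain_recovers_t2_exactly(self, calib):
        y_true = 0.585
        t2_true = so2_to_t2(y_true, calib)
        spec = T2PhantomSpec(t2_ms=t2_true, s0=200.0, noise_sd=0.0)
        series = make_t2_phantom(spec)
        lumen = disk_mask(series.images.shape[1:], spec.vessel_radius_px)
        roi = erode_to_central_fraction(lumen, 0.6)
        fit = fit_t2(mean_roi_signal(series, roi), series.prep_times_ms)
        assert fit.t2_ms == pytest.approx(t2_true, rel=1e-9)
        assert t2_to_so2(fit.t2_ms, calib).y == pytest.approx(y_true, abs=1e-9)
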