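"""OEF/CBF quantification: T2 fitting, calibration, Fick, flow integration."""

import numpy as np
import pytest

from hemopattern.mri import (
    CalibrationRangeError,
    FitError,
    TrustSeries,
    VelocityScene,
    calibration_for_hct,
    compute_cbf,
    compute_oef,
    fit_blood_t2,
    hct_default,
    integrate_flow,
    t2_to_yv,
    yv_to_t2,
)

ETES = (0.44, 40.0, 80.0, 160.0)


def _series(t2, s0=1000.0, etes=ETES):
    return TrustSeries(etes=etes, signals=tuple(s0 * np.exp(-np.asarray(etes) / t2)))


class TestBloodT2Fit:
    def test_exact_recovery_from_noiseless_decay(self):
        fit = fit_blood_t2(_series(80.0))
        assert fit.t2 == pytest.approx(80.0, abs=1e-6)
        assert fit.s0 == pytest.approx(1000.0, rel=1e-8)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_constant_series_is_non_decaying_error(self):
        with pytest.raises(FitError, match="does not decay"):
            fit_blood_t2(TrustSeries(etes=ETES, signals=(500.0,) * 4))

    def test_increasing_series_rejected(self):
        with pytest.raises(FitError):
            fit_blood_t2(TrustSeries(etes=ETES, signals=(100.0, 200.0, 400.0, 800.0)))

    def test_nonpositive_signal_uses_fallback_start(self):
        sig = list(1000.0 * np.exp(-np.asarray(ETES) / 60.0))
        sig[-1] = -1.0  # noise pushed the last point below zero
        fit = fit_blood_t2(TrustSeries(etes=ETES, signals=tuple(sig)))
        assert fit.used_fallback
        assert 0 < fit.t2 < 200

    def test_series_validation(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            TrustSeries(etes=(40.0, 40.0, 80.0), signals=(1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="at least 3"):
            TrustSeries(etes=(0.44, 40.0), signals=(1.0, 0.5))

    def test_unbiased_at_one_percent_noise(self, rng):
        """|bias| < 2 SE over seeded replicates at 1% amplitude noise."""
        truth = 65.0
        est = []
        for _ in range(400):
            noisy = 1000.0 * np.exp(-np.asarray(ETES) / truth)
            noisy = noisy + rng.normal(0, 10.0, 4)
            est.append(fit_blood_t2(TrustSeries(etes=ETES, signals=tuple(noisy))).t2)
        bias = np.mean(est) - truth
        se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(bias) < max(2 * se, 0.2)


class TestCalibration:
    @pytest.mark.parametrize("hct", [0.40, 0.42])
    def test_inverse_consistency(self, hct):
        model = calibration_for_hct(hct)
        for y in np.linspace(*model.valid_y_range, 57):
            assert t2_to_yv(yv_to_t2(y, model), model) == pytest.approx(y, abs=1e-9)

    def test_monotone_t2_in_saturation(self):
        model = calibration_for_hct(0.42)
        ys = np.linspace(*model.valid_y_range, 101)
        t2s = [model.yv_to_t2(y) for y in ys]
        assert np.all(np.diff(t2s) > 0)
        # equivalently Yv increases with T2
        assert model.t2_to_yv(t2s[60]) > model.t2_to_yv(t2s[40])

    def test_against_dense_grid_oracle(self):
        """Quadratic-root inversion agrees with brute-force grid search."""
        model = calibration_for_hct(0.42)
        ys = np.linspace(*model.valid_y_range, 1_000_001)
        a, b, c = model.coeffs
        u = 1.0 - ys
        t2s = 1000.0 / (a + b * u + c * u * u)
        for target in (45.0, 70.0, 110.0, 150.0):
            y_grid = ys[np.argmin(np.abs(t2s - target))]
            assert model.t2_to_yv(target) == pytest.approx(y_grid, abs=1e-4)

    def test_out_of_range_t2_names_admissible_interval(self):
        model = calibration_for_hct(0.42)
        with pytest.raises(CalibrationRangeError, match="admissible T2 interval"):
            model.t2_to_yv(1000.0)

    def test_oef_invariant_to_amplitude_rescaling(self):
        """S0 cancels: scaling the TRUST series leaves T2, hence OEF, unchanged."""
        model = calibration_for_hct(0.40)
        t2a = fit_blood_t2(_series(72.0, s0=1000.0)).t2
        t2b = fit_blood_t2(_series(72.0, s0=7321.5)).t2
        oef_a = compute_oef(98.0, model.t2_to_yv(t2a) * 100)
        oef_b = compute_oef(98.0, model.t2_to_yv(t2b) * 100)
        assert oef_a == pytest.approx(oef_b, abs=1e-9)


class TestOef:
    def test_no_extraction(self):
        assert compute_oef(98.0, 98.0) == 0.0

    def test_half_extraction(self):
        assert compute_oef(98.0, 49.0) == pytest.approx(50.0)

    def test_cohort_mean_inversion(self):
        # Yv implied by the cohort-mean OEF of 39.7% at Ya = 98%
        yv = 98.0 * (1 - 0.397)
        assert yv == pytest.approx(59.094)
        assert compute_oef(98.0, yv) == pytest.approx(39.7)

    def test_supply_exceeding_arterial_rejected(self):
        with pytest.raises(ValueError, match="exceeds Ya"):
            compute_oef(98.0, 99.0)

    @pytest.mark.parametrize("sex,hct", [("male", 0.42), ("female", 0.40),
                                         ("M", 0.42), ("f", 0.40)])
    def test_hct_defaults(self, sex, hct):
        assert hct_default(sex) == hct

    def test_unknown_sex_code(self):
        with pytest.raises(ValueError, match="unrecognized"):
            hct_default("x")


def _uniform_scene(value=10.0, shape=(4, 4), pixel_area=0.25, mask=None):
    vmap = np.full(shape, value)
    if mask is None:
        mask = np.zeros(shape, dtype=bool)
        mask[:2, :2] = True  # 4 pixels -> 1 cm^2 at 0.25 cm^2/px
    return VelocityScene(velocity_map=vmap, roi_masks={"roi": mask},
                         pixel_area=pixel_area)


class TestFlowIntegration:
    def test_unit_conversion(self):
        # 10 cm/s over 1 cm^2 -> 10 cm^3/s -> 600 ml/min
        assert integrate_flow(_uniform_scene(), "roi") == pytest.approx(600.0)

    def test_zero_velocity(self):
        assert integrate_flow(_uniform_scene(0.0), "roi") == 0.0

    def test_matches_brute_force_pixel_sum(self, rng):
        vmap = rng.uniform(-5, 15, (16, 16))
        mask = rng.random((16, 16)) < 0.3
        mask[0, 0] = True
        scene = VelocityScene(velocity_map=vmap, roi_masks={"roi": mask},
                              pixel_area=0.04)
        expected = 0.0
        for i in range(16):
            for j in range(16):
                if mask[i, j]:
                    expected += vmap[i, j] * 0.04 * 60.0
        assert integrate_flow(scene, "roi") == pytest.approx(expected, abs=1e-9)

    def test_additive_over_disjoint_rois_and_linear(self, rng):
        vmap = rng.uniform(-5, 15, (8, 8))
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[:4] = True
        b[4:] = True
        scene = VelocityScene(
            velocity_map=vmap,
            roi_masks={"a": a, "b": b, "both": a | b}, pixel_area=0.1,
        )
        fa = integrate_flow(scene, "a")
        fb = integrate_flow(scene, "b")
        assert fa + fb == pytest.approx(integrate_flow(scene, "both"), abs=1e-9)
        doubled = VelocityScene(velocity_map=2 * vmap,
                                roi_masks={"a": a}, pixel_area=0.1)
        assert integrate_flow(doubled, "a") == pytest.approx(2 * fa, abs=1e-9)

    def test_background_offset_subtracted(self):
        scene = _uniform_scene(10.0)
        background = ~scene.roi_masks["roi"]
        # whole map sits at +10 cm/s, so after offset removal flow is zero
        assert integrate_flow(scene, "roi", background_mask=background) == pytest.approx(0.0)

    def test_empty_and_unknown_roi(self):
        scene = _uniform_scene()
        with pytest.raises(ValueError, match="unknown ROI"):
            integrate_flow(scene, "nope")
        empty = VelocityScene(velocity_map=np.zeros((4, 4)),
                              roi_masks={"roi": np.zeros((4, 4), bool)},
                              pixel_area=0.25)
        with pytest.raises(ValueError, match="empty"):
            integrate_flow(empty, "roi")


class TestCbf:
    def test_arithmetic_with_density(self):
        res = compute_cbf({"a": 400.0, "b": 300.0}, brain_volume=1200.0)
        assert res.total_flow == 700.0
        assert res.cbf == pytest.approx(700.0 / (1200.0 * 1.06) * 100.0)
        assert res.cbf == pytest.approx(55.031, abs=1e-3)

    def test_zero_flow(self):
        assert compute_cbf([0.0, 0.0], 1200.0).cbf == 0.0

    def test_linear_in_flow(self):
        one = compute_cbf([200.0, 300.0], 1100.0).cbf
        two = compute_cbf([400.0, 600.0], 1100.0).cbf
        assert two == pytest.approx(2 * one)

    def test_negative_total_flow_warns_but_returns(self):
        with pytest.warns(UserWarning, match="negative"):
            res = compute_cbf([-500.0, 100.0], 1200.0)
        assert res.warning is not None
        assert res.cbf < 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_cbf([100.0], 0.0)
        with pytest.raises(ValueError):
            compute_cbf([], 1200.0)
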