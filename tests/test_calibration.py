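import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glusense.calibration import (
    HillCalibrator,
    delta_r_max,
    estimate_lod,
    fit_dose_response,
    hill_ratio,
    invert_dose_response,
    invert_ratio,
    make_fit,
    method_agreement,
    normalize_to_control,
    predict_ratio,
    quantify_samples,
    reference_correct,
)

CONC_GRID = np.array([0, 1, 2, 5, 10, 20, 50, 100, 200, 500, 1000, 2000.0])


@pytest.fixture
def glusor_fit(glusor_truth):
    return make_fit(**glusor_truth)


class TestHillAlgebra:
    def test_zero_concentration_gives_rmin_exactly(self, glusor_fit):
        assert predict_ratio(glusor_fit, 0.0) == glusor_fit.Rmin

    @pytest.mark.parametrize("p", [0.5, 1.0, 2.0, 3.7])
    def test_half_response_at_kd_for_any_hill_slope(self, p):
        fit = make_fit(1.0, 7.46, 60.68, p)
        mid = predict_ratio(fit, 60.68)
        assert abs(mid - (1.0 + 7.46) / 2.0) < 1e-12

    def test_ten_kd_hand_evaluation(self, glusor_fit):
        # R(10 Kd) = Rmax - (Rmax - Rmin)/11 for p = 1
        expected = 7.46 - (7.46 - 1.0) / 11.0
        assert abs(predict_ratio(glusor_fit, 10 * 60.68) - expected) < 1e-12

    def test_invert_is_exact_inverse_over_log_grid(self, glusor_fit):
        c = np.logspace(-2, 4, 50)
        back = invert_ratio(glusor_fit, predict_ratio(glusor_fit, c))
        np.testing.assert_allclose(back, c, rtol=1e-9)

    @given(
        rmin=st.floats(0.2, 3.0),
        span=st.floats(0.5, 10.0),
        kd=st.floats(0.5, 5000.0),
        p=st.floats(0.4, 3.5),
        factor=st.floats(0.02, 50.0),
    )
    def test_roundtrip_property(self, rmin, span, kd, p, factor):
        # conc expressed relative to Kd: far outside [Kd/50, 50 Kd] the
        # ratio saturates to Rmin/Rmax and cancellation dominates any inverse
        fit = make_fit(rmin, rmin + span, kd, p)
        conc = kd * factor
        r = predict_ratio(fit, conc)
        assert abs(invert_ratio(fit, r) - conc) <= 1e-6 * conc


class TestDeltaRmax:
    @pytest.mark.parametrize(
        "rmin,rmax,expected", [(1.0, 7.46, 6.46), (2.0, 2.0, 0.0), (2.0, 5.0, 1.5)]
    )
    def test_values(self, rmin, rmax, expected):
        fit = make_fit(rmin, max(rmax, rmin + 1e-12) if rmax == rmin else rmax, 10.0)
        fit.Rmax = rmax
        assert abs(delta_r_max(fit) - expected) < 1e-12

    def test_nonpositive_rmin_rejected(self, glusor_fit):
        glusor_fit.Rmin = 0.0
        with pytest.raises(ValueError):
            delta_r_max(glusor_fit)


class TestFitDoseResponse:
    def test_noiseless_recovery_to_machine_precision(self, glusor_truth):
        ratio = hill_ratio(CONC_GRID, **glusor_truth)
        fit = fit_dose_response(CONC_GRID, ratio)
        assert abs(fit.Kd_uM - 60.68) / 60.68 < 1e-6
        assert abs(fit.Rmin - 1.0) < 1e-6
        assert abs(fit.Rmax - 7.46) < 1e-6
        assert abs(fit.hill_p - 1.0) < 1e-6
        assert abs(fit.delta_Rmax - 6.46) < 1e-5

    def test_flat_data_flagged_degenerate(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_dose_response(CONC_GRID, np.full_like(CONC_GRID, 2.0))
        assert abs(fit.Rmax - fit.Rmin) < 1e-3
        assert abs(fit.delta_Rmax) < 1e-3
        assert "non_monotone_data" in fit.flags or "flat_curve" in fit.flags

    def test_point_order_invariance(self, glusor_truth):
        rng = np.random.default_rng(0)
        ratio = hill_ratio(CONC_GRID, **glusor_truth) * (
            1 + rng.normal(0, 0.02, CONC_GRID.size)
        )
        fit1 = fit_dose_response(CONC_GRID, ratio)
        perm = rng.permutation(CONC_GRID.size)
        fit2 = fit_dose_response(CONC_GRID[perm], ratio[perm])
        assert abs(fit1.Kd_uM - fit2.Kd_uM) < 1e-6 * fit1.Kd_uM
        assert abs(fit1.hill_p - fit2.hill_p) < 1e-6

    def test_global_ratio_rescaling_leaves_kd_and_p(self, glusor_truth):
        ratio = hill_ratio(CONC_GRID, **glusor_truth)
        fit1 = fit_dose_response(CONC_GRID, ratio)
        fit2 = fit_dose_response(CONC_GRID, 3.5 * ratio)
        assert abs(fit1.Kd_uM - fit2.Kd_uM) < 1e-6 * fit1.Kd_uM
        assert abs(fit1.hill_p - fit2.hill_p) < 1e-5
        assert abs(fit2.Rmax / fit2.Rmin - fit1.Rmax / fit1.Rmin) < 1e-6

    def test_normalization_to_initial_ratio_preserves_kd(self, glusor_truth):
        # dividing all ratios by the blank ratio rescales Rmin/Rmax only
        ratio = hill_ratio(CONC_GRID, **glusor_truth)
        fit = fit_dose_response(CONC_GRID, ratio / ratio[0])
        assert abs(fit.Kd_uM - 60.68) / 60.68 < 1e-6

    def test_requires_five_concentrations_with_zero(self):
        with pytest.raises(ValueError):
            fit_dose_response([1, 2, 3, 4.0], [1, 2, 3, 4.0])

    def test_fixed_hill_slope(self, glusor_truth):
        ratio = hill_ratio(CONC_GRID, **glusor_truth)
        fit = fit_dose_response(CONC_GRID, ratio, fix_hill_slope=1.0)
        assert fit.hill_p == 1.0
        assert np.all(fit.covariance[3] == 0)


class TestInversionCensoring:
    def test_midpoint_maps_to_kd(self, glusor_fit):
        est = invert_dose_response(glusor_fit, (1.0 + 7.46) / 2)
        assert est.censoring == "quantified"
        assert abs(est.conc_uM - 60.68) < 1e-9

    def test_above_range_censored_without_exception(self, glusor_fit):
        est = invert_dose_response(glusor_fit, 7.46 + 0.1)
        assert est.censoring == "above_range"

    def test_below_range_censored(self, glusor_fit):
        est = invert_dose_response(glusor_fit, 0.5)
        assert est.censoring == "below_range"
        assert est.conc_uM == 0.0


class TestLod:
    def test_noiseless_blanks_give_zero(self, glusor_fit):
        assert estimate_lod(glusor_fit, [1.0, 1.0, 1.0]) == 0.0

    def test_monotone_in_blank_sd(self, glusor_fit):
        base = np.array([-1.0, 0.0, 1.0, 0.5, -0.5])
        lods = [
            estimate_lod(glusor_fit, 1.0 + s * base) for s in (0.005, 0.01, 0.02)
        ]
        assert lods[0] < lods[1] < lods[2]

    def test_decreasing_in_dynamic_range(self):
        blanks = 1.0 + 0.01 * np.array([-1.0, 0.0, 1.0])
        small = estimate_lod(make_fit(1.0, 2.0, 60.68), blanks)
        large = estimate_lod(make_fit(1.0, 7.46, 60.68), blanks)
        assert large < small

    def test_saturated_blank_flagged_undefined(self, glusor_fit):
        with pytest.warns(UserWarning, match="LOD undefined"):
            lod = estimate_lod(glusor_fit, [7.0, 7.4, 6.5])
        assert np.isnan(lod)

    def test_requires_three_blanks(self, glusor_fit):
        with pytest.raises(ValueError):
            estimate_lod(glusor_fit, [1.0, 1.0])


class TestCorrectionsAndNormalization:
    def test_unit_reference(self):
        assert reference_correct(2.0, 1.0) == 2.0

    def test_shared_ph_factor_cancels(self):
        for g in (0.7, 1.0, 1.3):
            assert abs(reference_correct(2.0 * g, 1.0 * g) - 2.0) < 1e-12

    def test_simulated_ph_series_flattens(self, scenario):
        from glusense.io import read_plate_measurements
        from glusense.simulate import gen_ph_series

        df, truth = gen_ph_series(scenario)
        ms = read_plate_measurements(df)
        by_ph: dict[str, dict[str, list]] = {}
        for m in ms:
            slot = by_ph.setdefault(m.condition, {"sensor": [], "reference": []})
            slot["sensor" if m.well_id.startswith("S") else "reference"].append(
                m.ratio_R
            )
        raw = np.array([np.mean(v["sensor"]) for v in by_ph.values()])
        corrected = np.array(
            [
                np.mean(v["sensor"]) / np.mean(v["reference"])
                for v in by_ph.values()
            ]
        )
        # uncorrected varies strongly with pH; corrected is flat within noise
        assert raw.std() / raw.mean() > 0.05
        assert corrected.std() / corrected.mean() < 0.02

    def test_normalize_to_control(self):
        np.testing.assert_allclose(normalize_to_control([2.0, 2.0], [2.0, 2.0]), 1.0)
        np.testing.assert_allclose(
            normalize_to_control([4.0, 6.0], [2.0, 3.0]), [1.6, 2.4]
        )
        with pytest.raises(ValueError):
            normalize_to_control([1.0], [])

    def test_corrected_then_normalized_matches_hand_computation(self):
        # 6-well toy table: 3 control wells, 3 treatment wells, shared reference
        sensor = np.array([2.0, 2.2, 1.8, 4.0, 4.4, 3.6])
        reference = np.array([1.0, 1.1, 0.9, 1.0, 1.1, 0.9])
        corrected = reference_correct(sensor, reference)
        out = normalize_to_control(corrected[3:], corrected[:3])
        np.testing.assert_allclose(out, [2.0, 2.0, 2.0])


class TestQuantifySamples:
    def test_mixing_dilution_recovers_sample_concentration(self, glusor_fit):
        # sample at 100 uM diluted 3:1 reads as 75 uM in the well
        r = predict_ratio(glusor_fit, 75.0)
        (est,) = quantify_samples(glusor_fit, {"s": [r]}, dilution_factor=4 / 3)
        assert abs(est.conc_uM - 100.0) < 1e-9

    def test_identical_replicates_ci_from_fit_covariance_only(self, glusor_truth):
        rng = np.random.default_rng(1)
        ratio = hill_ratio(CONC_GRID, **glusor_truth) * (
            1 + rng.normal(0, 0.02, CONC_GRID.size)
        )
        fit = fit_dose_response(CONC_GRID, ratio)
        r = predict_ratio(fit, 50.0)
        (a,) = quantify_samples(fit, {"s": [r, r, r]}, dilution_factor=1.0)
        zero_cov = make_fit(fit.Rmin, fit.Rmax, fit.Kd_uM, fit.hill_p)
        (b,) = quantify_samples(zero_cov, {"s": [r, r, r]}, dilution_factor=1.0)
        assert a.ci_high_uM - a.ci_low_uM > 0
        assert b.ci_high_uM - b.ci_low_uM == 0  # no replicate scatter, no fit cov

    def test_below_lod_censoring(self, glusor_fit):
        r = predict_ratio(glusor_fit, 0.05)
        (est,) = quantify_samples(
            glusor_fit, {"s": [r]}, dilution_factor=1.0, lod_uM=0.2
        )
        assert est.censoring == "below_LOD"


class TestMethodAgreement:
    def test_identity(self):
        ref = np.array([10.0, 50.0, 200.0, 500.0])
        ag = method_agreement(ref, ref)
        assert ag.slope == pytest.approx(1.0)
        assert ag.intercept_uM == pytest.approx(0.0)
        assert ag.r_squared == pytest.approx(1.0)
        assert ag.mean_relative_error_pct == pytest.approx(0.0)

    def test_doubled_estimates_slope_two(self):
        ref = np.array([10.0, 50.0, 200.0, 500.0])
        assert method_agreement(2 * ref, ref).slope == pytest.approx(2.0)

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(ValueError):
            method_agreement([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_weighted_matches_ols_under_equal_weights(self):
        rng = np.random.default_rng(2)
        ref = np.linspace(10, 500, 12)
        est = ref * (1 + rng.normal(0, 0.05, 12))
        a = method_agreement(est, ref)
        b = method_agreement(est, ref, estimate_sds_uM=np.full(12, 3.0))
        assert a.slope == pytest.approx(b.slope, rel=1e-9)


class TestSklearnSurface:
    def test_get_set_params_and_predict(self, glusor_truth):
        cal = HillCalibrator(fix_hill_slope=1.0)
        assert cal.get_params()["fix_hill_slope"] == 1.0
        cal.set_params(fix_hill_slope=None)
        ratio = hill_ratio(CONC_GRID, **glusor_truth)
        cal.fit(CONC_GRID, ratio)
        np.testing.assert_allclose(cal.predict([0.0]), [1.0], atol=1e-6)
        np.testing.assert_allclose(cal.inverse(cal.predict([50.0])), [50.0], rtol=1e-6)

    def test_off_direction_sensor(self):
        fit_params = dict(Rmin=5.0, Rmax=1.0, Kd_uM=30.0, hill_p=1.0)
        ratio = hill_ratio(CONC_GRID, **fit_params)
        cal = HillCalibrator(direction="off").fit(CONC_GRID, ratio)
        assert cal.Rmin_ > cal.Rmax_
        assert abs(cal.Kd_uM_ - 30.0) / 30.0 < 1e-6
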