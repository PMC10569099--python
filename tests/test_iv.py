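"""Rectification, response, calibration and trace normalization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aptapore.errors import (PreconditionError, RangeError,
                             UndefinedRatioError)
from aptapore.iv import (NOT_DETECTED, CalibrationSeries, IVCurve, TimeTrace,
                         build_calibration, detection_threshold,
                         limit_of_detection, normalize_trace,
                         rectification_coefficient, sensor_response)


def ohmic_curve(R=1e8, v=0.6, n=13):
    volts = np.linspace(-v, v, n)
    return IVCurve(volts, volts / R)


def curve_with(i_pos, i_neg, v_eval=0.5):
    """Piecewise-linear curve hitting the given currents at +-v_eval."""
    v = np.array([-v_eval, 0.0, v_eval])
    return IVCurve(v, np.array([i_neg, 0.0, i_pos]))


class TestRectificationCoefficient:
    def test_symmetric_ohmic_curve_is_unrectified(self):
        assert rectification_coefficient(ohmic_curve()) == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("i_pos,i_neg,expected", [
        (2e-9, -1e-9, math.log10(2)),        # 2:1 current ratio
        (10 ** -0.2 * 1e-9, -1e-9, -0.2),    # the bare-quartz magnitude
        (1e-9, -10 ** 0.5 * 1e-9, -0.5),     # the aptamer-sensor magnitude
    ])
    def test_log_ratio_of_interpolated_currents(self, i_pos, i_neg, expected):
        r = rectification_coefficient(curve_with(i_pos, i_neg))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_antisymmetric_under_curve_reflection(self):
        rng = np.random.default_rng(7)
        v = np.linspace(-0.6, 0.6, 25)
        i = v / 1e8 * np.exp(1.7 * v) * (1 + 0.05 * rng.standard_normal(v.size))
        fwd = IVCurve(v, i)
        refl = IVCurve(-v[::-1], -i[::-1])
        assert rectification_coefficient(refl) == pytest.approx(
            -rectification_coefficient(fwd), abs=1e-12)

    @given(k=st.floats(1e-6, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_current_scaling(self, k):
        base = curve_with(2.3e-9, -0.9e-9)
        scaled = IVCurve(base.voltage, k * base.current)
        assert rectification_coefficient(scaled) == pytest.approx(
            rectification_coefficient(base), abs=1e-9)

    def test_cv_cycle_branches_are_averaged(self):
        v_f = np.linspace(-0.6, 0.6, 25)
        v_b = v_f[::-1]
        i_f, i_b = v_f / 1e8 * 1.1, v_b / 1e8 * 0.9  # hysteresis
        cycle = IVCurve(np.concatenate([v_f, v_b[1:]]),
                        np.concatenate([i_f, i_b[1:]]))
        assert rectification_coefficient(cycle) == pytest.approx(0.0, abs=1e-12)

    def test_bias_outside_sweep_raises(self):
        with pytest.raises(RangeError):
            rectification_coefficient(ohmic_curve(v=0.3), v_eval=0.5)

    def test_zero_current_raises(self):
        flat = IVCurve(np.linspace(-0.6, 0.6, 5), np.zeros(5))
        with pytest.raises(UndefinedRatioError):
            rectification_coefficient(flat)


class TestSensorResponse:
    def test_identical_curves_give_zero(self):
        c = ohmic_curve()
        assert sensor_response(c, c) == 0.0

    @pytest.mark.parametrize("i_base,i_tgt,expected", [
        (1.00e-9, 0.89e-9, -11.0),   # dopamine direction: current decrease
        (1.00e-9, 1.133e-9, +13.3),  # serotonin direction: current increase
    ])
    def test_percent_change_at_positive_bias(self, i_base, i_tgt, expected):
        base = curve_with(i_base, -i_base)
        tgt = curve_with(i_tgt, -i_tgt)
        assert sensor_response(base, tgt) == pytest.approx(expected, abs=1e-9)
        assert sensor_response(base, tgt, magnitude=True) == pytest.approx(
            abs(expected), abs=1e-9)

    def test_zero_baseline_raises(self):
        base = IVCurve(np.linspace(-0.6, 0.6, 5), np.zeros(5))
        with pytest.raises(UndefinedRatioError):
            sensor_response(base, ohmic_curve())


class TestCalibration:
    def test_two_point_statistics(self):
        cal = build_calibration({0.0: [0, 0], 1e-12: [1.0, 3.0]})
        assert cal.mean_response[1] == pytest.approx(2.0)
        assert cal.sd_response[1] == pytest.approx(math.sqrt(2.0))
        assert cal.sem_response[1] == pytest.approx(1.0)

    def test_blank_of_zeros(self):
        cal = build_calibration({0.0: [0.0, 0.0, 0.0]})
        assert cal.mean_response[0] == 0.0 and cal.sd_response[0] == 0.0

    def test_concentrations_sorted(self):
        cal = build_calibration({1e-9: [5.0], 0.0: [0.0], 1e-12: [2.0]})
        assert list(cal.concentration) == [0.0, 1e-12, 1e-9]

    def test_empty_input_raises(self):
        with pytest.raises(PreconditionError):
            build_calibration({})

    def test_threshold_is_blank_mean_plus_three_sd(self):
        cal = CalibrationSeries(np.array([0.0, 1e-12]), np.array([0.0, 5.0]),
                                np.array([0.5, 0.1]), np.array([5, 5]))
        assert detection_threshold(cal) == pytest.approx(1.5)

    def test_lod_crossing_interpolated_at_the_floor(self):
        # responses cross the 3-sigma threshold exactly at 1 fM
        conc = np.array([0.0, 1e-16, 1e-15, 1e-14, 1e-12])
        mean = np.array([0.0, 0.0, 1.5, 4.0, 9.0])
        cal = CalibrationSeries(conc, mean, np.array([0.5, 0.4, 0.4, 0.4, 0.4]),
                                np.full(5, 5))
        assert limit_of_detection(cal) == pytest.approx(1e-15, rel=1e-9)

    def test_lod_log_interpolation_between_brackets(self):
        conc = np.array([0.0, 1e-15, 1e-13])
        mean = np.array([0.0, 1.0, 3.0])
        cal = CalibrationSeries(conc, mean, np.array([0.5, 0.1, 0.1]),
                                np.full(3, 5))
        # threshold 1.5 is halfway between 1 and 3 -> log-midpoint 1e-14
        assert limit_of_detection(cal) == pytest.approx(1e-14, rel=1e-9)

    def test_flat_control_series_is_not_detected(self):
        conc = np.array([0.0, 1e-12, 1e-9, 1e-6])
        cal = CalibrationSeries(conc, np.array([0.0, 0.1, -0.2, 0.1]),
                                np.full(4, 0.3), np.full(4, 5))
        assert limit_of_detection(cal) is NOT_DETECTED

    def test_lod_monotone_under_response_inflation(self):
        conc = np.array([0.0, 1e-15, 1e-13, 1e-11])
        mean = np.array([0.0, 1.0, 3.0, 8.0])
        sd = np.array([0.4, 0.2, 0.2, 0.2])
        base = limit_of_detection(
            CalibrationSeries(conc, mean, sd, np.full(4, 5)))
        inflated = limit_of_detection(
            CalibrationSeries(conc, mean * np.array([1, 2, 2, 2]), sd,
                              np.full(4, 5)))
        assert inflated <= base

    def test_missing_blank_raises(self):
        cal = CalibrationSeries(np.array([1e-12]), np.array([5.0]),
                                np.array([0.1]), np.array([5]))
        with pytest.raises(PreconditionError):
            limit_of_detection(cal)


class TestNormalizeTrace:
    def test_constant_trace_normalizes_to_one(self):
        tr = TimeTrace(np.arange(10.0), np.full(10, 5e-9))
        out = normalize_trace(tr, (0.0, 9.0))
        assert np.allclose(out.current, 1.0)

    def test_step_preserved_as_fraction(self):
        t = np.arange(0.0, 20.0)
        i = np.where(t < 10, 1e-9, 0.9e-9)
        tr = TimeTrace(t, i, events=(10.0,))
        out = normalize_trace(tr)  # default window: before first event
        assert np.allclose(out.current[t < 10], 1.0)
        assert np.allclose(out.current[t >= 10], 0.9)

    def test_window_needs_two_samples(self):
        tr = TimeTrace(np.arange(5.0), np.ones(5))
        with pytest.raises(PreconditionError):
            normalize_trace(tr, (0.0, 0.5))


class TestValidation:
    def test_mismatched_lengths_rejected(self):
        with pytest.raises(PreconditionError):
            IVCurve(np.arange(4.0), np.arange(5.0))

    def test_non_monotone_branch_rejected(self):
        with pytest.raises(PreconditionError):
            IVCurve(np.array([0.0, 1.0, 1.0, 2.0]), np.zeros(4))

    def test_event_outside_range_rejected(self):
        with pytest.raises(PreconditionError):
            TimeTrace(np.arange(5.0), np.ones(5), events=(99.0,))
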