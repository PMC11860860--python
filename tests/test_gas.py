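"""Gas-pressure processing and Gompertz gas-production kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rumentox import (
    GasCurve,
    GompertzGasModel,
    GompertzParams,
    abc_to_shape,
    blank_correct,
    downsample,
    fit_gompertz,
    gompertz_value,
    pressure_to_volume,
)
from rumentox.gas import time_to_fraction, volume_to_pressure

TABLE_TRUTHS = {
    "CSM": GompertzParams(200.0, 18.6, 8.5),
    "PCM": GompertzParams(272.0, 17.5, 10.7),
    "SMS": GompertzParams(453.0, 43.5, 32.1),
}


def make_curve(times, values, **kwargs):
    defaults = dict(run="R1", fermenter="F1", variant="CSM")
    defaults.update(kwargs)
    return GasCurve(times=np.asarray(times, float), values=np.asarray(values, float), **defaults)


class TestPressureToVolume:
    def test_zero_pressure_zero_volume(self):
        assert pressure_to_volume(0.0) == 0.0

    def test_hand_calculation_at_stp(self):
        # n = (1 psi -> Pa) * 106 mL / (R * 312.15 K); volume = n * 22414 mL/mol
        n = 6894.757293168 * 106e-6 / (8.314462618 * 312.15)
        assert pressure_to_volume(1.0, 106.0, 39.0, "STP") == pytest.approx(n * 22414.0, rel=1e-9)
        assert pressure_to_volume(1.0, 106.0, 39.0, "STP") == pytest.approx(6.3117, abs=5e-4)

    @given(p=st.floats(min_value=0, max_value=20), scale=st.floats(min_value=0.1, max_value=5))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_linear_and_homogeneous(self, p, scale):
        base = pressure_to_volume(p)
        assert pressure_to_volume(scale * p) == pytest.approx(scale * base, rel=1e-12, abs=1e-12)
        assert pressure_to_volume(p, headspace_ml=106.0 * scale) == pytest.approx(scale * base, rel=1e-12, abs=1e-12)

    def test_negative_pressure_rejected(self):
        with pytest.raises(ValueError):
            pressure_to_volume(-0.1)

    def test_incubation_reference_larger_than_stp(self):
        # same moles occupy more volume at 39 degC / 1 atm than at STP
        assert pressure_to_volume(1.0, reference="incubation") > pressure_to_volume(1.0)

    def test_volume_round_trip(self):
        assert volume_to_pressure(pressure_to_volume(2.7)) == pytest.approx(2.7, rel=1e-12)


class TestBlankCorrection:
    def test_two_blank_mean_is_subtracted(self):
        t = np.arange(0.0, 5.0)
        test = make_curve(t, np.full(5, 10.0))
        blanks = [make_curve(t, np.full(5, 2.0)), make_curve(t, np.full(5, 4.0))]
        (out,) = blank_correct([test], blanks)
        assert np.allclose(out.values, 7.0)

    def test_test_equal_to_mean_blank_gives_zero(self):
        t = np.arange(0.0, 5.0)
        test = make_curve(t, t * 0.3)
        (out,) = blank_correct([test], [make_curve(t, t * 0.3)])
        assert np.allclose(out.values, 0.0)

    def test_zero_blank_is_identity(self):
        t = np.arange(0.0, 5.0)
        test = make_curve(t, t**2)
        (out,) = blank_correct([test], [make_curve(t, np.zeros(5))])
        assert np.allclose(out.values, test.values)

    def test_negative_corrected_values_preserved(self):
        t = np.arange(0.0, 3.0)
        (out,) = blank_correct([make_curve(t, np.full(3, 1.0))], [make_curve(t, np.full(3, 2.0))])
        assert np.all(out.values == -1.0)

    def test_mismatched_grids_interpolated(self):
        test = make_curve([0.0, 1.0, 2.0], [10.0, 10.0, 10.0])
        blank = make_curve([0.0, 2.0], [0.0, 2.0])
        (out,) = blank_correct([test], [blank])
        assert np.allclose(out.values, [10.0, 9.0, 8.0])

    def test_no_overlap_raises(self):
        test = make_curve([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])
        blank = make_curve([5.0, 6.0], [0.0, 0.0])
        with pytest.raises(ValueError, match="cover"):
            blank_correct([test], [blank])


class TestDownsample:
    def test_five_minute_data_to_half_hour(self):
        t = np.arange(0, 577) / 12.0  # 5-min grid over 0-48 h
        curve = make_curve(t, np.arange(577, dtype=float))
        out = downsample(curve, 0.5)
        assert out.times.size == 97
        assert out.times[0] == 0.0

    def test_resolution_spanning_whole_curve(self):
        t = np.arange(0, 577) / 12.0
        out = downsample(make_curve(t, t), 48.0)
        assert out.times.size == 2

    def test_monotone_input_stays_monotone(self):
        t = np.arange(0, 577) / 12.0
        out = downsample(make_curve(t, np.cumsum(np.abs(np.sin(t)))), 0.5)
        assert np.all(np.diff(out.values) >= 0)

    def test_resolution_below_native_rejected(self):
        t = np.arange(0, 13) / 12.0
        with pytest.raises(ValueError):
            downsample(make_curve(t, t), 1.0 / 24.0)


class TestParameterization:
    def test_shape_mapping_example(self):
        m, s = abc_to_shape(18.6, 8.5)
        assert s == pytest.approx(7.556, abs=1e-3)
        assert m == pytest.approx(19.31, abs=1e-2)

    @given(
        a=st.floats(min_value=10, max_value=600),
        b=st.floats(min_value=1, max_value=60),
        c=st.floats(min_value=1, max_value=50),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_defining_constraints_hold(self, a, b, c):
        """G(b) = a/3 and G(b+c) = 0.70 a define the (b, c) pair."""
        p = GompertzParams(a, b, c)
        assert gompertz_value(p, b) == pytest.approx(a / 3.0, rel=1e-9)
        assert gompertz_value(p, b + c) == pytest.approx(0.70 * a, rel=1e-9)

    def test_inflection_at_a_over_e(self):
        p = GompertzParams(100.0, 20.0, 10.0)
        m, _ = abc_to_shape(p.b, p.c)
        assert gompertz_value(p, m) == pytest.approx(100.0 / np.e, rel=1e-9)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            abc_to_shape(0.0, 5.0)
        with pytest.raises(ValueError):
            GompertzParams(100.0, 10.0, -1.0)


class TestGompertzCurve:
    def test_table_row_reaches_seventy_percent_at_b_plus_c(self):
        p = TABLE_TRUTHS["CSM"]
        assert gompertz_value(p, 27.1) == pytest.approx(140.0, rel=1e-9)

    def test_asymptote(self):
        p = GompertzParams(250.0, 20.0, 10.0)
        assert gompertz_value(p, 1e5) == pytest.approx(250.0, rel=1e-9)

    def test_strictly_increasing(self):
        p = GompertzParams(250.0, 20.0, 10.0)
        vals = np.asarray(gompertz_value(p, np.linspace(0, 96, 200)))
        assert np.all(np.diff(vals) > 0)


class TestGompertzFit:
    @pytest.mark.parametrize("variant", ["CSM", "PCM", "SMS"])
    def test_noise_free_recovery(self, variant):
        truth = TABLE_TRUTHS[variant]
        span = 96.0 if variant == "SMS" else 48.0
        t = np.arange(0.0, span + 0.25, 0.5)
        y = np.asarray(gompertz_value(truth, t))
        est = GompertzGasModel()
        est.fit(t, y)
        assert est.a_ == pytest.approx(truth.a, rel=1e-4)
        assert est.b_ == pytest.approx(truth.b, rel=1e-4)
        assert est.c_ == pytest.approx(truth.c, rel=1e-4)
        assert est.fit_result_.r2 > 1 - 1e-8

    def test_flat_curve_flagged_degenerate(self):
        curve = make_curve(np.arange(0.0, 6.0), np.zeros(6))
        res = fit_gompertz(curve)
        assert not res.converged and "flat" in res.message

    def test_noisy_fit_keeps_high_r2(self):
        rng = np.random.default_rng(5)
        truth = TABLE_TRUTHS["PCM"]
        t = np.arange(0.0, 48.5, 0.5)
        y = np.asarray(gompertz_value(truth, t)) * rng.normal(1.0, 0.02, t.size)
        est = GompertzGasModel()
        est.fit(t, y)
        assert est.fit_result_.r2 > 0.99
        assert est.a_ == pytest.approx(truth.a, rel=0.05)

    def test_interval_coverage_with_two_percent_noise(self):
        """True (a, b, c) inside the Wald intervals in most noisy refits
        (40-repetition spot check of the 2% multiplicative noise contract)."""
        truth = TABLE_TRUTHS["CSM"]
        t = np.arange(0.0, 48.5, 0.5)
        clean = np.asarray(gompertz_value(truth, t))
        covered = 0
        n_reps = 40
        for rep in range(n_reps):
            rng = np.random.default_rng(1000 + rep)
            est = GompertzGasModel()
            est.fit(t, clean * rng.normal(1.0, 0.02, t.size))
            ok = all(
                est.fit_result_.ci95[name][0] <= val <= est.fit_result_.ci95[name][1]
                for name, val in zip(("a", "b", "c"), (truth.a, truth.b, truth.c))
            )
            covered += ok
        assert covered / n_reps >= 0.85


def test_time_to_fraction_is_consistent_with_parameterization():
    p = TABLE_TRUTHS["SMS"]
    assert time_to_fraction(p, 1.0 / 3.0) == pytest.approx(p.b, abs=1e-6)
    assert time_to_fraction(p, 0.70) == pytest.approx(p.b + p.c, abs=1e-6)
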