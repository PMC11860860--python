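"""Conversion-clearance kinetics: closed form, numeric oracle, fitting."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rumentox import (
    ConversionClearanceModel,
    ToxinKineticParams,
    fit_conversion_model,
    fit_exponential_decay,
    hga_at,
    hga_peak_time,
    hgb_at,
    simulate_numeric,
)
from rumentox.simulate import ExperimentConfig, generate_toxin_experiment

from conftest import make_concentration_frame

GRID_48 = np.arange(0.0, 48.5, 0.5)

rates = st.floats(min_value=0.01, max_value=1.0)
concs = st.floats(min_value=0.0, max_value=50.0)


class TestClosedForm:
    @pytest.mark.parametrize(
        "hgb0, k, t, expected",
        [
            (19.9, 0.3, 0.0, 19.9),                      # forced initial value
            (10.0, math.log(2), 1.0, 5.0),               # one half-life
            (10.0, 0.2, 5.0, 10.0 * math.exp(-1.0)),     # hand evaluation
        ],
    )
    def test_hgb_examples(self, hgb0, k, t, expected):
        p = ToxinKineticParams(hga0=0.0, hgb0=hgb0, k=k, l=0.0)
        assert hgb_at(p, t) == pytest.approx(expected, rel=1e-12)

    def test_hga_initial_value_is_forced(self):
        p = ToxinKineticParams(hga0=4.7, hgb0=19.9, k=0.37, l=0.21)
        assert hga_at(p, 0.0) == pytest.approx(4.7, rel=1e-12)

    def test_hga_without_clearance_absorbs_all_precursor(self):
        p = ToxinKineticParams(hga0=1.0, hgb0=10.0, k=0.2, l=0.0)
        assert hga_at(p, 1e6) == pytest.approx(11.0, rel=1e-9)

    def test_hga_matches_runge_kutta_oracle(self, demo_params):
        hga, _ = simulate_numeric(demo_params, [5.0], step=1e-3)
        assert hga_at(demo_params, 5.0) == pytest.approx(hga[0], rel=1e-6)

    def test_negative_time_rejected(self, demo_params):
        with pytest.raises(ValueError):
            hga_at(demo_params, -1.0)
        with pytest.raises(ValueError):
            hgb_at(demo_params, [-0.5, 1.0])

    @given(hga0=concs, hgb0=concs, k=rates)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_confluent_branch_is_continuous(self, hga0, hgb0, k):
        """hga_at just off the l == k boundary matches the limit formula."""
        t = np.linspace(0.0, 48.0, 25)
        at_limit = (hga0 + k * hgb0 * t) * np.exp(-k * t)
        for eps in (1e-9, -1e-9):
            p = ToxinKineticParams(hga0=hga0, hgb0=hgb0, k=k, l=k * (1 + eps))
            off = np.asarray(hga_at(p, t))
            scale = max(np.max(np.abs(at_limit)), 1e-12)
            assert np.max(np.abs(off - at_limit)) / scale < 1e-6

    @given(hgb0=st.floats(min_value=0.1, max_value=50.0), k=rates)
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_hgb_strictly_decreasing(self, hgb0, k):
        p = ToxinKineticParams(hga0=0.0, hgb0=hgb0, k=k, l=0.0)
        vals = np.asarray(hgb_at(p, np.linspace(0, 48, 50)))
        assert np.all(np.diff(vals) < 0)


class TestNumericOracle:
    def test_grid_of_zero_returns_initial_values(self, demo_params):
        hga, hgb = simulate_numeric(demo_params, [0.0])
        assert hga[0] == demo_params.hga0 and hgb[0] == demo_params.hgb0

    def test_empty_grid_rejected(self, demo_params):
        with pytest.raises(ValueError):
            simulate_numeric(demo_params, [])

    def test_mass_conservation_without_clearance(self):
        p = ToxinKineticParams(hga0=1.0, hgb0=10.0, k=0.3, l=0.0)
        hga, hgb = simulate_numeric(p, GRID_48, step=1e-2)
        total = hga + hgb
        assert np.max(np.abs(total - 11.0)) / 11.0 < 1e-8

    def test_closed_form_agrees_on_dense_grid(self, demo_params):
        hga, hgb = simulate_numeric(demo_params, GRID_48, step=1e-3)
        cf_a = np.asarray(hga_at(demo_params, GRID_48))
        cf_b = np.asarray(hgb_at(demo_params, GRID_48))
        assert np.max(np.abs(hga - cf_a)) / np.max(cf_a) < 1e-6
        assert np.max(np.abs(hgb - cf_b)) / np.max(cf_b) < 1e-6


class TestPeakTime:
    def test_matches_dense_grid_search(self, demo_params):
        t = np.arange(0.0, 48.0, 1e-4)
        grid_star = t[np.argmax(np.asarray(hga_at(demo_params, t)))]
        assert hga_peak_time(demo_params) == pytest.approx(grid_star, abs=1e-3)
        assert hga_peak_time(demo_params) == pytest.approx(6.4436, abs=1e-3)

    def test_pure_decay_has_no_interior_peak(self):
        p = ToxinKineticParams(hga0=5.0, hgb0=0.0, k=0.2, l=0.3)
        assert hga_peak_time(p) is None

    def test_no_clearance_has_no_interior_peak(self):
        p = ToxinKineticParams(hga0=1.0, hgb0=10.0, k=0.2, l=0.0)
        assert hga_peak_time(p) is None

    def test_zero_initial_product_peaks_at_positive_time(self):
        p = ToxinKineticParams(hga0=0.0, hgb0=10.0, k=0.4, l=0.2)
        t_star = hga_peak_time(p)
        assert t_star is not None and 0 < t_star < math.inf

    @given(hga0=concs, hgb0=st.floats(min_value=0.5, max_value=50), k=rates, l=rates)
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_closed_form_vs_grid_search(self, hga0, hgb0, k, l):
        p = ToxinKineticParams(hga0=hga0, hgb0=hgb0, k=k, l=l)
        t_star = hga_peak_time(p)
        t = np.arange(0.0, 100.0, 1e-3)
        vals = np.asarray(hga_at(p, t))
        grid_star = t[np.argmax(vals)]
        if t_star is None:
            assert grid_star < 2e-3 or l == 0
        elif t_star < 99.0:
            assert t_star == pytest.approx(grid_star, abs=2e-3)


class TestConversionFit:
    def _series_pair(self, params, grid=(0, 1, 2, 4, 8, 24, 48)):
        g = np.asarray(grid, dtype=float)
        hga = make_concentration_frame(g, hga_at(params, g), analyte="HGA", variant="SMS")
        hgb = make_concentration_frame(g, hgb_at(params, g), analyte="HGB", variant="SMS")
        return hga, hgb

    def test_noise_free_round_trip(self, demo_params):
        hga, hgb = self._series_pair(demo_params)
        res = fit_conversion_model(hga, hgb)
        assert res.converged
        for name, truth in zip(("hga0", "hgb0", "k", "l"), (1.0, 10.0, 0.2, 0.1)):
            assert res.estimates[name] == pytest.approx(truth, rel=1e-4)
        assert res.r2 > 1 - 1e-8

    def test_means_mode_averages_replicates(self, demo_params):
        g = np.asarray([0, 1, 2, 4, 8, 24, 48], dtype=float)
        frames_a, frames_b = [], []
        for i, shift in enumerate((0.9, 1.1)):
            a = make_concentration_frame(g, np.asarray(hga_at(demo_params, g)) * shift,
                                         analyte="HGA", fermenter=f"F{i}")
            b = make_concentration_frame(g, np.asarray(hgb_at(demo_params, g)) * shift,
                                         analyte="HGB", fermenter=f"F{i}")
            frames_a.append(a)
            frames_b.append(b)
        res = fit_conversion_model(pd.concat(frames_a), pd.concat(frames_b), mode="means")
        assert res.converged and res.mode == "means"
        # replicate means are exactly the noise-free curve, so recovery is exact
        assert res.estimates["k"] == pytest.approx(0.2, rel=1e-3)

    def test_zero_precursor_flags_nonidentifiable(self):
        g = np.asarray([0, 1, 2, 4, 8], dtype=float)
        hga = make_concentration_frame(g, 5 * np.exp(-0.3 * g), analyte="HGA")
        hgb = make_concentration_frame(g, np.zeros_like(g), analyte="HGB")
        res = fit_conversion_model(hga, hgb)
        assert not res.converged
        assert "identifiable" in res.message

    def test_too_few_time_points_rejected(self, demo_params):
        hga, hgb = self._series_pair(demo_params, grid=(0, 1, 2))
        with pytest.raises(ValueError, match="4 distinct"):
            fit_conversion_model(hga, hgb)

    def test_censored_points_are_dropped(self, demo_params):
        hga, hgb = self._series_pair(demo_params)
        hga.loc[hga.index[-1], ["value", "censored"]] = [0.5, True]
        res = fit_conversion_model(hga, hgb)
        assert res.converged
        assert res.n_obs == len(hga) + len(hgb) - 1

    def test_estimator_api(self, demo_params):
        from sklearn.base import clone

        est = ConversionClearanceModel(n_restarts=2, random_state=1)
        assert clone(est).get_params()["n_restarts"] == 2
        g = np.asarray([0, 1, 2, 4, 8, 24, 48], dtype=float)
        X = np.column_stack([np.r_[g, g], np.r_[np.zeros(7), np.ones(7)]])
        y = np.r_[np.asarray(hga_at(demo_params, g)), np.asarray(hgb_at(demo_params, g))]
        est.fit(X, y)
        assert est.k_ == pytest.approx(0.2, rel=1e-4)
        assert np.allclose(est.predict(X), y, atol=1e-6)
        assert est.peak_time() == pytest.approx(6.4436, abs=1e-3)


class TestDecayFit:
    def test_two_point_closed_form(self):
        # exact interpolation of the reported PCM endpoints: the fitted rate
        # equals the two-point log slope and the half-life follows as ln2/k
        df = make_concentration_frame([0.0, 8.0], [564.0, 25.3])
        decay = fit_exponential_decay(df)
        k_expected = math.log(564.0 / 25.3) / 8.0
        assert decay.k == pytest.approx(k_expected, rel=1e-8)
        assert decay.half_life == pytest.approx(math.log(2) / k_expected, rel=1e-8)
        assert decay.half_life == pytest.approx(1.79, abs=0.005)

    def test_noise_free_recovery(self):
        t = np.asarray([0, 1, 2, 4, 8, 24], dtype=float)
        df = make_concentration_frame(t, 500.0 * np.exp(-0.34 * t))
        decay = fit_exponential_decay(df)
        assert decay.c0 == pytest.approx(500.0, rel=1e-6)
        assert decay.k == pytest.approx(0.34, rel=1e-6)

    def test_constant_series_flagged_invalid(self):
        df = make_concentration_frame([0, 2, 4, 8], [7.0, 7.0, 7.0, 7.0])
        decay = fit_exponential_decay(df)
        assert not decay.fit.converged

    def test_censored_exclusion_is_logged(self):
        t = np.asarray([0, 1, 2, 4, 8], dtype=float)
        vals = 500.0 * np.exp(-0.34 * t)
        censored = [False, False, False, False, True]
        df = make_concentration_frame(t, vals, censored=censored)
        decay = fit_exponential_decay(df)
        assert "1 censored" in decay.fit.message
        assert decay.fit.n_obs == 4


def test_interval_coverage_under_study_design():
    """True rate constants fall inside the Wald 95% intervals in most seeded
    repetitions of the 4-run x 2-duplicate design at 10% CV (spot check; the
    full 200-repetition study runs in the acceptance suite)."""
    from rumentox import recovery_study

    rep = recovery_study(n_reps=25, cv=0.10, seed=11)
    assert rep["coverage_k"] >= 0.8 and rep["coverage_l"] >= 0.8
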