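"""One-compartment kinetics: closed forms against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

import floxpk as fx
from floxpk.pk import _ss_fraction_above


class TestEliminationRate:
    def test_typical_patient(self, typical_params):
        k = fx.elimination_rate(typical_params)
        assert k == pytest.approx(75.24 / 330.0)
        assert typical_params.half_life == pytest.approx(3.04, abs=0.01)

    def test_identity_when_cl_equals_v(self):
        p = fx.IndividualParameters(42.0, 42.0, 0.5)
        assert fx.elimination_rate(p) == pytest.approx(1.0)

    @pytest.mark.parametrize("cl,v,fu", [(0.0, 10.0, 0.2), (10.0, 0.0, 0.2), (10.0, 10.0, 0.0), (10.0, 10.0, 1.5)])
    def test_invalid_parameters_rejected(self, cl, v, fu):
        with pytest.raises(ValueError):
            fx.IndividualParameters(cl, v, fu)


class TestConcentration:
    def test_zero_before_any_infusion(self, typical_params):
        doses = [fx.DoseEvent(1.0, 2000.0, 0.5)]
        assert fx.concentration_total(typical_params, doses, 0.0) == 0.0
        assert fx.concentration_total(typical_params, doses, 1.0) == 0.0

    def test_matches_ode_integration(self, typical_params):
        """Closed-form superposition vs Runge-Kutta on dC/dt = R(t)/V - kC."""
        doses = [fx.DoseEvent(0.0, 2000.0, 0.5), fx.DoseEvent(6.0, 1000.0, 0.5)]

        def rhs(t, y):
            rate = sum(d.rate for d in doses if d.start_time < t <= d.start_time + d.duration)
            return [rate / typical_params.v - typical_params.k_el * y[0]]

        ts = np.linspace(0.0, 24.0, 400)
        sol = solve_ivp(rhs, (0.0, 24.0), [0.0], t_eval=ts, rtol=1e-10, atol=1e-13,
                        max_step=0.01)
        closed = fx.concentration_total(typical_params, doses, ts)
        assert np.max(np.abs(closed - sol.y[0])) < 1e-6

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_linearity_in_dose(self, scale):
        p = fx.IndividualParameters(75.24, 330.0, 0.217)
        doses = [fx.DoseEvent(0.0, 2000.0, 0.5), fx.DoseEvent(4.0, 2000.0, 0.5)]
        scaled = [fx.DoseEvent(d.start_time, d.amount * scale, d.duration) for d in doses]
        ts = np.linspace(0.1, 12.0, 30)
        c1 = np.asarray(fx.concentration_total(p, doses, ts))
        c2 = np.asarray(fx.concentration_total(p, scaled, ts))
        assert np.allclose(c2, scale * c1, rtol=1e-12)


class TestSteadyState:
    def test_continuous_level_is_rate_over_clearance(self, typical_params, continuous_12g):
        prof = fx.steady_state_profile(typical_params, continuous_12g, 50)
        assert np.allclose(prof.total, 500.0 / 75.24)
        assert prof.total[0] == pytest.approx(6.645, abs=1e-3)
        assert prof.unbound[0] == pytest.approx(1.442, abs=1e-3)

    def test_continuous_level_independent_of_volume(self, continuous_12g):
        p1 = fx.IndividualParameters(75.24, 100.0, 0.217)
        p2 = fx.IndividualParameters(75.24, 900.0, 0.217)
        c1 = fx.steady_state_profile(p1, continuous_12g, 10).total
        c2 = fx.steady_state_profile(p2, continuous_12g, 10).total
        assert np.allclose(c1, c2)

    @pytest.mark.parametrize("interval,dose", [(4.0, 12000.0), (6.0, 4000.0), (4.0, 6000.0)])
    def test_matches_long_superposition(self, typical_params, interval, dose):
        """Closed-form steady state vs 50 superposed doses."""
        r = fx.DosingRegimen(dose, "intermittent", interval=interval, infusion_duration=0.5)
        n = 201
        prof = fx.steady_state_profile(typical_params, r, n)
        doses = r.dose_events(50 * interval)
        t = 49 * interval + np.linspace(0.0, interval, n, endpoint=False)
        long_run = fx.concentration_total(typical_params, doses, t)
        assert np.max(np.abs(prof.total - long_run)) < 1e-6

    def test_unbound_is_fu_times_total(self, typical_params, q4h_regimen):
        prof = fx.steady_state_profile(typical_params, q4h_regimen, 101)
        assert np.allclose(prof.unbound, 0.217 * prof.total)


class TestFractionTimeAbove:
    def test_continuous_below_threshold(self, typical_params, continuous_12g):
        # steady unbound level 1.442 mg/L never exceeds 2 mg/L
        assert fx.fraction_time_above(typical_params, continuous_12g, 2.0) == 0.0

    def test_continuous_above_threshold(self, typical_params, continuous_12g):
        assert fx.fraction_time_above(typical_params, continuous_12g, 1.0) == 100.0

    def test_threshold_zero_gives_full_interval(self, typical_params, q4h_regimen):
        assert fx.fraction_time_above(typical_params, q4h_regimen, 0.0) == 100.0

    def test_negative_threshold_rejected(self, typical_params, q4h_regimen):
        with pytest.raises(ValueError):
            fx.fraction_time_above(typical_params, q4h_regimen, -1.0)

    def test_against_dense_grid(self, typical_params, q4h_regimen):
        """Analytic crossing times vs a 10,000-point time-grid evaluation."""
        analytic = fx.fraction_time_above(typical_params, q4h_regimen, 2.0)
        prof = fx.steady_state_profile(typical_params, q4h_regimen, 10000)
        grid = 100.0 * np.mean(prof.unbound > 2.0)
        assert analytic == pytest.approx(grid, abs=0.1)

    @given(thr1=st.floats(0.0, 10.0), thr2=st.floats(0.0, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_non_increasing_in_threshold(self, thr1, thr2):
        p = fx.IndividualParameters(40.0, 250.0, 0.3)
        r = fx.DosingRegimen(6000.0, "intermittent", interval=6.0, infusion_duration=0.5)
        lo, hi = sorted((thr1, thr2))
        assert fx.fraction_time_above(p, r, lo) >= fx.fraction_time_above(p, r, hi)

    def test_non_decreasing_in_daily_dose(self, typical_params):
        fracs = [
            fx.fraction_time_above(
                typical_params,
                fx.DosingRegimen(d, "intermittent", interval=6.0, infusion_duration=0.5),
                2.0,
            )
            for d in (2000.0, 4000.0, 8000.0, 16000.0)
        ]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_vectorized_matches_scalar(self, q4h_regimen):
        cl = np.array([30.0, 75.24, 120.0])
        v = np.array([200.0, 330.0, 500.0])
        fu = np.array([0.1, 0.217, 0.4])
        vec = _ss_fraction_above(cl, v, fu, q4h_regimen, 2.0)
        for i in range(3):
            p = fx.IndividualParameters(cl[i], v[i], fu[i])
            assert vec[i] == pytest.approx(fx.fraction_time_above(p, q4h_regimen, 2.0))


class TestDosingRegimen:
    def test_continuous_normalizes_interval(self):
        r = fx.DosingRegimen(6000.0, "continuous", interval=7.0)
        assert r.interval == 24.0 and r.infusion_duration == 24.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(daily_dose=-1.0),
            dict(daily_dose=6000.0, mode="intermittent", interval=5.0),
            dict(daily_dose=6000.0, mode="intermittent", interval=4.0, infusion_duration=5.0),
            dict(daily_dose=6000.0, mode="bolus"),
        ],
    )
    def test_invalid_regimens_rejected(self, kwargs):
        with pytest.raises(ValueError):
            fx.DosingRegimen(**kwargs)

    def test_dose_events_cover_course(self, q4h_regimen):
        events = q4h_regimen.dose_events(48.0)
        assert len(events) == 12
        assert events[0].amount == pytest.approx(2000.0)
        assert all(e.duration == 0.5 for e in events)
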