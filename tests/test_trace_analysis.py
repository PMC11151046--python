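"""Amplification-time extraction, linear-phase fitting, endpoints and the
endpoint-versus-At regression."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from celia import (
    Trace,
    ValidationError,
    amplification_time,
    build_exponential_module,
    build_linear_module,
    coupled_circuit,
    endpoint_signal,
    endpoint_vs_at_regression,
    linear_phase_fit,
    simulate_ode,
)
from scipy import stats


class TestAmplificationTime:
    def test_linear_interpolation_between_samples(self):
        tr = Trace([0.0, 10.0, 20.0], [0.0, 0.4, 1.2])
        res = amplification_time(tr, {"absolute": 1.0})
        assert res.crossed
        assert res.at == pytest.approx(10 + 10 * (1.0 - 0.4) / (1.2 - 0.4))  # 17.5

    def test_flat_trace_never_crosses(self):
        tr = Trace(np.arange(5.0), np.zeros(5))
        res = amplification_time(tr, {"absolute": 0.5})
        assert not res.crossed and res.at is None

    def test_threshold_not_above_start_rejected(self):
        tr = Trace([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValidationError):
            amplification_time(tr, {"absolute": 0.5})

    def test_non_monotone_time_axis_rejected(self):
        with pytest.raises(ValidationError):
            amplification_time(Trace([0.0, 2.0, 1.0], [0.0, 1.0, 2.0]), {"absolute": 0.5})

    def test_fraction_of_max_threshold(self):
        tr = Trace(np.arange(11.0), np.arange(11.0))
        res = amplification_time(tr, {"fraction_of_max": 0.5})
        assert res.threshold_used == pytest.approx(5.0)
        assert res.at == pytest.approx(5.0)

    def test_baseline_correction_subtracts_initial_offset(self):
        tr = Trace(np.arange(8.0), 2.0 + np.array([0, 0, 0, 0, 1, 2, 3, 4.0]))
        res = amplification_time(tr, {"absolute": 2.0}, baseline_correct=True)
        assert res.at == pytest.approx(5.0)  # corrected trace crosses 2.0 at t=5

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.01, 0.99), min_size=2, max_size=2, unique=True))
    def test_monotone_in_threshold_on_nondecreasing_trace(self, fracs):
        tr = Trace(np.arange(30.0), np.minimum(np.arange(30.0) ** 1.5, 80.0))
        lo, hi = sorted(fracs)
        a_lo = amplification_time(tr, {"fraction_of_max": lo}).at
        a_hi = amplification_time(tr, {"fraction_of_max": hi}).at
        assert a_lo <= a_hi

    def test_at_log_linear_in_initiator(self, params, at_threshold_abs):
        """Noise-free exponential module across 5 decades of initiator: At
        versus log10(alpha0) is linear with slope -ln(10)/r_exp within 2%."""
        l10, ats = [], []
        for a0 in np.logspace(-4, 0, 8):
            ts = simulate_ode(build_exponential_module(20, 0, 50, a0, params), 1500, 2.0)
            res = amplification_time(ts.trace("alpha"), {"absolute": at_threshold_abs})
            l10.append(math.log10(a0))
            ats.append(res.at)
        fit = stats.linregress(l10, ats)
        expected = -math.log(10) / params.r_exp
        assert fit.slope == pytest.approx(expected, rel=0.02)
        assert fit.rvalue**2 > 0.999


class TestLinearPhaseFit:
    def test_exact_ramp_with_plateau(self):
        t = np.arange(0.0, 401.0, 1.0)
        v = np.minimum(0.01 * t, 2.0)
        fit = linear_phase_fit(Trace(t, v), sat_fraction=0.99)
        assert fit.gain == pytest.approx(0.01, rel=1e-6)
        assert fit.saturation == pytest.approx(2.0, rel=1e-6)
        assert fit.window == pytest.approx(0.99 * 200.0, rel=1e-6)
        assert fit.r2_fit == pytest.approx(1.0)
        assert not fit.censored

    def test_unsaturated_ramp_censored_at_horizon(self):
        t = np.arange(0.0, 101.0, 1.0)
        fit = linear_phase_fit(Trace(t, 0.01 * t))
        assert fit.censored
        assert fit.window == pytest.approx(100.0)
        assert fit.gain == pytest.approx(0.01, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            linear_phase_fit(Trace([0.0, 1.0, 2.0], [0.0, 1.0, 2.0]))

    @pytest.mark.parametrize("ato", [1.0, 2.0, 5.0, 10.0])
    def test_gain_proportional_to_linear_template(self, params, ato):
        """Gain scales with [alpha_to_omega] at fixed 125 nM reporter."""
        net = build_linear_module(ato, 125.0, params, activated_fraction=1.0)
        ts = simulate_ode(net, 6000, 5.0)
        fit = linear_phase_fit(ts.trace("omega"))
        assert fit.gain == pytest.approx(params.s_F * params.k_lin * ato, rel=0.05)

    @pytest.mark.parametrize("rT", [50.0, 125.0, 200.0])
    def test_saturation_proportional_to_reporter(self, params, rT):
        net = build_linear_module(5.0, rT, params, activated_fraction=1.0)
        ts = simulate_ode(net, 4000, 5.0)
        fit = linear_phase_fit(ts.trace("omega"))
        assert fit.saturation == pytest.approx(params.s_F * rT, rel=0.01)

    @pytest.mark.parametrize("ato,rT", [(2.0, 100.0), (5.0, 125.0)])
    def test_window_identity(self, params, ato, rT):
        """window ~ saturation/gain = [rT_omega]/(k_lin*[alpha_to_omega])."""
        net = build_linear_module(ato, rT, params, activated_fraction=1.0)
        ts = simulate_ode(net, 8000, 5.0)
        fit = linear_phase_fit(ts.trace("omega"))
        assert fit.window == pytest.approx(fit.saturation / fit.gain, rel=0.05)


class TestEndpoint:
    def test_ramp_endpoint(self):
        t = np.arange(0.0, 1001.0, 1.0)
        assert endpoint_signal(Trace(t, 0.01 * t), 1000.0) == pytest.approx(10.0)

    def test_endpoint_at_sample_time_exact(self):
        tr = Trace([0.0, 5.0, 10.0], [0.0, 3.0, 4.0])
        assert endpoint_signal(tr, 5.0) == 3.0

    def test_endpoint_outside_span_rejected(self):
        tr = Trace([0.0, 5.0], [0.0, 1.0])
        with pytest.raises(ValidationError):
            endpoint_signal(tr, 6.0)

    def test_endpoint_nondecreasing_in_time_for_irreversible_channel(self):
        ts = simulate_ode(coupled_circuit(alpha0=1e-2), 1000, 2.0)
        tr = ts.trace("omega")
        eps = [endpoint_signal(tr, t) for t in (200.0, 500.0, 800.0, 1000.0)]
        assert all(b >= a for a, b in zip(eps, eps[1:]))

    def test_late_amplification_endpoint_tracks_remaining_window(self, params, at_threshold_abs):
        """A well whose amplification fires near the end of the run
        accumulates endpoint ~ gain*(horizon - At - onset delay)."""
        a0 = 2.2 * math.exp(-params.r_exp * 900)
        ts = simulate_ode(coupled_circuit(alpha0=a0, params=params), 1000, 2.0)
        at = amplification_time(ts.trace("alpha"), {"absolute": at_threshold_abs}).at
        ep = endpoint_signal(ts.trace("omega"), 1000.0)
        gain = params.s_F * params.k_lin * 2.0
        delta = 1000.0 - at - ep / gain  # implied onset delay
        assert 0 < delta < 60


class TestRegression:
    def test_exact_line_recovered(self):
        at = np.array([10.0, 300.0, 700.0, 1000.0])
        res = endpoint_vs_at_regression(list(zip(at, -0.01 * at + 10.0)))
        assert res.slope == pytest.approx(-0.01)
        assert res.intercept == pytest.approx(10.0)
        assert res.r2 == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            endpoint_vs_at_regression([(1.0, 2.0), (2.0, 3.0)])
        with pytest.raises(ValidationError):
            endpoint_vs_at_regression([(5.0, 1.0), (5.0, 2.0), (5.0, 3.0)])
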