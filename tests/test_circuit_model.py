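"""Structure and kinetics of the circuit builders, validated against
hand-written ODE oracles integrated with fixed-step Euler."""

import math

import numpy as np
import pytest
from conftest import euler_integrate

from celia import (
    KineticParams,
    ValidationError,
    build_converter,
    build_exponential_module,
    build_inverter_module,
    build_linear_module,
    compose,
    coupled_circuit,
    inverter_circuit,
    simulate_ode,
)
from celia.network import RateLaw, Reaction, Species, TemplateSpec
from celia.traces import amplification_time


class TestValidation:
    @pytest.mark.parametrize(
        "builder, kwargs",
        [
            (build_exponential_module, dict(aT_alpha_conc=-1, pT_alpha_conc=0, rT_alpha_conc=0, alpha0=0)),
            (build_exponential_module, dict(aT_alpha_conc=10, pT_alpha_conc=0, rT_alpha_conc=0, alpha0=-2)),
            (build_linear_module, dict(alpha_to_omega_conc=-0.5, rT_omega_conc=10)),
            (build_inverter_module, dict(beta_to_omega_conc=5, beta0=-1, alpha_k_beta_conc=1, rT_omega_conc=10)),
            (build_converter, dict(miR_to_alpha_conc=5, miR_conc_molar=-1e-12)),
        ],
    )
    def test_negative_concentration_rejected_with_field_name(self, builder, kwargs):
        with pytest.raises(ValidationError) as err:
            builder(**kwargs)
        # the error names the offending field
        bad = [k for k, v in kwargs.items() if isinstance(v, (int, float)) and v < 0][0]
        stem = bad.split("_conc")[0]
        assert stem in err.value.field

    def test_rate_law_constants_must_be_positive(self):
        with pytest.raises(ValidationError):
            RateLaw("mass-action", 0.0)
        with pytest.raises(ValidationError):
            RateLaw("saturating", 1.0, half_saturation=-1.0, driver="x")

    def test_species_cannot_be_reactant_and_modifier(self):
        with pytest.raises(ValidationError):
            Reaction(
                "bad",
                reactants=(("x", 1),),
                modifiers=("x",),
                law=RateLaw("mass-action", 1.0),
            )

    def test_template_activation_mode_fixed_by_chemistry(self):
        with pytest.raises(ValidationError):
            TemplateSpec("alpha_to_omega", 2.0, "reversible")
        with pytest.raises(ValidationError):
            TemplateSpec("beta_to_omega", 2.0, "irreversible")
        assert TemplateSpec("alpha_to_omega", 2.0, "irreversible").total_conc == 2.0

    def test_kinetic_params_positive(self):
        with pytest.raises(ValidationError):
            KineticParams(r_exp=-0.01)


class TestCompose:
    def test_coupled_circuit_structure(self):
        net = coupled_circuit(alpha0=0.1)
        assert set(net.reporters) == {"alpha", "omega"}
        assert "pT_beta" not in net.species
        assert "alpha_to_omega_inactive" in net.species

    def test_inverter_circuit_structure(self):
        net = inverter_circuit(alpha0=0.1)
        assert {"pT_beta", "beta", "beta_i"} <= set(net.species)

    def test_single_module_compose_is_identity(self):
        mod = build_linear_module(2.0, 50.0, activated_fraction=1.0)
        ts1 = simulate_ode(mod, 100, 10.0)
        ts2 = simulate_ode(compose([mod]), 100, 10.0)
        np.testing.assert_array_equal(ts1.channel("omega"), ts2.channel("omega"))

    def test_shared_species_initials_sum(self):
        a = build_exponential_module(20, 0, 50, alpha0=0.5)
        b = build_linear_module(2.0, 200.0)
        net = compose([a, b])
        assert net.initial["alpha"] == pytest.approx(0.5)

    def test_conflicting_role_rejected(self):
        a = build_linear_module(2.0, 200.0)
        b = build_linear_module(2.0, 200.0)
        bad = b.copy()
        bad.species["alpha"] = Species("alpha", "inert")
        with pytest.raises(ValidationError):
            compose([a, bad])

    def test_duplicate_channel_rejected(self):
        a = build_linear_module(2.0, 200.0)
        b = build_linear_module(2.0, 100.0)  # different reporter definition
        with pytest.raises(ValidationError):
            compose([a, b])


class TestExponentialModule:
    def test_empty_initiator_fixed_point(self):
        net = build_exponential_module(20, 0, 50, alpha0=0.0)
        ts = simulate_ode(net, 500, 10.0)
        assert np.all(ts.species("alpha") == 0)
        assert np.all(ts.channel("alpha") == 0)

    def test_strong_pseudotemplate_suppresses_amplification(self, params):
        # pT high enough that deactivation beats net growth: alpha decays
        pT = 3.0 * params.r_exp / params.k_deact
        net = build_exponential_module(20, pT, 50, alpha0=0.1, params=params)
        ts = simulate_ode(net, 1000, 10.0)
        alpha = ts.species("alpha")
        assert alpha[-1] < 1e-6
        assert np.all(np.diff(alpha) <= 1e-12)

        # Euler oracle on the hand-written 3-ODE system
        p = params
        k_grow = p.r_exp + p.k_deg

        def rhs(y):
            a, ai, _ = y
            growth = k_grow * a * (1 - a / p.alpha_max)
            deact = p.k_deact * pT * a
            return np.array([growth - deact - p.k_deg * a, deact, 0.0])

        _, states = euler_integrate(rhs, [0.1, 0.0, 0.0], 200.0, dt=1e-3)
        ode = simulate_ode(net, 200, 200.0)
        assert ode.species("alpha")[-1] == pytest.approx(states[-1, 0], rel=1e-3)

    def test_doubling_initiator_advances_at_by_ln2_over_rate(self, params, at_threshold_abs):
        ats = []
        for a0 in (1e-3, 2e-3):
            ts = simulate_ode(build_exponential_module(20, 0, 50, a0, params), 1200, 2.0)
            ats.append(amplification_time(ts.trace("alpha"), {"absolute": at_threshold_abs}).at)
        shift = ats[0] - ats[1]
        assert shift == pytest.approx(math.log(2) / params.r_exp, rel=0.01)


class TestLinearModule:
    def test_preactivated_gain_matches_euler_oracle(self, params):
        # 5 nM fully active template, reporter in excess: QSS slope = k_lin*[active]
        p = params
        net = build_linear_module(5.0, 500.0, p, activated_fraction=1.0)
        ts = simulate_ode(net, 500, 2.0)
        chan = ts.channel("omega")
        slope = (chan[-1] - chan[-50]) / (ts.times[-1] - ts.times[-50])
        assert slope == pytest.approx(p.k_lin * 5.0 * p.s_F, rel=1e-3)

        def rhs(y):
            om, intact, reacted = y
            prod = p.k_lin * 5.0
            rep = p.k_rep * om * intact
            return np.array([prod - rep, -rep, rep])

        times, states = euler_integrate(rhs, [0.0, 500.0, 0.0], 500.0, dt=1e-3, record_every=100)
        for t, s in zip(times[1:], states[1:]):
            i = int(t / 2)
            assert chan[i] == pytest.approx(p.s_F * s[2], rel=1e-3)

    def test_no_reporter_no_signal(self):
        net = build_linear_module(5.0, 0.0, activated_fraction=1.0)
        ts = simulate_ode(net, 200, 10.0)
        assert np.all(ts.channel("omega") == 0)
        assert ts.species("omega")[-1] > 1.0  # omega still accumulates

    @pytest.mark.parametrize("rT", [50.0, 125.0, 200.0])
    def test_saturation_equals_reporter_total(self, params, rT):
        net = build_linear_module(5.0, rT, params, activated_fraction=1.0)
        ts = simulate_ode(net, 3000, 5.0)
        assert ts.channel("omega")[-1] == pytest.approx(params.s_F * rT, rel=0.01)


class TestInverterModule:
    def test_without_alpha_and_leak_behaves_as_pure_linear_ramp(self, params):
        p = params.replace(leak_kill=1e-12)  # leak off (constants must stay > 0)
        net = build_inverter_module(10.0, 2.0, 1.0, 30.0, p)
        ts = simulate_ode(net, 4000, 5.0)
        chan = ts.channel("omega")
        early_slope = (chan[20] - chan[10]) / (ts.times[20] - ts.times[10])
        expected = p.s_F * p.k_lin * 10.0 * 2.0 / (p.K_beta + 2.0)
        assert early_slope == pytest.approx(expected, rel=0.02)
        assert chan[-1] == pytest.approx(p.s_F * 30.0, rel=0.01)  # reporter exhaustion

    def test_saturating_alpha_kills_beta_early(self, params):
        net = compose(
            [
                build_exponential_module(20, 0, 50, alpha0=50.0, params=params),
                build_inverter_module(10.0, 2.0, 1.0, 200.0, params),
            ]
        )
        ts = simulate_ode(net, 1000, 2.0)
        assert ts.species("beta")[-1] < 1e-3
        # endpoint far below what the uninhibited ramp would give
        uninhibited = params.k_lin * 10.0 * 2.0 / (params.K_beta + 2.0) * 1000
        assert ts.channel("omega")[-1] < 0.25 * uninhibited

    def test_full_inverter_matches_euler_oracle(self, params):
        p = params
        net = inverter_circuit(alpha0=0.05, params=p)
        ts = simulate_ode(net, 600, 2.0)

        k_grow = p.r_exp + p.k_deg
        bto, akb, rT = 10.0, 1.0, 200.0

        def rhs(y):
            a, b, bi, pTb, om, intact, reacted = y
            growth = k_grow * a * (1 - a / p.alpha_max)
            da = growth - p.k_deg * a
            prod = p.k_lin * bto * b / (p.K_beta + b)
            kill = p.k_kill * akb * a / (p.K_exp + a) + p.leak_kill * akb
            deact = p.k_deact * pTb * b
            rep = p.k_rep * om * intact
            return np.array(
                [da, -deact, deact, kill - p.k_degP * pTb, prod - rep, -rep, rep]
            )

        times, states = euler_integrate(
            rhs, [0.05, 2.0, 0.0, 0.0, 0.0, rT, 0.0], 600.0, dt=1e-3, record_every=200
        )
        for t, s in zip(times[1:], states[1:]):
            i = int(t / 2)
            assert ts.channel("omega")[i] == pytest.approx(p.s_F * s[6], rel=1e-3)

    def test_leak_slows_omega_production_without_alpha(self, params):
        net = build_inverter_module(10.0, 2.0, 1.0, 500.0, params)
        ts = simulate_ode(net, 2000, 5.0)
        chan = ts.channel("omega")
        slopes = np.gradient(chan, ts.times)
        assert slopes[-10] < 0.8 * slopes[10]  # production rate decays from leak alone


class TestConverter:
    def test_zero_target_means_no_alpha_source(self):
        net = build_converter(10.0, 0.0)
        ts = simulate_ode(net, 500, 10.0)
        assert np.all(ts.species("alpha") == 0)

    def test_tenfold_target_advances_at_by_one_decade(self, params, at_threshold_abs):
        from celia import quantification_circuit

        ats = []
        for conc in (1e-13, 1e-12):
            ts = simulate_ode(quantification_circuit(conc, params=params), 1000, 2.0)
            ats.append(amplification_time(ts.trace("alpha"), {"absolute": at_threshold_abs}).at)
        assert ats[0] - ats[1] == pytest.approx(math.log(10) / params.r_exp, rel=0.02)

    def test_converters_interchangeable_up_to_label(self):
        a = build_converter(10.0, 1e-12, target_name="let-7a")
        b = build_converter(10.0, 1e-12, target_name="miR-203a")
        tsa = simulate_ode(a, 200, 10.0)
        tsb = simulate_ode(b, 200, 10.0)
        np.testing.assert_array_equal(tsa.species("alpha"), tsb.species("alpha"))


class TestConservation:
    @pytest.mark.parametrize("factory", [
        lambda: coupled_circuit(alpha0=1e-2),
        lambda: inverter_circuit(alpha0=1e-2),
    ])
    def test_template_and_reporter_totals_conserved(self, factory):
        net = factory()
        ts = simulate_ode(net, 1000, 10.0)
        for tmpl in net.templates:
            if not tmpl.state_species or tmpl.total_conc == 0:
                continue
            total = sum(ts.species(s) for s in tmpl.state_species)
            np.testing.assert_allclose(total, tmpl.total_conc, rtol=1e-6)

    def test_zero_input_fixed_point(self, params):
        p = params.replace(leak_kill=1e-15)
        net = inverter_circuit(alpha0=0.0, beta0=0.0, params=p)
        ts = simulate_ode(net, 500, 10.0)
        for name in net.species:
            np.testing.assert_allclose(
                ts.species(name), ts.species(name)[0], atol=1e-9
            )
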