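"""Flux terms, the reference-differenced ODE and its oracles."""

import numpy as np
import pytest

from leafkin.energy_balance import (
    SolverConfig,
    ThermalObjectProps,
    budget_terms,
    differenced_rhs,
    full_budget_rhs,
    net_radiation,
    predict_temperature,
    predict_temperature_fast,
    sensible_heat,
    steady_state_temperature,
    total_conductance,
    transpiration,
)
from leafkin.physics import (
    STEFAN_BOLTZMANN,
    AirState,
    air_density,
    air_vapour_pressure,
    humid_air_specific_heat,
    latent_heat,
    molar_density,
    saturation_vapour_pressure,
)
from leafkin.signals import PiecewiseSmoothSignal, Trace, smooth

AIR20 = AirState(293.15, 0.5, 101325.0)


def _props(**kw):
    base = dict(alpha=0.7, epsilon=0.96, k=900.0, g_bh=0.0143,
                transpiring_sides=2, light_scale=1.0)
    base.update(kw)
    return ThermalObjectProps(**base)


class TestFluxTerms:
    def test_net_radiation_zero_for_transparent_nonemissive_object(self):
        p = _props(alpha=0.0, epsilon=0.0)
        assert net_radiation(p, 500.0, 310.0, 0.0) == 0.0

    def test_net_radiation_balances_constructed_longwave(self):
        p = _props(alpha=0.5, epsilon=0.96)
        T = 295.0
        ld = 2 * STEFAN_BOLTZMANN * 0.96 * T ** 4
        assert net_radiation(p, 0.0, T, ld) == pytest.approx(0.0, abs=1e-9)

    def test_net_radiation_hand_computed_terms(self):
        p = _props(alpha=0.96, epsilon=0.96)
        ld = 2 * STEFAN_BOLTZMANN * 0.96 * 288.15 ** 4
        expected = (0.96 * 100.0
                    - 2 * STEFAN_BOLTZMANN * 0.96 * 293.15 ** 4
                    + ld)
        assert net_radiation(p, 100.0, 293.15, ld) == pytest.approx(expected, rel=1e-12)

    def test_sensible_heat_zero_at_air_temperature_and_signed(self):
        p = _props(g_bh=0.01)
        assert sensible_heat(p, AIR20.T_air, AIR20) == 0.0
        assert sensible_heat(p, 295.15, AIR20) > 0
        assert sensible_heat(p, 291.15, AIR20) < 0

    def test_sensible_heat_product_of_property_oracles(self):
        air = AirState(293.15, 0.0, 101325.0)
        p = _props(g_bh=0.01)
        expected = 2 * 0.01 * air_density(air) * humid_air_specific_heat(air) * 1.0
        assert sensible_heat(p, 294.15, air) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(24.2, rel=0.01)

    def test_total_conductance_series_limits(self):
        assert total_conductance(1e12, 0.5) == pytest.approx(0.5)
        assert total_conductance(0.3, 0.3) == pytest.approx(0.15)
        assert total_conductance(1.284, 0.5) == pytest.approx(0.3599, rel=5e-4)
        assert total_conductance(0.0, 0.5) == 0.0
        assert total_conductance(0.5, 0.0) == 0.0

    def test_transpiration_zero_cases_and_hand_computation(self):
        assert transpiration(0.0, 294.15, AIR20) == 0.0
        sat_air = AirState(294.15, 1.0, 101325.0)
        assert transpiration(0.36, 294.15, sat_air) == pytest.approx(0.0, abs=1e-12)
        # term-by-term with oracle property values
        g_tw, T = 0.36, 294.15
        rho = air_density(AIR20)
        e_grad = saturation_vapour_pressure(T) - air_vapour_pressure(AIR20)
        expected = (0.622 * rho / 101325.0) * (8.31446 * T / 101325.0) * g_tw * e_grad
        assert transpiration(g_tw, T, AIR20) == pytest.approx(expected, rel=1e-12)

    def test_transpiration_condensation_clamped(self, caplog):
        dry_leaf = 283.15  # cold leaf in humid warm air -> condensation
        humid = AirState(303.15, 1.0, 101325.0)
        with caplog.at_level("WARNING"):
            E = transpiration(0.4, dry_leaf, humid)
        assert E == 0.0
        E_free = transpiration(0.4, dry_leaf, humid, clamp=False)
        assert E_free < 0

    def test_flux_breakdown_identity(self, short_protocol):
        env = short_protocol.exact_environment()
        fb = budget_terms(294.0, 400.0, _props(), env, L_d=400.0,
                          sw_factor=short_protocol.sw_factor, g_sw=0.3)
        assert fb.storage == fb.Rn - fb.C - fb.latent


class TestDifferencedRhs:
    def test_identical_objects_reduce_to_reference_derivative(self, short_protocol):
        env = short_protocol.exact_environment()
        t = np.linspace(0.0, 1000.0, 30)
        ref = smooth(
            Trace(t, 293.15 + 0.5 * np.sin(t / 200.0)))
        p = _props(transpiring_sides=0)
        for tq in (100.0, 500.0, 900.0):
            d = differenced_rhs(float(ref.value(tq)), tq, ref, env, p, p, 0.0,
                                short_protocol.sw_factor)
            assert d == pytest.approx(float(ref.derivative(tq)), abs=1e-12)

    def test_latent_flux_always_cools(self, short_protocol):
        env = short_protocol.exact_environment()
        t = np.linspace(0.0, 1000.0, 30)
        ref = smooth(Trace(t, np.full_like(t, 293.15)))
        p = _props(transpiring_sides=0)
        base = differenced_rhs(293.15, 500.0, ref, env, p, p, 0.0,
                               short_protocol.sw_factor)
        cooled = differenced_rhs(293.15, 500.0, ref, env, p, p, 50.0,
                                 short_protocol.sw_factor)
        assert cooled < base

    def test_transpiring_reference_rejected(self, short_protocol):
        env = short_protocol.exact_environment()
        t = np.linspace(0.0, 100.0, 10)
        ref = smooth(Trace(t, np.full_like(t, 293.15)))
        with pytest.raises(ValueError, match="non-transpiring"):
            differenced_rhs(293.15, 50.0, ref, env, _props(), _props(), 0.0, 0.22)

    def test_differenced_equals_budget_difference_oracle(self, short_protocol, rng):
        # algebraic identity: differenced RHS == full budget of object 1
        # with the L_d term eliminated through object 2's budget
        env = short_protocol.exact_environment()
        t = np.linspace(0.0, 1000.0, 40)
        y = 293.15 + np.cumsum(0.01 * rng.standard_normal(t.size))
        ref = smooth(Trace(t, y), 0.0)
        p1 = _props(alpha=0.7, k=900.0, g_bh=0.012, transpiring_sides=0)
        p2 = _props(alpha=0.95, epsilon=0.93, k=2300.0, g_bh=0.015,
                    transpiring_sides=0)
        for tq in rng.uniform(10, 990, size=5):
            T1 = 293.0 + rng.uniform(-2, 2)
            ld = rng.uniform(300, 500)
            T2 = float(ref.value(tq))
            lhs = differenced_rhs(T1, tq, ref, env, p1, p2, 0.0,
                                  short_protocol.sw_factor)
            rhs1 = full_budget_rhs(T1, tq, p1, env, ld, short_protocol.sw_factor)
            rhs2 = full_budget_rhs(T2, tq, p2, env, ld, short_protocol.sw_factor)
            expected = rhs1 + (p2.k / p1.k) * (float(ref.derivative(tq)) - rhs2)
            assert lhs == pytest.approx(expected, rel=1e-10, abs=1e-12)


class TestPredictTemperature:
    def test_zero_conductance_identity_follows_reference(self, short_protocol,
                                                         short_experiment):
        env = short_protocol.exact_environment()
        black = short_experiment.clean["black"]
        ref = PiecewiseSmoothSignal(black, short_protocol.switch_times, 0.0)
        props = short_experiment.truth["black_props"]
        # identity check at 1e-5 K needs rtol well below 1e-5/T ~ 3e-8
        pred = predict_temperature(props, props, ref, env, None, black.y[0],
                                   black.t, short_protocol.sw_factor,
                                   SolverConfig(rtol=1e-10, atol=1e-10))
        assert np.max(np.abs(pred.y - black.y)) < 1e-5

    def test_terminal_state_matches_steady_state_root(self):
        # constant environment, fixed conductance: after many thermal
        # time constants the ODE must land on the algebraic equilibrium
        from leafkin.synthetic import Protocol

        proto = Protocol(durations=(4000.0,), levels=(430.0,),
                         dT_air_light=0.0, dRH_light=0.0, noise_sd=0.0,
                         wall_temp=293.15)
        env = proto.exact_environment()
        p1 = _props(g_bh=0.0143, transpiring_sides=2)
        p2 = _props(alpha=0.95, k=2309.0, transpiring_sides=0,
                    light_scale=proto.ref_light_scale)
        ld = 2 * STEFAN_BOLTZMANN * 293.15 ** 4
        air = AirState(293.15, proto.rh0, proto.p_atm)
        t_ref = np.arange(0.0, 4000.0, 3.0)
        T2_eq = steady_state_temperature(p2, 430.0 * proto.sw_factor, ld, air)
        ref = smooth(Trace(t_ref, np.full_like(t_ref, T2_eq)), 0.0)
        g = 0.3
        pred = predict_temperature(p1, p2, ref, env, g, 293.15, t_ref,
                                   proto.sw_factor)
        expected = steady_state_temperature(p1, 430.0 * proto.sw_factor, ld, air, g_sw=g)
        tau = p1.k / 45.0  # ~20 s; 4000 s >> 20 tau
        assert abs(pred.y[-1] - expected) < 1e-3

    def test_stiff_solver_matches_fine_rk4_oracle(self, short_protocol,
                                                  short_experiment):
        env = short_protocol.exact_environment()
        black = short_experiment.clean["black"]
        ref = PiecewiseSmoothSignal(black, short_protocol.switch_times, 0.0)
        p1 = short_experiment.truth["leaf_props"]
        p2 = short_experiment.truth["black_props"]
        gs = (short_experiment.truth["gs"], short_protocol.schedule)
        t_eval = black.t[black.t <= 600.0]
        T0 = short_experiment.clean["leaf"].y[0]
        bdf = predict_temperature(p1, p2, ref, env, gs, T0, t_eval,
                                  short_protocol.sw_factor,
                                  SolverConfig(rtol=1e-8, atol=1e-10))
        rk4 = predict_temperature_fast(p1, p2, ref, env, gs, T0, t_eval,
                                       short_protocol.sw_factor, dt=0.01)
        assert np.max(np.abs(bdf.y - rk4.y)) < 1e-3

    def test_solver_tolerance_refinement_stable(self, short_protocol,
                                                short_experiment):
        env = short_protocol.exact_environment()
        black = short_experiment.clean["black"]
        ref = PiecewiseSmoothSignal(black, short_protocol.switch_times, 0.0)
        p1 = short_experiment.truth["leaf_props"]
        p2 = short_experiment.truth["black_props"]
        gs = (short_experiment.truth["gs"], short_protocol.schedule)
        t_eval = black.t[black.t <= 400.0]
        T0 = short_experiment.clean["leaf"].y[0]
        coarse = predict_temperature(p1, p2, ref, env, gs, T0, t_eval,
                                     short_protocol.sw_factor,
                                     SolverConfig(rtol=1e-6, atol=1e-8))
        fine = predict_temperature(p1, p2, ref, env, gs, T0, t_eval,
                                   short_protocol.sw_factor,
                                   SolverConfig(rtol=5e-7, atol=5e-9))
        # change bounded by the coarse run's own tolerance (rtol * T)
        assert np.max(np.abs(coarse.y - fine.y)) < 1e-6 * 300.0

    def test_output_grid_outside_domain_rejected(self, short_protocol,
                                                 short_experiment):
        env = short_protocol.exact_environment()
        black = short_experiment.clean["black"]
        ref = smooth(black)
        p = short_experiment.truth["black_props"]
        with pytest.raises(ValueError, match="beyond the signal domains"):
            predict_temperature(p, p, ref, env, None, black.y[0],
                                np.array([0.0, 1e6]), short_protocol.sw_factor)


class TestLinearizedRelaxation:
    def test_step_response_initial_slope_and_time_constant(self):
        # from equilibrium, an irradiance step of dI changes only the
        # absorbed shortwave at t=0+: slope = alpha*dI/k exactly; the
        # subsequent relaxation is exponential with
        # tau = k / (8*theta*eps*T^3 + 2*g_bh*rho*Cs) in the linear regime
        from leafkin.synthetic import Protocol

        proto = Protocol(durations=(600.0, 3000.0), levels=(0.0, 430.0),
                         dT_air_light=0.0, dRH_light=0.0, noise_sd=0.0,
                         wall_temp=293.15, ref_light_scale=1.0)
        env = proto.exact_environment()
        p = _props(transpiring_sides=0, g_bh=0.0143, k=2309.0, alpha=0.95)
        air = AirState(293.15, proto.rh0, proto.p_atm)
        ld = 2 * STEFAN_BOLTZMANN * 293.15 ** 4
        T_eq = steady_state_temperature(p, 0.0, ld, air)
        dI = 430.0 * proto.sw_factor
        slope = full_budget_rhs(T_eq, 600.5, p, env, ld, proto.sw_factor)
        assert slope == pytest.approx(p.alpha * dI / p.k, rel=1e-6)

        rho = air_density(air)
        cs = humid_air_specific_heat(air)
        tau = p.k / (8 * STEFAN_BOLTZMANN * p.epsilon * T_eq ** 3
                     + 2 * p.g_bh * rho * cs)
        T_end = steady_state_temperature(p, dI, ld, air)
        # reference: a non-absorbing object resting at its own
        # equilibrium, so its constant trace is dynamically consistent
        p_ref = _props(alpha=0.0, k=2309.0, transpiring_sides=0)
        T_ref = steady_state_temperature(p_ref, 0.0, ld, air)
        pred = predict_temperature_fast(
            p, p_ref,
            smooth(Trace(
                np.arange(0.0, 3600.0, 3.0),
                np.full(1200, T_ref)), 0.0),
            env, None, T_eq, np.arange(600.0, 3600.0, 3.0),
            proto.sw_factor, dt=0.5)
        # compare against the one-time-constant exponential within the
        # small-signal range (the full model is mildly nonlinear in T^4)
        t_rel = pred.t - 600.0
        analytic = T_end + (T_eq - T_end) * np.exp(-t_rel / tau)
        mask = t_rel < 3 * tau
        assert np.max(np.abs(pred.y[mask] - analytic[mask])) < 0.05
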