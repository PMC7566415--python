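"""Rate fits, gating kinetics, channel conductances and model building."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hhsim.circuit_core import CircuitModel
from hhsim.hh_library import (
    ALPHA_H,
    ALPHA_M,
    ALPHA_N,
    BETA_H,
    BETA_M,
    BETA_N,
    DegenerateRatesError,
    ExponentialFit,
    Gate,
    GoldmanFit,
    HHParameters,
    LeakChannel,
    LogisticFit,
    ParameterError,
    SodiumChannel,
    TauInfGate,
    build_hh_model,
    build_slow_inactivation_sodium,
    exp_fit,
    gate_derivative,
    gate_steady_state,
    goldman_fit,
    logistic_fit,
    potassium_conductance,
    sodium_conductance,
    tau_inf_gate_derivative,
    temperature_factor,
)
from hhsim.simulation import ExperimentConfig, integrate


class TestFitFunctions:
    @pytest.mark.parametrize(
        "x, sx, sy, expected",
        [
            (0.0, 0.3, 2.5, 2.5),  # exp(0) = 1
            (1.0, 1.0, 1.0, math.e),
            (0.0, 1.0 / 80.0, 0.125, 0.125),  # K closing rate at rest
        ],
    )
    def test_exp_fit(self, x, sx, sy, expected):
        assert exp_fit(x, sx, sy) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "x, x0, sx, sy, expected",
        [
            (-30.0, -30.0, 0.1, 1.0, 0.5),  # midpoint
            (0.0, -30.0, 0.1, 1.0, 0.04742587317756678),  # Na inactivation closing
            (42.0, -30.0, 0.0, 1.0, 0.5),  # flat logistic in the sx → 0 limit
        ],
    )
    def test_logistic_fit(self, x, x0, sx, sy, expected):
        assert logistic_fit(x, x0, sx, sy) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "x, x0, sx, sy, expected",
        [
            (-10.0, -10.0, 0.1, 0.01, 0.1),  # removable singularity: sy/sx
            (0.0, -10.0, 0.1, 0.01, 0.05819767068693265),  # K opening rate
            (0.0, -25.0, 0.1, 0.1, 0.22356372458463003),  # Na activation opening
        ],
    )
    def test_goldman_fit(self, x, x0, sx, sy, expected):
        assert goldman_fit(x, x0, sx, sy) == pytest.approx(expected, rel=1e-12)

    def test_goldman_fit_continuous_at_singularity(self):
        # near x0 the fit behaves as (sy/sx)·(1 - sx·(x-x0)/2 + ...), so the
        # admissible deviation shrinks linearly with the approach distance
        limit = goldman_fit(-10.0, -10.0, 0.1, 0.01)
        assert limit == 0.01 / 0.1
        for eps in (1e-6, 1e-9, 1e-12):
            for x in (-10.0 + eps, -10.0 - eps):
                assert goldman_fit(x, -10.0, 0.1, 0.01) == pytest.approx(
                    limit, rel=max(eps, 1e-12)
                )


class TestGateKinetics:
    def test_symmetric_rates_give_half(self):
        fit = ExponentialFit(sx=0.0, sy=1.0)
        assert gate_steady_state(fit, fit, -40.0) == 0.5

    @pytest.mark.parametrize(
        "fopen, fclose, expected",
        [
            (ALPHA_N, BETA_N, 0.3176769140606974),  # n∞(0)
            (ALPHA_M, BETA_M, 0.05293248525724958),  # m∞(0)
            (ALPHA_H, BETA_H, 0.5961207535084603),  # h∞(0)
        ],
    )
    def test_resting_steady_states(self, fopen, fclose, expected):
        assert gate_steady_state(fopen, fclose, 0.0) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_rates_rejected(self):
        zero = ExponentialFit(sx=0.0, sy=0.0)
        with pytest.raises(DegenerateRatesError):
            gate_steady_state(zero, zero, 0.0)

    def test_derivative_limits(self):
        v = -20.0
        n_inf = gate_steady_state(ALPHA_N, BETA_N, v)
        assert gate_derivative(n_inf, v, 1.0, ALPHA_N, BETA_N) == pytest.approx(0.0, abs=1e-15)
        assert gate_derivative(0.0, v, 2.0, ALPHA_N, BETA_N) == pytest.approx(2.0 * ALPHA_N(v))
        assert gate_derivative(1.0, v, 2.0, ALPHA_N, BETA_N) == pytest.approx(-2.0 * BETA_N(v))

    @given(
        sx_o=st.floats(-0.2, 0.2),
        sy_o=st.floats(0.001, 5.0),
        sx_c=st.floats(-0.2, 0.2),
        sy_c=st.floats(0.001, 5.0),
        v=st.floats(-110.0, 30.0),
        n0=st.floats(0.0, 1.0),
    )
    def test_gate_stays_bounded(self, sx_o, sy_o, sx_c, sy_c, v, n0):
        """Nonnegative rates confine the open fraction to [0, 1]."""
        from scipy.integrate import solve_ivp

        gate = Gate("g", ExponentialFit(sx_o, sy_o), ExponentialFit(sx_c, sy_c))
        sol = solve_ivp(
            lambda t, y: [gate.derivative(y[0], v, 6.3)],
            (0.0, 5.0),
            [n0],
            method="LSODA",
            rtol=1e-8,
            atol=1e-10,
        )
        assert sol.success
        assert sol.y.min() >= -1e-7 and sol.y.max() <= 1.0 + 1e-7

    @given(
        sx_o=st.floats(-0.2, 0.2),
        sy_o=st.floats(0.001, 5.0),
        sx_c=st.floats(-0.2, 0.2),
        sy_c=st.floats(0.001, 5.0),
    )
    def test_initialization_follows_the_fit_parameters(self, sx_o, sy_o, sx_c, sy_c):
        """Changing a fit parameter automatically moves the initial value."""
        gate = Gate("g", ExponentialFit(sx_o, sy_o), ExponentialFit(sx_c, sy_c))
        assert gate.initial() == gate_steady_state(gate.fopen, gate.fclose, 0.0)

    def test_temperature_factor(self):
        assert temperature_factor(6.3, 6.3, 3.0) == 1.0
        assert temperature_factor(16.3, 6.3, 3.0) == pytest.approx(3.0)
        assert temperature_factor(26.3, 6.3, 3.0) == pytest.approx(9.0)
        with pytest.raises(ParameterError):
            temperature_factor(6.3, 6.3, 0.0)


class TestConductances:
    @pytest.mark.parametrize("n, expected", [(1.0, 36.0), (0.5, 36.0 / 16), (0.0, 0.0)])
    def test_potassium_fourth_power(self, n, expected):
        assert potassium_conductance(n, 36.0) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "m, h, expected",
        [(1.0, 1.0, 120.0), (0.5, 1.0, 120.0 / 8), (0.9, 0.0, 0.0)],
    )
    def test_sodium_cubed_times_inactivation(self, m, h, expected):
        assert sodium_conductance(m, h, 120.0) == pytest.approx(expected)

    def test_leak_current_is_linear(self):
        leak = LeakChannel("leak", g_max=0.3, v_eq=-10.0)
        for v in (-100.0, -10.0, 0.0, 25.0):
            assert leak.branch_current(v, {}, None) == 0.3 * (v + 10.0)


class TestParameters:
    def test_leak_reversal_balances_rest(self, params):
        n0 = gate_steady_state(ALPHA_N, BETA_N, 0.0)
        m0 = gate_steady_state(ALPHA_M, BETA_M, 0.0)
        h0 = gate_steady_state(ALPHA_H, BETA_H, 0.0)
        total = (
            sodium_conductance(m0, h0, params.g_max_na) * (0.0 - params.v_eq_na)
            + potassium_conductance(n0, params.g_max_k) * (0.0 - params.v_eq_k)
            + params.g_max_leak * (0.0 - params.v_eq_leak)
        )
        assert abs(total) < 1e-12

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            HHParameters(c=0.0)
        with pytest.raises(ParameterError):
            HHParameters(g_max_na=-1.0)

    def test_round_trip_dict(self, params):
        clone = HHParameters.from_dict(params.to_dict())
        assert clone.v_eq_leak == params.v_eq_leak
        with pytest.raises(ParameterError):
            HHParameters.from_dict({"no_such_parameter": 1.0})


class TestExtensions:
    def test_p_slow_zero_reproduces_base_channel(self, params):
        base = SodiumChannel("na")
        ext = build_slow_inactivation_sodium(params, p_slow=0.0)
        rng = np.random.default_rng(3)
        for _ in range(50):
            v = rng.uniform(-110, 30)
            m, h, hs = rng.uniform(0, 1, 3)
            i_base = base.branch_current(v, {"gateAct.n": m, "gateInact.n": h}, None)
            i_ext = ext.branch_current(
                v, {"gateAct.n": m, "gateInact.n": h, "gateSlowInact.n": hs}, None
            )
            assert abs(i_ext - i_base) <= 1e-12 * max(1.0, abs(i_base))

    def test_p_slow_one_with_identical_gates_reproduces_base(self, params):
        base = SodiumChannel("na")
        ext = build_slow_inactivation_sodium(params, p_slow=1.0)
        i_base = base.branch_current(-40.0, {"gateAct.n": 0.7, "gateInact.n": 0.2}, None)
        i_ext = ext.branch_current(
            -40.0, {"gateAct.n": 0.7, "gateInact.n": 0.9, "gateSlowInact.n": 0.2}, None
        )
        assert i_ext == pytest.approx(i_base, abs=1e-12)

    def test_half_slow_mixture_arithmetic(self, params):
        ext = build_slow_inactivation_sodium(params, p_slow=0.5)
        g = ext.conductance({"gateAct.n": 1.0, "gateInact.n": 1.0, "gateSlowInact.n": 0.0})
        assert g == pytest.approx(params.g_max_na / 2.0)

    def test_p_slow_out_of_range(self, params):
        with pytest.raises(ParameterError):
            build_slow_inactivation_sodium(params, p_slow=1.5)

    def test_tau_inf_gate_identity_matches_rate_gate(self):
        def n_inf(v):
            return ALPHA_N(v) / (ALPHA_N(v) + BETA_N(v))

        def tau(v):
            return 1.0 / (ALPHA_N(v) + BETA_N(v))

        rng = np.random.default_rng(5)
        for _ in range(100):
            v = rng.uniform(-110, 30)
            n = rng.uniform(0, 1)
            d_tau = tau_inf_gate_derivative(n, v, n_inf, tau)
            d_rate = gate_derivative(n, v, 1.0, ALPHA_N, BETA_N)
            assert abs(d_tau - d_rate) <= 1e-12 * max(1.0, abs(d_rate))

    def test_tau_inf_gate_basics(self):
        gate = TauInfGate("g", n_inf_fn=lambda v: 1.0, tau_fn=lambda v: 2.0)
        assert gate.derivative(0.0, 0.0, None) == 0.5
        assert gate.derivative(1.0, 0.0, None) == 0.0
        with pytest.raises(ParameterError):
            tau_inf_gate_derivative(0.5, 0.0, lambda v: 1.0, lambda v: 0.0)


class TestModelBuilder:
    def test_ten_connect_statements(self, model):
        assert model.count_connects() == 10
        assert len(model.electrical_connections) == 8
        assert len(model.signal_connections) == 2

    def test_four_differential_states(self, flat):
        assert flat.n_states == 4

    def test_validates_cleanly(self, model):
        assert model.validate() == []

    def test_without_leak_rest_is_not_held(self, params):
        model = build_hh_model(params)
        model.components = [c for c in model.components if c.name != "leakChannel"]
        model.electrical_connections = [
            (a, b)
            for a, b in model.electrical_connections
            if "leakChannel" not in (a.owner.name, b.owner.name)
        ]
        # reconnect the chain across the gap left by the leak channel
        na, clamp = model["sodiumChannel"], model["currentClamp"]
        model.connect_electrical(na.pins["p"], clamp.pins["p"])
        model.connect_electrical(na.pins["n"], clamp.pins["n"])
        assert model.validate() == []
        sys = model.flatten()
        sys.initial_state[0] = 0.0
        t, y = integrate(sys, ExperimentConfig(duration=20.0, output_step=0.1, v_init=0.0))
        assert np.max(np.abs(y[:, 0])) > 1.0  # drifts away from rest
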