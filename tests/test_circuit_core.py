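"""Connector semantics, node partition, validation and flattening."""

import math

import numpy as np
import pytest

from hhsim.circuit_core import (
    Capacitor,
    CircuitModel,
    Conductor,
    CurrentSource,
    DeclarationError,
    Ground,
    MultipleDriverError,
    SignalDirectionError,
    TypeMismatchError,
    UnsupportedStructureError,
)
from hhsim.hh_library import LipidBilayer, build_hh_model
from hhsim.simulation import ExperimentConfig, integrate


def _ramp_circuit(v0=0.0, i=1.0):
    """Capacitor charged by a constant source; oriented so dv/dt = +i/C."""
    cap = Capacitor("cap", c=1.0, v_init=v0)
    src = CurrentSource("src", i_const=i)
    gnd = Ground("gnd")
    m = CircuitModel("ramp", [cap, src, gnd])
    m.connect_electrical(cap.pins["p"], src.pins["n"])
    m.connect_electrical(cap.pins["p"], gnd.pins["pin"])
    m.connect_electrical(cap.pins["n"], src.pins["p"])
    return m


def _rc_circuit(c=1.0, g=0.5, v0=10.0, v_eq=0.0):
    cap = Capacitor("cap", c=c, v_init=v0)
    res = Conductor("res", g=g, v_eq=v_eq)
    gnd = Ground("gnd")
    m = CircuitModel("rc", [cap, res, gnd])
    m.connect_electrical(cap.pins["p"], res.pins["p"])
    m.connect_electrical(cap.pins["p"], gnd.pins["pin"])
    m.connect_electrical(cap.pins["n"], res.pins["n"])
    return m


class TestConnections:
    def test_connected_pins_share_a_node(self):
        m = _rc_circuit()
        nodes = m.partition_nodes()
        cap_p = m["cap"].pins["p"]
        res_p = m["res"].pins["p"]
        node = next(n for n in nodes if cap_p in n)
        assert res_p in node

    def test_self_connection_is_idempotent(self):
        cap = Capacitor("cap", c=1.0)
        m = CircuitModel("loop", [cap])
        m.connect_electrical(cap.pins["p"], cap.pins["p"])
        nodes = m.partition_nodes()
        assert sorted(len(n.pins) for n in nodes) == [1, 1]

    def test_transitive_merge(self):
        caps = [Capacitor(f"c{i}", c=1.0) for i in range(2)]
        m = CircuitModel("chain", caps)
        a, b = caps[0].pins["p"], caps[0].pins["n"]
        c, d = caps[1].pins["p"], caps[1].pins["n"]
        m.connect_electrical(a, b)
        m.connect_electrical(c, d)
        m.connect_electrical(b, c)
        nodes = m.partition_nodes()
        assert len(nodes) == 1 and len(nodes[0].pins) == 4

    def test_no_connections_gives_singletons(self):
        m = CircuitModel("iso", [Conductor("r1", 1.0), Conductor("r2", 1.0)])
        assert [len(n.pins) for n in m.partition_nodes()] == [1, 1, 1, 1]

    def test_unknown_pin_rejected(self):
        m = CircuitModel("m", [Conductor("r", 1.0)])
        stray = Conductor("other", 1.0)
        with pytest.raises(DeclarationError):
            m.connect_electrical(m["r"].pins["p"], stray.pins["p"])

    def test_pin_port_type_mismatch(self):
        bilayer = LipidBilayer("b")
        m = CircuitModel("m", [bilayer])
        with pytest.raises(TypeMismatchError):
            m.connect_electrical(bilayer.pins["p"], bilayer.ports["temp"])

    def test_count_connects(self):
        assert CircuitModel("empty").count_connects() == 0
        m = CircuitModel("m", [Conductor("a", 1.0), Conductor("b", 1.0)])
        m.connect_electrical(m["a"].pins["p"], m["b"].pins["p"])
        assert m.count_connects() == 1


class TestSignals:
    def test_fanout_accepted_and_resolved(self):
        model = build_hh_model()
        sys = model.flatten()  # two inputs driven by one output
        assert sys.n_states == 4

    def test_direction_error(self):
        model = build_hh_model()
        k, na = model["potassiumChannel"], model["sodiumChannel"]
        with pytest.raises(SignalDirectionError):
            model.connect_signal(k.ports["temp"], na.ports["temp"])

    def test_multiple_driver_error(self):
        model = build_hh_model()
        bilayer, k = model["lipidBilayer"], model["potassiumChannel"]
        with pytest.raises(MultipleDriverError):
            model.connect_signal(bilayer.ports["temp"], k.ports["temp"])


class TestValidate:
    def test_full_model_is_clean(self):
        assert build_hh_model().validate() == []

    def test_unbound_temperature_input_reported(self):
        model = build_hh_model()
        model.signal_connections = [
            (o, i) for o, i in model.signal_connections
            if i.owner.name != "sodiumChannel"
        ]
        issues = model.validate()
        assert any("unbound temperature input" in s for s in issues)

    def test_missing_ground_reported(self):
        m = _rc_circuit()
        m.components = [c for c in m.components if c.name != "gnd"]
        assert any("no ground" in s for s in m.validate())

    def test_partial_instantiation_reported(self):
        from hhsim.hh_library import IonChannel

        chan = IonChannel("raw", g_max=1.0, v_eq=0.0)
        m = CircuitModel("m", [chan])
        assert any("partial" in s for s in m.validate())

    def test_flatten_refuses_invalid_model(self):
        m = _rc_circuit()
        m.components = [c for c in m.components if c.name != "gnd"]
        with pytest.raises(DeclarationError):
            m.flatten()


class TestFlatten:
    def test_constant_current_ramp_matches_analytic(self):
        sys = _ramp_circuit(v0=2.0, i=1.0).flatten()
        t, y = integrate(
            sys, ExperimentConfig(duration=10.0, output_step=0.1, rtol=1e-10, atol=1e-12)
        )
        assert np.max(np.abs(y[:, 0] - (2.0 + t))) < 1e-8

    def test_rc_decay_matches_analytic(self):
        c, g, v0, v_eq = 1.0, 0.5, 10.0, 0.0
        sys = _rc_circuit(c, g, v0, v_eq).flatten()
        t, y = integrate(
            sys, ExperimentConfig(duration=10.0, output_step=0.1, rtol=1e-10, atol=1e-12)
        )
        expected = v_eq + (v0 - v_eq) * np.exp(-g * t / c)
        assert np.max(np.abs(y[:, 0] - expected)) < 1e-8

    def test_hh_model_states(self, flat):
        assert flat.state_names == [
            "lipidBilayer.v",
            "potassiumChannel.gateN.n",
            "sodiumChannel.gateAct.n",
            "sodiumChannel.gateInact.n",
        ]

    def test_hh_model_two_nodes_with_ground(self, model):
        nodes = model.partition_nodes()
        assert len(nodes) == 2
        assert sorted(len(n.pins) for n in nodes) == [6, 7]
        assert sum(n.is_ground for n in nodes) == 1
        ground = next(n for n in nodes if n.is_ground)
        # the grounded (extracellular) node holds every positive pin
        assert all(p.polarity == "positive" for p in ground.pins)

    def test_flatten_is_deterministic(self, model):
        s1, s2 = model.flatten(), model.flatten()
        assert s1.state_names == s2.state_names
        assert np.array_equal(s1.initial_state, s2.initial_state)
        rng = np.random.default_rng(7)
        for _ in range(5):
            y = rng.uniform([-110, 0, 0, 0], [30, 1, 1, 1])
            assert np.array_equal(s1.rhs(0.0, y), s2.rhs(0.0, y))

    def test_node_current_law_holds(self, flat):
        rng = np.random.default_rng(11)
        for _ in range(20):
            y = rng.uniform([-110, 0, 0, 0], [30, 1, 1, 1])
            obs = flat.observables(0.0, y)
            scale = sum(
                abs(v) for k, v in obs.items() if k.endswith(".i")
            ) + 1.0
            for label, residual in flat.node_residuals(0.0, y).items():
                assert abs(residual) < 1e-12 * scale, label

    def test_pins_of_one_node_share_potential(self, flat):
        y = flat.initial_state
        obs = flat.observables(0.0, y)
        # branch voltages all alias the same pair of node potentials
        assert obs["potassiumChannel.v"] == obs["sodiumChannel.v"] == obs["leakChannel.v"]
        assert obs["currentClamp.v"] == obs["lipidBilayer.v"]

    def test_series_algebraic_chain_unsupported(self):
        cap = Capacitor("cap", c=1.0, v_init=1.0)
        r1 = Conductor("r1", 1.0)
        r2 = Conductor("r2", 1.0)
        gnd = Ground("gnd")
        m = CircuitModel("series", [cap, r1, r2, gnd])
        m.connect_electrical(cap.pins["p"], gnd.pins["pin"])
        m.connect_electrical(cap.pins["n"], r1.pins["p"])
        m.connect_electrical(r1.pins["n"], r2.pins["p"])
        m.connect_electrical(r2.pins["n"], cap.pins["p"])
        with pytest.raises(UnsupportedStructureError):
            m.flatten()
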