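"""Hodgkin-Huxley component library: fits, gates, channels, bilayer, clamp.

All quantities follow the 1952 displacement convention of the squid-axon
model: the membrane voltage ``v`` is the displacement from rest (0 mV at
rest, *negative* during depolarization), time is in ms, currents in µA/cm²,
conductances in mS/cm², capacitance in µF/cm² and rates in 1/ms.  The
measured membrane potential is recovered as ``V_m = E_r - v`` with a resting
potential ``E_r`` of -75 mV (see :mod:`hhsim.simulation`).

The voltage dependence of the gating rates is expressed through three small
reusable fitting functions (exponential, logistic and the "goldman" linoid
form with its removable singularity).  Each :class:`Gate` stores its
open/close rate functions as first-class values, so its steady-state
initialization is derived from the same objects that drive its kinetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Callable, Mapping, Sequence

from .circuit_core import (
    CircuitModel,
    Component,
    GateSpec,
    Ground,
    Pin,
)

__all__ = [
    "ParameterError",
    "DegenerateRatesError",
    "FitFunction",
    "ExponentialFit",
    "LogisticFit",
    "GoldmanFit",
    "exp_fit",
    "logistic_fit",
    "goldman_fit",
    "gate_steady_state",
    "gate_derivative",
    "tau_inf_gate_derivative",
    "temperature_factor",
    "potassium_conductance",
    "sodium_conductance",
    "ALPHA_N",
    "BETA_N",
    "ALPHA_M",
    "BETA_M",
    "ALPHA_H",
    "BETA_H",
    "HHParameters",
    "rest_balancing_leak_reversal",
    "TwoPinComponent",
    "LipidBilayer",
    "Gate",
    "TauInfGate",
    "IonChannel",
    "GatedIonChannel",
    "LeakChannel",
    "PotassiumChannel",
    "SodiumChannel",
    "SlowInactivationSodiumChannel",
    "ConstantCurrent",
    "CurrentClamp",
    "build_hh_model",
    "build_slow_inactivation_sodium",
]


class ParameterError(ValueError):
    """A physical parameter is outside its admissible range."""


class DegenerateRatesError(ValueError):
    """Opening and closing rates are both zero; the steady state is undefined."""


# --------------------------------------------------------------------------
# fitting functions
# --------------------------------------------------------------------------


def exp_fit(x: float, sx: float, sy: float) -> float:
    """Exponential rate fit ``sy * exp(sx * x)`` (x in mV, result in 1/ms)."""
    return sy * math.exp(sx * x)


def logistic_fit(x: float, x0: float, sx: float, sy: float) -> float:
    """Logistic rate fit ``sy / (1 + exp(sx * (x - x0)))``."""
    return sy / (1.0 + math.exp(sx * (x - x0)))


def goldman_fit(x: float, x0: float, sx: float, sy: float) -> float:
    """Linoid rate fit ``sy * (x - x0) / (exp(sx * (x - x0)) - 1)``.

    The removable singularity at ``x == x0`` is evaluated as its analytic
    limit ``sy / sx``; near the singularity ``expm1`` keeps the quotient
    accurate to machine precision.
    """
    u = x - x0
    t = sx * u
    if t == 0.0:
        return sy / sx
    return sy * u / math.expm1(t)


@dataclass(frozen=True)
class FitFunction:
    """Base class for the stored, replaceable rate-fit functions."""

    sx: float
    sy: float

    @property
    def kind(self) -> str:
        return type(self).__name__

    def __call__(self, x: float) -> float:  # pragma: no cover - overridden
        raise NotImplementedError


@dataclass(frozen=True)
class ExponentialFit(FitFunction):
    def __call__(self, x: float) -> float:
        return exp_fit(x, self.sx, self.sy)


@dataclass(frozen=True)
class LogisticFit(FitFunction):
    x0: float = 0.0

    def __call__(self, x: float) -> float:
        return logistic_fit(x, self.x0, self.sx, self.sy)


@dataclass(frozen=True)
class GoldmanFit(FitFunction):
    x0: float = 0.0

    def __call__(self, x: float) -> float:
        return goldman_fit(x, self.x0, self.sx, self.sy)


#: Classic squid-axon gating rates (displacement convention, 1/ms, mV).
ALPHA_N = GoldmanFit(sx=0.1, sy=0.01, x0=-10.0)
BETA_N = ExponentialFit(sx=1.0 / 80.0, sy=0.125)
ALPHA_M = GoldmanFit(sx=0.1, sy=0.1, x0=-25.0)
BETA_M = ExponentialFit(sx=1.0 / 18.0, sy=4.0)
ALPHA_H = ExponentialFit(sx=1.0 / 20.0, sy=0.07)
BETA_H = LogisticFit(sx=0.1, sy=1.0, x0=-30.0)


# --------------------------------------------------------------------------
# gating kinetics primitives
# --------------------------------------------------------------------------


def gate_steady_state(
    fopen: Callable[[float], float], fclose: Callable[[float], float], v: float
) -> float:
    """Open fraction reached by holding the voltage at ``v``: α/(α+β)."""
    a, b = fopen(v), fclose(v)
    if a + b <= 0.0:
        raise DegenerateRatesError(f"total rate {a + b} at v={v} mV")
    return a / (a + b)


def gate_derivative(
    n: float,
    v: float,
    phi: float,
    fopen: Callable[[float], float],
    fclose: Callable[[float], float],
) -> float:
    """First-order gating kinetics: φ·(α(v)·(1-n) - β(v)·n), in 1/ms."""
    return phi * (fopen(v) * (1.0 - n) - fclose(v) * n)


def tau_inf_gate_derivative(
    n: float,
    v: float,
    n_inf_fn: Callable[[float], float],
    tau_fn: Callable[[float], float],
) -> float:
    """Relaxation form of the gating kinetics: (n∞(v) - n)/τ(v)."""
    tau = tau_fn(v)
    if tau <= 0.0:
        raise ParameterError(f"nonpositive time constant τ={tau} at v={v} mV")
    return (n_inf_fn(v) - n) / tau


def temperature_factor(temp: float, t_ref: float, q10: float) -> float:
    """Rate acceleration φ = q10^((T - T_ref)/10) for warmer membranes."""
    if q10 <= 0.0:
        raise ParameterError(f"q10 must be positive, got {q10}")
    return q10 ** ((temp - t_ref) / 10.0)


def potassium_conductance(n: float, g_max: float) -> float:
    """Delayed-rectifier conductance g_max·n⁴ (four cooperative subunits)."""
    return g_max * n**4


def sodium_conductance(m: float, h: float, g_max: float) -> float:
    """Sodium conductance g_max·m³·h (three activation subunits, one lid)."""
    return g_max * m**3 * h


#: Q10 and reference temperature of the classic rate fits; treated as fixed
#: properties of the 1952 parameterization rather than per-gate parameters.
Q10_DEFAULT = 3.0
T_REF_DEFAULT = 6.3


# --------------------------------------------------------------------------
# parameter set
# --------------------------------------------------------------------------


def rest_balancing_leak_reversal(
    g_max_na: float,
    g_max_k: float,
    g_max_leak: float,
    v_eq_na: float,
    v_eq_k: float,
    alpha_n: Callable[[float], float] = ALPHA_N,
    beta_n: Callable[[float], float] = BETA_N,
    alpha_m: Callable[[float], float] = ALPHA_M,
    beta_m: Callable[[float], float] = BETA_M,
    alpha_h: Callable[[float], float] = ALPHA_H,
    beta_h: Callable[[float], float] = BETA_H,
) -> float:
    """Leak reversal (mV) that makes v = 0 an exact resting equilibrium.

    With the gates at their v = 0 steady states the total ionic current
    must vanish; solving ``Σ g_i (0 - v_eq,i) = 0`` for the leak reversal
    gives the value below (≈ -10.599 mV; the commonly printed -10.613 mV is
    a historical rounding that leaves a residual current of ~4e-3 µA/cm²).
    """
    n0 = gate_steady_state(alpha_n, beta_n, 0.0)
    m0 = gate_steady_state(alpha_m, beta_m, 0.0)
    h0 = gate_steady_state(alpha_h, beta_h, 0.0)
    i_fixed = sodium_conductance(m0, h0, g_max_na) * v_eq_na + potassium_conductance(
        n0, g_max_k
    ) * v_eq_k
    return -i_fixed / g_max_leak


@dataclass
class HHParameters:
    """Full parameter set of the squid-axon model (displacement convention).

    The leak reversal defaults to the value that balances the resting state
    exactly (see :func:`rest_balancing_leak_reversal`).  The six rate-fit
    functions are stored as replaceable values so alternative kinetics can
    be dropped in without touching any initialization code.
    """

    c: float = 1.0  # µF/cm²
    g_max_na: float = 120.0  # mS/cm²
    g_max_k: float = 36.0
    g_max_leak: float = 0.3
    v_eq_na: float = -115.0  # mV, displacement convention
    v_eq_k: float = 12.0
    v_eq_leak: float | None = None  # None → computed rest balance
    temperature: float = 6.3  # °C
    t_ref: float = T_REF_DEFAULT
    q10: float = Q10_DEFAULT
    e_rest: float = -75.0  # mV, measured resting potential for V_m = E_r - v
    v_init: float = -15.0  # mV, initial displacement (15 mV depolarization)
    i_const: float = 0.0  # µA/cm², clamp current (positive outward)
    alpha_n: FitFunction = ALPHA_N
    beta_n: FitFunction = BETA_N
    alpha_m: FitFunction = ALPHA_M
    beta_m: FitFunction = BETA_M
    alpha_h: FitFunction = ALPHA_H
    beta_h: FitFunction = BETA_H

    def __post_init__(self) -> None:
        if self.c <= 0.0:
            raise ParameterError(f"capacitance must be positive, got {self.c}")
        for name in ("g_max_na", "g_max_k", "g_max_leak"):
            if getattr(self, name) <= 0.0:
                raise ParameterError(f"{name} must be positive, got {getattr(self, name)}")
        if self.q10 <= 0.0:
            raise ParameterError(f"q10 must be positive, got {self.q10}")
        if self.v_eq_leak is None:
            self.v_eq_leak = rest_balancing_leak_reversal(
                self.g_max_na,
                self.g_max_k,
                self.g_max_leak,
                self.v_eq_na,
                self.v_eq_k,
                self.alpha_n,
                self.beta_n,
                self.alpha_m,
                self.beta_m,
                self.alpha_h,
                self.beta_h,
            )

    def phi(self) -> float:
        """Temperature acceleration factor at the configured temperature."""
        return temperature_factor(self.temperature, self.t_ref, self.q10)

    def evolve(self, **changes) -> "HHParameters":
        """Copy with scalar fields replaced (leak re-balanced if requested)."""
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if isinstance(getattr(self, f.name), (int, float))
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "HHParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**dict(data))


# --------------------------------------------------------------------------
# component hierarchy
# --------------------------------------------------------------------------


class TwoPinComponent(Component):
    """Abstract element with an extracellular (p) and intracellular (n) pin.

    Declares the through-quantities ``v = p.v - n.v`` (the displacement
    voltage across the element) and ``i`` (the current flowing through it
    from the negative to the positive pin, i.e. positive outward), plus the
    pin-level current balance.  Partial: subclasses must add the relation
    between ``v`` and ``i``.
    """

    partial = True

    def _declare_local(self) -> None:
        self.declare_pin("p", "positive", doc="extracellular pin")
        self.declare_pin("n", "negative", doc="intracellular pin")
        self.declare_variable("v", "mV", "voltage across the component (p - n)")
        self.declare_variable("i", "µA/cm²", "through-current (n → p, positive outward)")
        self.declare_equation(
            "pin_current_balance", "algebraic", "0 = p.i + n.i (Kirchhoff at the element)"
        )
        self.declare_equation("voltage_alias", "alias", "v = p.v - n.v")
        self.declare_equation("current_alias", "alias", "i = n.i")


class Gate(Component):
    """Voltage-dependent gating subunit of an ion channel.

    ``n`` is the fraction of gating molecules in open conformation; it
    relaxes with first-order kinetics between the voltage-dependent rates
    ``fopen`` (closed→open) and ``fclose`` (open→closed), accelerated by the
    Q10 temperature factor.  The initial value is the steady state at the
    holding potential v = 0 mV, derived from the same stored rate functions.
    """

    def __init__(
        self,
        name: str,
        fopen: Callable[[float], float],
        fclose: Callable[[float], float],
        q10: float = Q10_DEFAULT,
        t_ref: float = T_REF_DEFAULT,
        doc: str = "",
    ):
        self.fopen = fopen
        self.fclose = fclose
        self.q10 = q10
        self.t_ref = t_ref
        super().__init__(name, doc or "voltage-dependent gate")

    def _declare_local(self) -> None:
        self.declare_variable("n", "1", "open fraction of gating molecules")
        self.declare_variable("fopen", "1/ms", "replaceable closed→open rate function")
        self.declare_variable("fclose", "1/ms", "replaceable open→closed rate function")
        self.declare_variable("v", "mV", "input displacement voltage")
        self.declare_port("temp", "input", doc="membrane temperature")
        self.declare_equation(
            "kinetics",
            "differential",
            "der(n) = φ(temp)·(fopen(v)·(1-n) - fclose(v)·n)",
        )

    def steady_state(self, v: float) -> float:
        return gate_steady_state(self.fopen, self.fclose, v)

    def initial(self) -> float:
        return self.steady_state(0.0)

    def derivative(self, n: float, v: float, temp: float | None) -> float:
        phi = 1.0 if temp is None else temperature_factor(temp, self.t_ref, self.q10)
        return gate_derivative(n, v, phi, self.fopen, self.fclose)


class TauInfGate(Component):
    """Gate parameterized by steady state n∞(v) and time constant τ(v).

    Alternative to the rate form: der(n) = (n∞(v) - n)/τ(v).  With
    n∞ = α/(α+β) and τ = 1/(α+β) it is algebraically identical to
    :class:`Gate` at reference temperature; temperature scaling, if wanted,
    is folded into the τ fit.
    """

    def __init__(
        self,
        name: str,
        n_inf_fn: Callable[[float], float],
        tau_fn: Callable[[float], float],
        doc: str = "",
    ):
        self.n_inf_fn = n_inf_fn
        self.tau_fn = tau_fn
        super().__init__(name, doc or "steady-state/time-constant gate")

    def _declare_local(self) -> None:
        self.declare_variable("n", "1", "open fraction of gating molecules")
        self.declare_variable("n_inf", "1", "replaceable steady-state function")
        self.declare_variable("tau", "ms", "replaceable time-constant function")
        self.declare_variable("v", "mV", "input displacement voltage")
        self.declare_port("temp", "input", doc="membrane temperature (absorbed in τ)")
        self.declare_equation("kinetics", "differential", "der(n) = (n∞(v) - n)/τ(v)")

    def steady_state(self, v: float) -> float:
        return self.n_inf_fn(v)

    def initial(self) -> float:
        return self.n_inf_fn(0.0)

    def derivative(self, n: float, v: float, temp: float | None) -> float:
        return tau_inf_gate_derivative(n, v, self.n_inf_fn, self.tau_fn)


class LipidBilayer(TwoPinComponent):
    """Membrane capacitance separating the intra- and extracellular charge.

    Acts as a capacitor: der(v) = i/c (ms/mV units, so no unit prefactor is
    needed).  At t = 0 the displacement voltage equals ``v_init``, emulating
    a short initial stimulation from the holding potential.  The membrane
    temperature parameter is propagated through the ``temp`` output port.
    """

    partial = False

    def __init__(self, name: str, c: float = 1.0, v_init: float = 0.0, temp_m: float = 6.3):
        self.c = float(c)
        self.v_init = float(v_init)
        self.temp_m = float(temp_m)
        super().__init__(name, doc="lipid bilayer (membrane capacitance)")

    def _declare_local(self) -> None:
        self.declare_parameter("c", self.c, "µF/cm²", "membrane capacitance")
        self.declare_parameter("v_init", self.v_init, "mV", "initial displacement voltage")
        self.declare_parameter("temp_m", self.temp_m, "°C", "membrane temperature")
        self.declare_port(
            "temp", "output", value_fn=lambda: self.temp_m, doc="temperature source"
        )
        self.declare_equation("capacitor_law", "differential", "der(v) = i/c")
        self.declare_equation("temperature_source", "algebraic", "temp = temp_m")

    @property
    def element_kind(self) -> str:
        return "capacitive"

    def capacitance(self) -> float:
        return self.c

    def initial_voltage(self) -> float:
        return self.v_init


class IonChannel(TwoPinComponent):
    """Abstract channel: conductor relative to its ionic reversal potential.

    Adds the conductance variable ``g`` and the current law
    ``i = g·(v - v_eq)``; subclasses define how ``g`` arises.
    """

    partial = True

    def __init__(self, name: str, g_max: float, v_eq: float, doc: str = ""):
        if g_max <= 0.0:
            raise ParameterError(f"g_max must be positive, got {g_max}")
        self.g_max = float(g_max)
        self.v_eq = float(v_eq)
        super().__init__(name, doc)

    def _declare_local(self) -> None:
        self.declare_variable("g", "mS/cm²", "instantaneous channel conductance")
        self.declare_parameter("g_max", self.g_max, "mS/cm²", "maximum conductance")
        self.declare_parameter("v_eq", self.v_eq, "mV", "equilibrium (reversal) potential")
        self.declare_equation("channel_law", "algebraic", "i = g·(v - v_eq)")

    @property
    def element_kind(self) -> str:
        return "branch"

    def branch_current(self, v: float, states: Mapping[str, float], temp: float | None) -> float:
        g = self.conductance(states)
        assert g is not None
        return g * (v - self.v_eq)


class GatedIonChannel(IonChannel):
    """Abstract ion channel whose gates need the membrane temperature."""

    partial = True

    def _declare_local(self) -> None:
        self.declare_port("temp", "input", doc="membrane temperature for the gating rates")


class LeakChannel(IonChannel):
    """Always-open channel maintaining the resting potential: g = g_max."""

    partial = False

    def __init__(self, name: str, g_max: float = 0.3, v_eq: float | None = None):
        if v_eq is None:
            v_eq = rest_balancing_leak_reversal(120.0, 36.0, g_max, -115.0, 12.0)
        super().__init__(name, g_max, v_eq, doc="leak channel (always open)")

    def _declare_local(self) -> None:
        self.declare_equation("open_pore", "algebraic", "g = g_max")

    def conductance(self, states: Mapping[str, float]) -> float:
        return self.g_max


class PotassiumChannel(GatedIonChannel):
    """Delayed-rectifier K⁺ channel: g = g_max·n⁴ with one activation gate."""

    partial = False

    def __init__(
        self,
        name: str,
        g_max: float = 36.0,
        v_eq: float = 12.0,
        alpha_n: Callable[[float], float] = ALPHA_N,
        beta_n: Callable[[float], float] = BETA_N,
        q10: float = Q10_DEFAULT,
        t_ref: float = T_REF_DEFAULT,
    ):
        self._gate_args = (alpha_n, beta_n, q10, t_ref)
        super().__init__(name, g_max, v_eq, doc="delayed-rectifier potassium channel")

    def _declare_local(self) -> None:
        alpha_n, beta_n, q10, t_ref = self._gate_args
        gate = Gate("gateN", alpha_n, beta_n, q10, t_ref, doc="K⁺ activation gate")
        self.declare_subcomponent("gateN", gate)
        self.bind_internal(self.ports["temp"], gate.ports["temp"])
        self.declare_equation("conductance_law", "algebraic", "g = g_max·n⁴")

    def gate_specs(self) -> Sequence[GateSpec]:
        gate = self.subcomponents["gateN"]
        return (
            GateSpec("gateN.n", "1", gate.initial, gate.derivative),
        )

    def conductance(self, states: Mapping[str, float]) -> float:
        return potassium_conductance(states["gateN.n"], self.g_max)


class SodiumChannel(GatedIonChannel):
    """Na⁺ channel: g = g_max·m³·h with activation and inactivation gates."""

    partial = False

    def __init__(
        self,
        name: str,
        g_max: float = 120.0,
        v_eq: float = -115.0,
        alpha_m: Callable[[float], float] = ALPHA_M,
        beta_m: Callable[[float], float] = BETA_M,
        alpha_h: Callable[[float], float] = ALPHA_H,
        beta_h: Callable[[float], float] = BETA_H,
        q10: float = Q10_DEFAULT,
        t_ref: float = T_REF_DEFAULT,
    ):
        self._gate_args = (alpha_m, beta_m, alpha_h, beta_h, q10, t_ref)
        super().__init__(name, g_max, v_eq, doc="fast sodium channel")

    def _declare_local(self) -> None:
        alpha_m, beta_m, alpha_h, beta_h, q10, t_ref = self._gate_args
        act = Gate("gateAct", alpha_m, beta_m, q10, t_ref, doc="Na⁺ activation gate (m)")
        inact = Gate("gateInact", alpha_h, beta_h, q10, t_ref, doc="Na⁺ inactivation gate (h)")
        self.declare_subcomponent("gateAct", act)
        self.declare_subcomponent("gateInact", inact)
        self.bind_internal(self.ports["temp"], act.ports["temp"])
        self.bind_internal(self.ports["temp"], inact.ports["temp"])
        self.declare_equation("conductance_law", "algebraic", "g = g_max·m³·h")

    def gate_specs(self) -> Sequence[GateSpec]:
        act = self.subcomponents["gateAct"]
        inact = self.subcomponents["gateInact"]
        return (
            GateSpec("gateAct.n", "1", act.initial, act.derivative),
            GateSpec("gateInact.n", "1", inact.initial, inact.derivative),
        )

    def conductance(self, states: Mapping[str, float]) -> float:
        return sodium_conductance(states["gateAct.n"], states["gateInact.n"], self.g_max)


class SlowInactivationSodiumChannel(GatedIonChannel):
    """Na⁺ channel with an additional slow inactivation gate.

    A fraction ``p_slow`` of the current is governed by the slow gate:
    g = g_max·m³·((1 - p_slow)·h_fast + p_slow·h_slow).  With p_slow = 0 the
    channel is identical to :class:`SodiumChannel` for any trajectory.
    """

    partial = False

    def __init__(
        self,
        name: str,
        p_slow: float,
        slow_gate: Gate | TauInfGate | None = None,
        g_max: float = 120.0,
        v_eq: float = -115.0,
        alpha_m: Callable[[float], float] = ALPHA_M,
        beta_m: Callable[[float], float] = BETA_M,
        alpha_h: Callable[[float], float] = ALPHA_H,
        beta_h: Callable[[float], float] = BETA_H,
        q10: float = Q10_DEFAULT,
        t_ref: float = T_REF_DEFAULT,
    ):
        if not 0.0 <= p_slow <= 1.0:
            raise ParameterError(f"p_slow must lie in [0, 1], got {p_slow}")
        self.p_slow = float(p_slow)
        if slow_gate is None:
            # placeholder kinetics reusing the fast-inactivation fits; real
            # slow inactivation would use fits on a seconds time scale
            slow_gate = Gate("gateSlowInact", alpha_h, beta_h, q10, t_ref,
                             doc="Na⁺ slow inactivation gate")
        self._gate_args = (alpha_m, beta_m, alpha_h, beta_h, q10, t_ref, slow_gate)
        super().__init__(name, g_max, v_eq, doc="sodium channel with slow inactivation")

    def _declare_local(self) -> None:
        alpha_m, beta_m, alpha_h, beta_h, q10, t_ref, slow = self._gate_args
        act = Gate("gateAct", alpha_m, beta_m, q10, t_ref, doc="Na⁺ activation gate (m)")
        inact = Gate("gateInact", alpha_h, beta_h, q10, t_ref, doc="Na⁺ fast inactivation gate (h)")
        self.declare_subcomponent("gateAct", act)
        self.declare_subcomponent("gateInact", inact)
        self.declare_subcomponent("gateSlowInact", slow)
        self.declare_parameter("p_slow", self.p_slow, "1", "slow-inactivation current fraction")
        for gate in (act, inact, slow):
            self.bind_internal(self.ports["temp"], gate.ports["temp"])
        self.declare_equation(
            "conductance_law",
            "algebraic",
            "g = g_max·m³·((1 - p_slow)·h_fast + p_slow·h_slow)",
        )

    def gate_specs(self) -> Sequence[GateSpec]:
        act = self.subcomponents["gateAct"]
        inact = self.subcomponents["gateInact"]
        slow = self.subcomponents["gateSlowInact"]
        return (
            GateSpec("gateAct.n", "1", act.initial, act.derivative),
            GateSpec("gateInact.n", "1", inact.initial, inact.derivative),
            GateSpec("gateSlowInact.n", "1", slow.initial, slow.derivative),
        )

    def conductance(self, states: Mapping[str, float]) -> float:
        h_mix = (1.0 - self.p_slow) * states["gateInact.n"] + self.p_slow * states[
            "gateSlowInact.n"
        ]
        return sodium_conductance(states["gateAct.n"], h_mix, self.g_max)


class ConstantCurrent(TwoPinComponent):
    """Constant-current element of the clamp: i = i_const (positive outward)."""

    partial = False

    def __init__(self, name: str, i_const: float = 0.0):
        self.i_const = float(i_const)
        super().__init__(name, doc="constant current source")

    def _declare_local(self) -> None:
        self.declare_parameter("i_const", self.i_const, "µA/cm²", "clamp current")
        self.declare_equation("source_law", "algebraic", "i = i_const")

    @property
    def element_kind(self) -> str:
        return "branch"

    def branch_current(self, v: float, states: Mapping[str, float], temp: float | None) -> float:
        return self.i_const


class CurrentClamp(Component):
    """Current clamp: grounded extracellular electrode plus constant source.

    Holds the transmembrane current constant while the variable ``v``
    records the voltage that the experimenter would read between the two
    electrodes.  Composed of a :class:`~hhsim.circuit_core.Ground` on the
    extracellular pin and a :class:`ConstantCurrent` spanning the membrane.
    """

    def __init__(self, name: str, i_const: float = 0.0):
        self._i_const = float(i_const)
        super().__init__(name, doc="current clamp")

    def _declare_local(self) -> None:
        self.declare_pin("p", "positive", doc="extracellular electrode")
        self.declare_pin("n", "negative", doc="intracellular electrode")
        self.declare_variable("v", "mV", "measured voltage between the electrodes")
        ground = self.declare_subcomponent("ground", Ground("ground"))
        source = self.declare_subcomponent("source", ConstantCurrent("source", self._i_const))
        self.connect_internal(self.pins["p"], ground.pins["pin"])
        self.connect_internal(self.pins["p"], source.pins["p"])
        self.connect_internal(self.pins["n"], source.pins["n"])
        self.declare_equation("measured_voltage", "alias", "v = p.v - n.v")

    @property
    def i_const(self) -> float:
        return self.subcomponents["source"].i_const


# --------------------------------------------------------------------------
# model builders
# --------------------------------------------------------------------------


def build_hh_model(params: HHParameters | None = None) -> CircuitModel:
    """Assemble the five-component modular squid-axon model.

    Components are placed side by side and wired with four positive-pin
    links, four negative-pin links and two temperature bindings (ten connect
    statements in total); the returned model validates cleanly.
    """
    p = params or HHParameters()
    bilayer = LipidBilayer("lipidBilayer", c=p.c, v_init=p.v_init, temp_m=p.temperature)
    potassium = PotassiumChannel(
        "potassiumChannel", p.g_max_k, p.v_eq_k, p.alpha_n, p.beta_n, p.q10, p.t_ref
    )
    sodium = SodiumChannel(
        "sodiumChannel",
        p.g_max_na,
        p.v_eq_na,
        p.alpha_m,
        p.beta_m,
        p.alpha_h,
        p.beta_h,
        p.q10,
        p.t_ref,
    )
    assert p.v_eq_leak is not None
    leak = LeakChannel("leakChannel", p.g_max_leak, p.v_eq_leak)
    clamp = CurrentClamp("currentClamp", p.i_const)

    model = CircuitModel("HHmodular", [bilayer, potassium, sodium, leak, clamp])
    chain = [bilayer, potassium, sodium, leak, clamp]
    for left, right in zip(chain, chain[1:]):
        model.connect_electrical(left.pins["p"], right.pins["p"])
    for left, right in zip(chain, chain[1:]):
        model.connect_electrical(left.pins["n"], right.pins["n"])
    model.connect_signal(bilayer.ports["temp"], potassium.ports["temp"])
    model.connect_signal(bilayer.ports["temp"], sodium.ports["temp"])
    return model


def build_slow_inactivation_sodium(
    params: HHParameters | None = None,
    p_slow: float = 0.0,
    slow_gate: Gate | TauInfGate | None = None,
    name: str = "sodiumChannel",
) -> SlowInactivationSodiumChannel:
    """Sodium channel extended with a slow inactivation gate (fraction p_slow)."""
    p = params or HHParameters()
    return SlowInactivationSodiumChannel(
        name,
        p_slow,
        slow_gate,
        p.g_max_na,
        p.v_eq_na,
        p.alpha_m,
        p.beta_m,
        p.alpha_h,
        p.beta_h,
        p.q10,
        p.t_ref,
    )
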