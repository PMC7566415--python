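"""Flat (monolithic) squid-axon equation system, used as an oracle.

This module is a deliberately literal transcription of the classic
conductance-based membrane equations in the displacement convention
(V = 0 at rest, negative during depolarization, time in ms):

    C dV/dt = -(i_Na + i_K + i_L + I_app)
    i_Na = g_Na·m³·h·(V - V_Na)      i_K = g_K·n⁴·(V - V_K)
    i_L  = g_L·(V - V_L)
    dx/dt = φ·(α_x(V)·(1 - x) - β_x(V)·x)   for x in {n, m, h}
    φ = q10^((T - T_ref)/10)

    α_n = 0.01 (V+10) / (e^{(V+10)/10} - 1)     β_n = 0.125 e^{V/80}
    α_m = 0.1 (V+25) / (e^{(V+25)/10} - 1)      β_m = 4 e^{V/18}
    α_h = 0.07 e^{V/20}                          β_h = 1 / (e^{(V+30)/10} + 1)

It intentionally shares no evaluation code with the component library, so
that agreement between the flattened modular model and this system is a
genuine cross-check rather than a tautology.  The parameter container
(:class:`~hhsim.hh_library.HHParameters`) is shared, since parameters are
inputs to both formulations.

The module also carries the annotated item enumeration of this flat
formulation (every variable, parameter and equation a reader has to face at
once), which the complexity metrics tally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .circuit_core import FlatSystem
from .hh_library import HHParameters

__all__ = [
    "MonolithicState",
    "monolithic_rhs",
    "monolithic_initial_state",
    "monolithic_system",
    "MonolithicEntry",
    "MONOLITHIC_DECLARATION",
]


@dataclass(frozen=True)
class MonolithicState:
    """State of the flat system: displacement voltage and gate fractions."""

    V: float
    n: float
    m: float
    h: float

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.n, self.m, self.h], dtype=float)


# -- literal rate functions (do not refactor onto hh_library) ---------------


def _alpha_n(V: float) -> float:
    u = V + 10.0
    if u == 0.0:
        return 0.1  # limit of 0.01·u/(e^{u/10} - 1)
    return 0.01 * u / (math.exp(u / 10.0) - 1.0)


def _beta_n(V: float) -> float:
    return 0.125 * math.exp(V / 80.0)


def _alpha_m(V: float) -> float:
    u = V + 25.0
    if u == 0.0:
        return 1.0
    return 0.1 * u / (math.exp(u / 10.0) - 1.0)


def _beta_m(V: float) -> float:
    return 4.0 * math.exp(V / 18.0)


def _alpha_h(V: float) -> float:
    return 0.07 * math.exp(V / 20.0)


def _beta_h(V: float) -> float:
    return 1.0 / (math.exp((V + 30.0) / 10.0) + 1.0)


def monolithic_rhs(
    t: float,
    y: np.ndarray | MonolithicState,
    params: HHParameters,
    i_app: float = 0.0,
) -> np.ndarray:
    """Time derivative (dV/dt, dn/dt, dm/dt, dh/dt) of the flat system."""
    if isinstance(y, MonolithicState):
        y = y.as_array()
    V, n, m, h = y
    phi = params.q10 ** ((params.temperature - params.t_ref) / 10.0)
    i_na = params.g_max_na * m**3 * h * (V - params.v_eq_na)
    i_k = params.g_max_k * n**4 * (V - params.v_eq_k)
    i_l = params.g_max_leak * (V - params.v_eq_leak)
    i_ion = i_na + i_k + i_l
    dV = -(i_ion + i_app) / params.c
    dn = phi * (_alpha_n(V) * (1.0 - n) - _beta_n(V) * n)
    dm = phi * (_alpha_m(V) * (1.0 - m) - _beta_m(V) * m)
    dh = phi * (_alpha_h(V) * (1.0 - h) - _beta_h(V) * h)
    return np.array([dV, dn, dm, dh])


def monolithic_initial_state(params: HHParameters, v_init: float | None = None) -> MonolithicState:
    """Initial state: V = v_init with gates at their V = 0 steady states.

    The gates are initialized at the pre-stimulus holding potential (0 mV),
    not at v_init, mirroring a sudden displacement of a previously resting
    membrane; the gate values therefore do not depend on v_init.
    """
    if v_init is None:
        v_init = params.v_init
    n0 = _alpha_n(0.0) / (_alpha_n(0.0) + _beta_n(0.0))
    m0 = _alpha_m(0.0) / (_alpha_m(0.0) + _beta_m(0.0))
    h0 = _alpha_h(0.0) / (_alpha_h(0.0) + _beta_h(0.0))
    return MonolithicState(V=float(v_init), n=n0, m=m0, h=h0)


def monolithic_system(
    params: HHParameters | None = None,
    v_init: float | None = None,
    i_app: float | None = None,
) -> FlatSystem:
    """Package the flat equations in the same contract as a flattened circuit."""
    p = params or HHParameters()
    if i_app is None:
        i_app = p.i_const
    y0 = monolithic_initial_state(p, v_init).as_array()

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        return monolithic_rhs(t, y, p, i_app)

    def observables(t: float, y: np.ndarray) -> dict[str, float]:
        V, n, m, h = y
        g_na = p.g_max_na * m**3 * h
        g_k = p.g_max_k * n**4
        return {
            "i_Na": g_na * (V - p.v_eq_na),
            "i_K": g_k * (V - p.v_eq_k),
            "i_L": p.g_max_leak * (V - p.v_eq_leak),
            "g_Na": g_na,
            "g_K": g_k,
            "g_L": p.g_max_leak,
            "phi": p.phi(),
        }

    def node_residuals(t: float, y: np.ndarray) -> dict[str, float]:
        return {}

    return FlatSystem(
        state_names=["V", "n", "m", "h"],
        state_units=["mV", "1", "1", "1"],
        initial_state=y0,
        parameters=p.to_dict(),
        rhs=rhs,
        observables=observables,
        node_residuals=node_residuals,
        nodes=[],
    )


# -- annotated item enumeration ---------------------------------------------


@dataclass(frozen=True)
class MonolithicEntry:
    """One named item of the flat formulation (for the complexity tally)."""

    name: str
    role: str  # "variable" | "parameter" | "equation"
    doc: str


#: Every item a reader of the flat formulation is confronted with at once.
#: Fitting constants are grouped by the three functional forms of the rate
#: fits (linoid, exponential, logistic); each form contributes its constant
#: slots once, since the same algebraic shape recurs across the six rates.
MONOLITHIC_DECLARATION: tuple[MonolithicEntry, ...] = (
    # time-varying quantities
    MonolithicEntry("V", "variable", "displacement voltage (mV)"),
    MonolithicEntry("n", "variable", "K⁺ activation gate fraction"),
    MonolithicEntry("m", "variable", "Na⁺ activation gate fraction"),
    MonolithicEntry("h", "variable", "Na⁺ inactivation gate fraction"),
    MonolithicEntry("i_Na", "variable", "sodium current (µA/cm²)"),
    MonolithicEntry("i_K", "variable", "potassium current (µA/cm²)"),
    MonolithicEntry("i_L", "variable", "leak current (µA/cm²)"),
    MonolithicEntry("i_ion", "variable", "total ionic current (µA/cm²)"),
    MonolithicEntry("alpha_n", "variable", "n opening rate (1/ms)"),
    MonolithicEntry("beta_n", "variable", "n closing rate (1/ms)"),
    MonolithicEntry("alpha_m", "variable", "m opening rate (1/ms)"),
    MonolithicEntry("beta_m", "variable", "m closing rate (1/ms)"),
    MonolithicEntry("alpha_h", "variable", "h opening rate (1/ms)"),
    MonolithicEntry("beta_h", "variable", "h closing rate (1/ms)"),
    MonolithicEntry("phi", "variable", "temperature acceleration factor"),
    # physical constants
    MonolithicEntry("C", "parameter", "membrane capacitance (µF/cm²)"),
    MonolithicEntry("g_Na", "parameter", "maximum sodium conductance (mS/cm²)"),
    MonolithicEntry("g_K", "parameter", "maximum potassium conductance (mS/cm²)"),
    MonolithicEntry("g_L", "parameter", "leak conductance (mS/cm²)"),
    MonolithicEntry("V_Na", "parameter", "sodium reversal displacement (mV)"),
    MonolithicEntry("V_K", "parameter", "potassium reversal displacement (mV)"),
    MonolithicEntry("V_L", "parameter", "leak reversal displacement (mV)"),
    MonolithicEntry("I_app", "parameter", "applied clamp current (µA/cm²)"),
    MonolithicEntry("T", "parameter", "temperature (°C)"),
    MonolithicEntry("T_ref", "parameter", "reference temperature (°C)"),
    MonolithicEntry("q10", "parameter", "rate acceleration per 10 °C"),
    # fitting constants, grouped by fit-function form
    MonolithicEntry("A_linoid", "parameter", "linoid-form amplitude (α_n, α_m)"),
    MonolithicEntry("V0_linoid", "parameter", "linoid-form voltage offset (α_n, α_m)"),
    MonolithicEntry("s_linoid", "parameter", "linoid-form voltage scale (α_n, α_m)"),
    MonolithicEntry("A_exp", "parameter", "exponential-form amplitude (β_n, β_m, α_h)"),
    MonolithicEntry("s_exp", "parameter", "exponential-form voltage scale (β_n, β_m, α_h)"),
    MonolithicEntry("V0_logistic", "parameter", "logistic-form midpoint (β_h)"),
    MonolithicEntry("s_logistic", "parameter", "logistic-form voltage scale (β_h)"),
    # equations
    MonolithicEntry("membrane_law", "equation", "C·dV/dt = -(i_ion + I_app)"),
    MonolithicEntry("total_ionic_current", "equation", "i_ion = i_Na + i_K + i_L"),
    MonolithicEntry("sodium_current", "equation", "i_Na = g_Na·m³·h·(V - V_Na)"),
    MonolithicEntry("potassium_current", "equation", "i_K = g_K·n⁴·(V - V_K)"),
    MonolithicEntry("leak_current", "equation", "i_L = g_L·(V - V_L)"),
    MonolithicEntry("n_kinetics", "equation", "dn/dt = φ·(α_n·(1-n) - β_n·n)"),
    MonolithicEntry("m_kinetics", "equation", "dm/dt = φ·(α_m·(1-m) - β_m·m)"),
    MonolithicEntry("h_kinetics", "equation", "dh/dt = φ·(α_h·(1-h) - β_h·h)"),
    MonolithicEntry("alpha_n_fit", "equation", "α_n = 0.01(V+10)/(e^{(V+10)/10} - 1)"),
    MonolithicEntry("beta_n_fit", "equation", "β_n = 0.125·e^{V/80}"),
    MonolithicEntry("alpha_m_fit", "equation", "α_m = 0.1(V+25)/(e^{(V+25)/10} - 1)"),
    MonolithicEntry("beta_m_fit", "equation", "β_m = 4·e^{V/18}"),
    MonolithicEntry("alpha_h_fit", "equation", "α_h = 0.07·e^{V/20}"),
    MonolithicEntry("beta_h_fit", "equation", "β_h = 1/(e^{(V+30)/10} + 1)"),
    MonolithicEntry("temperature_factor", "equation", "φ = q10^{(T-T_ref)/10}"),
)
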