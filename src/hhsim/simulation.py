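"""Time integration, output conventions and trace comparison.

Simulations integrate a :class:`~hhsim.circuit_core.FlatSystem` (either the
flattened modular circuit or the monolithic reference) on a uniform output
grid.  Two solvers are offered: an adaptive stiff integrator (LSODA) with
tight tolerances, and a fixed-step classic Runge-Kutta scheme whose output
is bitwise reproducible across runs.

Internally the membrane state is the displacement voltage V (0 at rest,
negative during depolarization).  Traces always carry both V and the
measured membrane potential V_m = E_r - V, with a resting potential E_r of
-75 mV by default, so either convention can be inspected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .circuit_core import FlatSystem
from .hh_library import HHParameters
from .monolithic import monolithic_system

__all__ = [
    "IntegrationError",
    "TraceComparisonError",
    "ExperimentConfig",
    "Trace",
    "TRACE_COLUMNS",
    "to_measured_potential",
    "integrate",
    "simulate",
    "run_modular",
    "run_monolithic",
    "compare_traces",
]


class IntegrationError(RuntimeError):
    """The solver failed; ``last_time`` holds the last accepted time (ms)."""

    def __init__(self, message: str, last_time: float = 0.0):
        super().__init__(message)
        self.last_time = last_time


class TraceComparisonError(ValueError):
    """Traces cannot be compared (mismatched time grids)."""


@dataclass
class ExperimentConfig:
    """Settings of one current-clamp experiment.

    ``seed`` is reserved for future stochastic extensions; the dynamics here
    are deterministic.
    """

    duration: float = 50.0  # ms
    output_step: float = 0.01  # ms
    v_init: float = -15.0  # mV displacement (15 mV depolarizing stimulus)
    i_const: float = 0.0  # µA/cm²
    temperature: float = 6.3  # °C
    solver: str = "stiff"  # "stiff" (adaptive LSODA) | "rk4" (fixed step)
    rtol: float = 1e-8
    atol: float = 1e-10  # mV
    rk4_dt: float = 0.01  # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0.0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.output_step <= 0.0:
            raise ValueError(f"output_step must be positive, got {self.output_step}")
        if self.rtol <= 0.0 or self.atol <= 0.0:
            raise ValueError("solver tolerances must be positive")
        if self.solver not in ("stiff", "rk4"):
            raise ValueError(f"unknown solver {self.solver!r}")
        if self.rk4_dt <= 0.0:
            raise ValueError(f"rk4_dt must be positive, got {self.rk4_dt}")

    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration / self.output_step))
        return np.linspace(0.0, n * self.output_step, n + 1)


#: canonical trace column order of the CSV format
TRACE_COLUMNS = [
    "time_ms",
    "V_mV",
    "Vm_mV",
    "n",
    "m",
    "h",
    "iNa_uAcm2",
    "iK_uAcm2",
    "iL_uAcm2",
]


def to_measured_potential(V, e_rest: float):
    """Convert displacement voltage to measured potential: V_m = E_r - V."""
    return e_rest - np.asarray(V) if np.ndim(V) else e_rest - V


@dataclass
class Trace:
    """Uniform time series of one simulation run."""

    data: pd.DataFrame
    e_rest: float = -75.0

    @property
    def time(self) -> np.ndarray:
        return self.data["time_ms"].to_numpy()

    @property
    def V(self) -> np.ndarray:
        return self.data["V_mV"].to_numpy()

    @property
    def V_m(self) -> np.ndarray:
        return self.data["Vm_mV"].to_numpy()

    def __getitem__(self, column: str) -> np.ndarray:
        return self.data[column].to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_csv(cls, path, e_rest: float = -75.0) -> "Trace":
        return cls(pd.read_csv(path), e_rest)


# -- state/observable naming of the two formulations ------------------------

_ROLE_CANDIDATES = {
    "V": [("state", "lipidBilayer.v"), ("state", "V")],
    "n": [("state", "potassiumChannel.gateN.n"), ("state", "n")],
    "m": [("state", "sodiumChannel.gateAct.n"), ("state", "m")],
    "h": [("state", "sodiumChannel.gateInact.n"), ("state", "h")],
    "iNa": [("obs", "sodiumChannel.i"), ("obs", "i_Na")],
    "iK": [("obs", "potassiumChannel.i"), ("obs", "i_K")],
    "iL": [("obs", "leakChannel.i"), ("obs", "i_L")],
}


def _resolve_roles(system: FlatSystem) -> dict[str, tuple[str, object]]:
    obs_names = set(system.observables(0.0, system.initial_state))
    roles: dict[str, tuple[str, object]] = {}
    for role, candidates in _ROLE_CANDIDATES.items():
        for kind, name in candidates:
            if kind == "state" and name in system.state_names:
                roles[role] = ("state", system.state_names.index(name))
                break
            if kind == "obs" and name in obs_names:
                roles[role] = ("obs", name)
                break
        else:
            raise KeyError(
                f"cannot locate the {role!r} column in system states/observables"
            )
    return roles


# -- integration -------------------------------------------------------------


def integrate(system: FlatSystem, config: ExperimentConfig) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a flat system on the config's uniform grid.

    Returns ``(t, Y)`` with ``Y`` of shape (len(t), n_states).
    """
    grid = config.time_grid()
    if config.solver == "stiff":
        sol = solve_ivp(
            system.rhs,
            (grid[0], grid[-1]),
            system.initial_state,
            method="LSODA",
            t_eval=grid,
            rtol=config.rtol,
            atol=config.atol,
        )
        if not sol.success:
            last = float(sol.t[-1]) if len(sol.t) else 0.0
            raise IntegrationError(f"solver failed: {sol.message}", last_time=last)
        return grid, sol.y.T
    # fixed-step classic RK4; substeps tile each output interval exactly
    n_sub = max(1, int(math.ceil(config.output_step / config.rk4_dt)))
    dt = config.output_step / n_sub
    y = system.initial_state.astype(float).copy()
    out = np.empty((len(grid), len(y)))
    out[0] = y
    t = grid[0]
    rhs = system.rhs
    for k in range(1, len(grid)):
        for _ in range(n_sub):
            k1 = rhs(t, y)
            k2 = rhs(t + dt / 2.0, y + dt / 2.0 * k1)
            k3 = rhs(t + dt / 2.0, y + dt / 2.0 * k2)
            k4 = rhs(t + dt, y + dt * k3)
            y = y + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            t += dt
        t = grid[k]  # avoid accumulated rounding in the reported grid
        out[k] = y
    return grid, out


def simulate(
    system: FlatSystem,
    config: ExperimentConfig,
    params: HHParameters | None = None,
) -> Trace:
    """Run one experiment and assemble the membrane trace.

    Works for any system exposing the membrane voltage, the three gates and
    the three branch currents under either the modular qualified names or
    the flat V/n/m/h names.
    """
    p = params or HHParameters()
    roles = _resolve_roles(system)
    t, Y = integrate(system, config)

    obs_keys = [key for kind, key in roles.values() if kind == "obs"]
    obs_rows: dict[str, np.ndarray] = {key: np.empty(len(t)) for key in obs_keys}
    for i in range(len(t)):
        row = system.observables(t[i], Y[i])
        for key in obs_keys:
            obs_rows[key][i] = row[key]

    def column(role: str) -> np.ndarray:
        kind, key = roles[role]
        if kind == "state":
            return Y[:, key]
        return obs_rows[key]

    V = column("V")
    frame = pd.DataFrame(
        {
            "time_ms": t,
            "V_mV": V,
            "Vm_mV": to_measured_potential(V, p.e_rest),
            "n": column("n"),
            "m": column("m"),
            "h": column("h"),
            "iNa_uAcm2": column("iNa"),
            "iK_uAcm2": column("iK"),
            "iL_uAcm2": column("iL"),
        }
    )
    return Trace(frame, e_rest=p.e_rest)


def _merge(params: HHParameters | None, config: ExperimentConfig) -> HHParameters:
    p = params or HHParameters()
    return p.evolve(
        v_init=config.v_init, i_const=config.i_const, temperature=config.temperature
    )


def run_modular(config: ExperimentConfig, params: HHParameters | None = None) -> Trace:
    """Build, flatten and simulate the modular circuit model."""
    from .hh_library import build_hh_model  # local import avoids cycle at module load

    p = _merge(params, config)
    system = build_hh_model(p).flatten()
    return simulate(system, config, p)


def run_monolithic(config: ExperimentConfig, params: HHParameters | None = None) -> Trace:
    """Simulate the monolithic reference system under the same config."""
    p = _merge(params, config)
    return simulate(monolithic_system(p), config, p)


def compare_traces(a: Trace, b: Trace) -> dict[str, float]:
    """Max absolute difference and RMSE of the measured-potential columns."""
    if len(a) != len(b) or not np.array_equal(a.time, b.time):
        raise TraceComparisonError("traces have different time grids")
    diff = a.V_m - b.V_m
    return {
        "max_abs_diff": float(np.max(np.abs(diff))),
        "rmse": float(np.sqrt(np.mean(diff**2))),
    }
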