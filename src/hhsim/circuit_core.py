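"""Acausal component/connector framework for membrane-circuit models.

Components declare parameters, variables, equations, electrical pins and
signal ports.  A :class:`CircuitModel` wires components together; electrical
connections merge pins into :class:`ConnectionNode` equivalence classes with
Kirchhoff current-law semantics (the signed pin currents of every node sum
to zero), while signal connections bind an output port to input ports.

:func:`CircuitModel.flatten` turns a validated model into a
:class:`FlatSystem` — an explicit ODE system with one differential state per
capacitive element and per gating subunit — by structural causalization:
node potentials are propagated from the ground reference across capacitive
elements, algebraic branch currents are evaluated from the node potentials,
and each capacitor's charging current is recovered from the current law of
one of its nodes.  This covers circuits made of capacitive nodes bridged by
parallel algebraic branches and sources (the conductance-based membrane
class); genuinely implicit structures raise :class:`UnsupportedStructureError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "CircuitError",
    "DeclarationError",
    "TypeMismatchError",
    "SignalDirectionError",
    "MultipleDriverError",
    "UnsupportedStructureError",
    "Pin",
    "Port",
    "Parameter",
    "Variable",
    "Equation",
    "GateSpec",
    "Component",
    "ConnectionNode",
    "FlatSystem",
    "CircuitModel",
    "Ground",
    "Capacitor",
    "Conductor",
    "CurrentSource",
]


class CircuitError(Exception):
    """Base class for circuit declaration and flattening errors."""


class DeclarationError(CircuitError):
    """A referenced pin, port or component is unknown or redeclared."""


class TypeMismatchError(CircuitError):
    """An electrical pin was paired with a signal port (or vice versa)."""


class SignalDirectionError(CircuitError):
    """A signal connection does not run from an output to an input."""


class MultipleDriverError(CircuitError):
    """An input port was bound to more than one output."""


class UnsupportedStructureError(CircuitError):
    """The circuit contains an algebraic structure the flattener cannot causalize."""


# --------------------------------------------------------------------------
# declaration records
# --------------------------------------------------------------------------


@dataclass(eq=False)
class Pin:
    """Electrical connector carrying a potential (mV) and a flow current (µA/cm²)."""

    owner: "Component"
    name: str
    polarity: str  # "positive" | "negative"

    @property
    def qualname(self) -> str:
        return f"{self.owner.qualname}.{self.name}"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Pin {self.qualname} ({self.polarity})>"


@dataclass(eq=False)
class Port:
    """Scalar signal connector (here: temperature in °C) with a fixed direction."""

    owner: "Component"
    name: str
    direction: str  # "input" | "output"
    value_fn: Callable[[], float] | None = None

    @property
    def qualname(self) -> str:
        return f"{self.owner.qualname}.{self.name}"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Port {self.qualname} ({self.direction})>"


@dataclass(frozen=True)
class Parameter:
    name: str
    value: float
    unit: str = ""
    doc: str = ""
    origin: str = ""


@dataclass(frozen=True)
class Variable:
    name: str
    unit: str = ""
    doc: str = ""
    origin: str = ""


@dataclass(frozen=True)
class Equation:
    """Named, documented equation entry.

    ``kind`` distinguishes differential relations, genuine algebraic
    constraints, and pure alias definitions (renamings such as
    ``v = p.v - n.v``); the distinction is what the complexity metrics count.
    """

    name: str
    kind: str  # "differential" | "algebraic" | "alias"
    doc: str = ""
    origin: str = ""


@dataclass(frozen=True)
class GateSpec:
    """Differential gating state exposed by a component.

    ``initial`` yields the state's initialization value; ``derivative`` maps
    (state value, branch voltage mV, temperature °C or None) to d/dt in 1/ms.
    """

    name: str
    unit: str
    initial: Callable[[], float]
    derivative: Callable[[float, float, float | None], float]


# --------------------------------------------------------------------------
# components
# --------------------------------------------------------------------------


class Component:
    """Named model unit with declared items and optional electrical behavior.

    Subclasses declare their local items in ``_declare_local``; the base
    constructor walks the MRO so that every class level records its own
    declarations with an ``origin`` tag (used by the complexity metrics to
    attribute items to the class that introduced them).  Classes marked
    ``partial = True`` are abstract building blocks; instantiating them
    directly is flagged by :meth:`CircuitModel.validate`.
    """

    partial: bool = False

    def __init__(self, name: str, doc: str = ""):
        self.name = name
        self.doc = doc
        self.parameters: dict[str, Parameter] = {}
        self.variables: dict[str, Variable] = {}
        self.equations: list[Equation] = []
        self.pins: dict[str, Pin] = {}
        self.ports: dict[str, Port] = {}
        self.subcomponents: dict[str, Component] = {}
        self.internal_electrical: list[tuple[Pin, Pin]] = []
        self.internal_signal: list[tuple[Port, Port]] = []
        self._parent: Component | None = None
        self._origin: str = ""
        for cls in reversed(type(self).__mro__):
            if "_declare_local" in cls.__dict__:
                self._origin = cls.__name__
                cls.__dict__["_declare_local"](self)
        self._origin = ""

    # -- declaration API ----------------------------------------------------

    def _check_name(self, name: str) -> None:
        taken = (
            name in self.parameters
            or name in self.variables
            or name in self.pins
            or name in self.ports
            or name in self.subcomponents
        )
        if taken:
            raise DeclarationError(f"duplicate declaration {name!r} in {self.name!r}")

    def declare_parameter(self, name: str, value: float, unit: str = "", doc: str = "") -> None:
        self._check_name(name)
        self.parameters[name] = Parameter(name, float(value), unit, doc, self._origin)

    def declare_variable(self, name: str, unit: str = "", doc: str = "") -> None:
        self._check_name(name)
        self.variables[name] = Variable(name, unit, doc, self._origin)

    def declare_equation(self, name: str, kind: str, doc: str = "") -> None:
        if kind not in ("differential", "algebraic", "alias"):
            raise DeclarationError(f"unknown equation kind {kind!r}")
        self.equations.append(Equation(name, kind, doc, self._origin))

    def declare_pin(self, name: str, polarity: str, doc: str = "") -> Pin:
        self._check_name(name)
        if polarity not in ("positive", "negative"):
            raise DeclarationError(f"unknown pin polarity {polarity!r}")
        pin = Pin(self, name, polarity)
        self.pins[name] = pin
        # a connector instance is one item the reader must track
        self.variables[name] = Variable(name, "mV/µA·cm⁻²", doc or "electrical pin", self._origin)
        return pin

    def declare_port(
        self,
        name: str,
        direction: str,
        value_fn: Callable[[], float] | None = None,
        doc: str = "",
    ) -> Port:
        self._check_name(name)
        if direction not in ("input", "output"):
            raise DeclarationError(f"unknown port direction {direction!r}")
        port = Port(self, name, direction, value_fn)
        self.ports[name] = port
        self.variables[name] = Variable(name, "°C", doc or f"temperature {direction}", self._origin)
        return port

    def declare_subcomponent(self, name: str, comp: "Component", doc: str = "") -> "Component":
        self._check_name(name)
        comp._parent = self
        self.subcomponents[name] = comp
        self.variables[name] = Variable(name, "", doc or comp.doc, self._origin)
        return comp

    def connect_internal(self, a: Pin, b: Pin) -> None:
        self.internal_electrical.append((a, b))

    def bind_internal(self, src: Port, inp: Port) -> None:
        """Bind a subcomponent input to ``src``.

        ``src`` may be an output port or an input port of the enclosing
        component that is forwarded down the hierarchy.
        """
        if inp.direction != "input":
            raise SignalDirectionError(
                f"internal binding {src.qualname} -> {inp.qualname} must end at an input"
            )
        self.internal_signal.append((src, inp))

    # -- hierarchy ----------------------------------------------------------

    @property
    def qualname(self) -> str:
        if self._parent is None:
            return self.name
        return f"{self._parent.qualname}.{self.name}"

    def walk(self) -> Iterator["Component"]:
        yield self
        for sub in self.subcomponents.values():
            yield from sub.walk()

    # -- electrical behavior hooks (overridden by element classes) ----------

    @property
    def element_kind(self) -> str | None:
        """"capacitive" | "branch" | "ground" | None (pure container)."""
        return None

    def capacitance(self) -> float:  # pragma: no cover - overridden
        raise NotImplementedError

    def initial_voltage(self) -> float:  # pragma: no cover - overridden
        raise NotImplementedError

    def branch_current(
        self, v: float, states: Mapping[str, float], temp: float | None
    ) -> float:  # pragma: no cover - overridden
        raise NotImplementedError

    def conductance(self, states: Mapping[str, float]) -> float | None:
        return None

    def gate_specs(self) -> Sequence[GateSpec]:
        return ()

    def ground_pin(self) -> Pin | None:
        return None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<{type(self).__name__} {self.qualname!r}>"


# --------------------------------------------------------------------------
# nodes and flattened systems
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ConnectionNode:
    """Equivalence class of electrical pins sharing one potential.

    The signed flow currents of all member pins (positive into the owning
    component) sum to zero; exactly one node in a valid model is the ground
    reference with potential 0 mV.
    """

    pins: frozenset
    is_ground: bool
    label: str

    def __contains__(self, pin: Pin) -> bool:
        return pin in self.pins


@dataclass
class FlatSystem:
    """Assembled ODE system of a connected circuit model.

    ``rhs`` and ``observables`` are pure functions of (t, y); the state
    vector holds one entry per capacitive element (membrane voltage, mV)
    followed by one per gating subunit (open fraction).
    """

    state_names: list[str]
    state_units: list[str]
    initial_state: np.ndarray
    parameters: dict[str, float]
    rhs: Callable[[float, np.ndarray], np.ndarray]
    observables: Callable[[float, np.ndarray], dict[str, float]]
    node_residuals: Callable[[float, np.ndarray], dict[str, float]]
    nodes: list[ConnectionNode]

    @property
    def n_states(self) -> int:
        return len(self.state_names)


# --------------------------------------------------------------------------
# the model container
# --------------------------------------------------------------------------


class CircuitModel:
    """A set of components plus their electrical and signal connections."""

    def __init__(self, name: str = "model", components: Iterable[Component] = ()):
        self.name = name
        self.components: list[Component] = []
        self.electrical_connections: list[tuple[Pin, Pin]] = []
        self.signal_connections: list[tuple[Port, Port]] = []
        for comp in components:
            self.add_component(comp)

    def add_component(self, comp: Component) -> Component:
        if any(c.name == comp.name for c in self.components):
            raise DeclarationError(f"duplicate component name {comp.name!r}")
        self.components.append(comp)
        return comp

    def __getitem__(self, name: str) -> Component:
        for comp in self.components:
            if comp.name == name:
                return comp
        raise KeyError(name)

    # -- hierarchy helpers --------------------------------------------------

    def all_components(self) -> Iterator[Component]:
        for comp in self.components:
            yield from comp.walk()

    def all_pins(self) -> Iterator[Pin]:
        for comp in self.all_components():
            yield from comp.pins.values()

    def _all_electrical_connections(self) -> Iterator[tuple[Pin, Pin]]:
        yield from self.electrical_connections
        for comp in self.all_components():
            yield from comp.internal_electrical

    def _all_signal_connections(self) -> Iterator[tuple[Port, Port]]:
        yield from self.signal_connections
        for comp in self.all_components():
            yield from comp.internal_signal

    # -- connection API -----------------------------------------------------

    def connect_electrical(self, a: Pin, b: Pin) -> "CircuitModel":
        for pin in (a, b):
            if isinstance(pin, Port):
                raise TypeMismatchError(
                    f"{pin.qualname} is a signal port, not an electrical pin"
                )
            if not isinstance(pin, Pin):
                raise TypeMismatchError(f"{pin!r} is not an electrical pin")
        known = set(self.all_pins())
        for pin in (a, b):
            if pin not in known:
                raise DeclarationError(f"pin {pin.qualname} is not part of this model")
        self.electrical_connections.append((a, b))
        return self

    def connect_signal(self, out: Port, inp: Port) -> "CircuitModel":
        for port in (out, inp):
            if isinstance(port, Pin):
                raise TypeMismatchError(
                    f"{port.qualname} is an electrical pin, not a signal port"
                )
            if not isinstance(port, Port):
                raise TypeMismatchError(f"{port!r} is not a signal port")
        if out.direction != "output" or inp.direction != "input":
            raise SignalDirectionError(
                f"signal connection {out.qualname} -> {inp.qualname} "
                "must run from an output to an input"
            )
        if any(i is inp for _, i in self._all_signal_connections()):
            raise MultipleDriverError(f"input {inp.qualname} is already bound")
        self.signal_connections.append((out, inp))
        return self

    def count_connects(self) -> int:
        """Number of model-level connect statements (electrical + signal)."""
        return len(self.electrical_connections) + len(self.signal_connections)

    # -- node partition ------------------------------------------------------

    def partition_nodes(self) -> list[ConnectionNode]:
        """Union-find partition of all electrical pins into connection nodes."""
        graph = nx.Graph()
        graph.add_nodes_from(self.all_pins())
        for a, b in self._all_electrical_connections():
            graph.add_edge(a, b)
        ground_pins = {
            comp.ground_pin() for comp in self.all_components() if comp.ground_pin()
        }
        nodes = []
        groups = sorted(
            (sorted(group, key=lambda p: p.qualname) for group in nx.connected_components(graph)),
            key=lambda pins: pins[0].qualname,
        )
        for idx, pins in enumerate(groups):
            nodes.append(
                ConnectionNode(
                    pins=frozenset(pins),
                    is_ground=any(p in ground_pins for p in pins),
                    label=f"node{idx}({pins[0].qualname})",
                )
            )
        return nodes

    # -- validation ----------------------------------------------------------

    def validate(self) -> list[str]:
        """Structural checks; returns a list of human-readable issues."""
        issues: list[str] = []
        for comp in self.all_components():
            if type(comp).partial:
                issues.append(f"partial component {comp.qualname} instantiated directly")
        bound = [inp for _, inp in self._all_signal_connections()]
        for comp in self.all_components():
            for port in comp.ports.values():
                if port.direction == "input":
                    n = sum(1 for b in bound if b is port)
                    if n == 0:
                        issues.append(f"unbound temperature input {port.qualname}")
                    elif n > 1:
                        issues.append(f"multiply driven input {port.qualname}")
                elif port.direction == "output" and port.value_fn is None:
                    issues.append(f"output port {port.qualname} has no value rule")
        grounds = [c for c in self.all_components() if c.ground_pin() is not None]
        if not grounds:
            issues.append("no ground reference")
        elif len(grounds) > 1:
            issues.append(
                "multiple ground references: " + ", ".join(c.qualname for c in grounds)
            )
        for node in self.partition_nodes():
            if not any(p.owner.element_kind for p in node.pins):
                issues.append(
                    f"{node.label} has no current-defining element attached"
                )
        return issues

    # -- flattening ----------------------------------------------------------

    def flatten(self) -> FlatSystem:
        """Causalize the connected model into an explicit ODE system."""
        issues = self.validate()
        if issues:
            raise DeclarationError("model not valid: " + "; ".join(issues))

        nodes = self.partition_nodes()
        node_of: dict[Pin, int] = {}
        for i, node in enumerate(nodes):
            for pin in node.pins:
                node_of[pin] = i
        ground_idx = next(i for i, n in enumerate(nodes) if n.is_ground)

        caps = [c for c in self.all_components() if c.element_kind == "capacitive"]
        branches = [c for c in self.all_components() if c.element_kind == "branch"]

        # state layout: per component (declaration order): capacitor voltage,
        # then gating states; ties broken by declaration order throughout.
        state_names: list[str] = []
        state_units: list[str] = []
        initial: list[float] = []
        cap_state: dict[Component, int] = {}
        gate_state: dict[tuple[Component, str], int] = {}
        for comp in self.all_components():
            if comp.element_kind == "capacitive":
                cap_state[comp] = len(state_names)
                state_names.append(f"{comp.qualname}.v")
                state_units.append("mV")
                initial.append(comp.initial_voltage())
            for spec in comp.gate_specs():
                gate_state[(comp, spec.name)] = len(state_names)
                state_names.append(f"{comp.qualname}.{spec.name}")
                state_units.append(spec.unit)
                initial.append(spec.initial())

        # node potentials as affine forms over the capacitor states, found by
        # propagating from ground across capacitive elements (v = v_p - v_n).
        pot_expr: dict[int, list[tuple[int, float]]] = {ground_idx: []}
        frontier = [ground_idx]
        while frontier:
            here = frontier.pop()
            for cap in caps:
                p_idx, n_idx = node_of[cap.pins["p"]], node_of[cap.pins["n"]]
                s = cap_state[cap]
                if p_idx == here and n_idx not in pot_expr:
                    pot_expr[n_idx] = pot_expr[here] + [(s, -1.0)]
                    frontier.append(n_idx)
                elif n_idx == here and p_idx not in pot_expr:
                    pot_expr[p_idx] = pot_expr[here] + [(s, +1.0)]
                    frontier.append(p_idx)
        missing = [nodes[i].label for i in range(len(nodes)) if i not in pot_expr]
        if missing:
            raise UnsupportedStructureError(
                "node potentials cannot be causalized (algebraic loop or floating "
                "subcircuit): " + ", ".join(missing)
            )

        # temperature resolution: every input port follows its driver output.
        drivers = {inp: out for out, inp in self._all_signal_connections()}

        def port_value(port: Port) -> float:
            seen = set()
            while port.direction == "input":
                if port in seen:  # defensive; validate precludes cycles
                    raise UnsupportedStructureError(f"signal cycle at {port.qualname}")
                seen.add(port)
                port = drivers[port]
            assert port.value_fn is not None
            return float(port.value_fn())

        temp_of: dict[Component, float | None] = {}
        for comp in self.all_components():
            t = None
            for port in comp.ports.values():
                if port.direction == "input":
                    t = port_value(port)
            temp_of[comp] = t

        # per-branch precomputation
        branch_info = []
        for comp in branches:
            p_idx, n_idx = node_of[comp.pins["p"]], node_of[comp.pins["n"]]
            gates = [(spec, gate_state[(comp, spec.name)]) for spec in comp.gate_specs()]
            branch_info.append((comp, p_idx, n_idx, gates, temp_of[comp]))

        # choose, per capacitor, the node whose current law determines its
        # charging current: all other attached pins must be branch pins.
        branch_pins = {pin: comp for comp in branches for pin in comp.pins.values()}
        cap_info = []
        for cap in caps:
            chosen = None
            for pin_name, sign in (("n", +1.0), ("p", -1.0)):
                idx = node_of[cap.pins[pin_name]]
                # container pins are pure junctions and carry no flow of
                # their own; only element pins enter the node current law
                others = sorted(
                    (
                        p
                        for p in nodes[idx].pins
                        if p.owner is not cap and p.owner.element_kind is not None
                    ),
                    key=lambda p: p.qualname,
                )
                if all(p in branch_pins for p in others):
                    chosen = (idx, sign, others)
                    break
            if chosen is None:
                raise UnsupportedStructureError(
                    f"cannot isolate the charging current of {cap.qualname}: "
                    "neither of its nodes is spanned only by algebraic branches"
                )
            cap_info.append((cap, cap_state[cap], cap.capacitance(), chosen))

        parameters = {
            f"{comp.qualname}.{p.name}": p.value
            for comp in self.all_components()
            for p in comp.parameters.values()
        }

        def potentials(y: np.ndarray) -> np.ndarray:
            pot = np.empty(len(nodes))
            for i in range(len(nodes)):
                pot[i] = sum(coef * y[s] for s, coef in pot_expr[i])
            return pot

        def branch_currents(y: np.ndarray) -> dict[Component, float]:
            pot = potentials(y)
            currents = {}
            for comp, p_idx, n_idx, gates, temp in branch_info:
                v = pot[p_idx] - pot[n_idx]
                states = {spec.name: y[s] for spec, s in gates}
                currents[comp] = comp.branch_current(v, states, temp)
            return currents

        def cap_currents(y: np.ndarray, ib: dict[Component, float]) -> dict[Component, float]:
            out = {}
            for cap, _, _, (idx, sign, others) in cap_info:
                total = 0.0
                for pin in others:
                    i = ib[branch_pins[pin]]
                    total += i if pin.polarity == "negative" else -i
                out[cap] = -sign * total
            return out

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            dy = np.zeros_like(y)
            pot = potentials(y)
            ib = branch_currents(y)
            ic = cap_currents(y, ib)
            for cap, s, c, _ in cap_info:
                dy[s] = ic[cap] / c
            for comp, p_idx, n_idx, gates, temp in branch_info:
                v = pot[p_idx] - pot[n_idx]
                for spec, s in gates:
                    dy[s] = spec.derivative(y[s], v, temp)
            return dy

        def observables(t: float, y: np.ndarray) -> dict[str, float]:
            pot = potentials(y)
            ib = branch_currents(y)
            ic = cap_currents(y, ib)
            obs: dict[str, float] = {}
            for i, node in enumerate(nodes):
                obs[f"{node.label}.v"] = pot[i]
            for comp, p_idx, n_idx, gates, _ in branch_info:
                v = pot[p_idx] - pot[n_idx]
                obs[f"{comp.qualname}.v"] = v
                obs[f"{comp.qualname}.i"] = ib[comp]
                g = comp.conductance({spec.name: y[s] for spec, s in gates})
                if g is not None:
                    obs[f"{comp.qualname}.g"] = g
            for cap, s, _, _ in cap_info:
                obs[f"{cap.qualname}.v"] = y[s]
                obs[f"{cap.qualname}.i"] = ic[cap]
            # containers spanning two pins (e.g. a clamp) expose their span
            for comp in self.all_components():
                if comp.element_kind is None and {"p", "n"} <= set(comp.pins):
                    obs[f"{comp.qualname}.v"] = (
                        pot[node_of[comp.pins["p"]]] - pot[node_of[comp.pins["n"]]]
                    )
            return obs

        def node_residuals(t: float, y: np.ndarray) -> dict[str, float]:
            """Signed current sum per node over capacitor and branch pins.

            The pin of a ground element carries the reference electrode's
            return current and is excluded; every other sum must vanish.
            """
            ib = branch_currents(y)
            ic = cap_currents(y, ib)
            through = {**ib, **ic}
            res = {}
            for node in nodes:
                total = 0.0
                for pin in sorted(node.pins, key=lambda p: p.qualname):
                    comp = pin.owner
                    if comp.element_kind in ("branch", "capacitive"):
                        i = through[comp]
                        total += i if pin.polarity == "negative" else -i
                res[node.label] = total
            return res

        return FlatSystem(
            state_names=state_names,
            state_units=state_units,
            initial_state=np.array(initial, dtype=float),
            parameters=parameters,
            rhs=rhs,
            observables=observables,
            node_residuals=node_residuals,
            nodes=nodes,
        )


# --------------------------------------------------------------------------
# elementary electrical components
# --------------------------------------------------------------------------


class Ground(Component):
    """Reference electrode fixing its node potential to 0 mV."""

    def _declare_local(self) -> None:
        self.declare_pin("pin", "positive", doc="reference electrode pin")
        self.declare_equation("reference", "algebraic", "pin potential is 0 mV")

    @property
    def element_kind(self) -> str:
        return "ground"

    def ground_pin(self) -> Pin:
        return self.pins["pin"]


class Capacitor(Component):
    """Ideal capacitor: dv/dt = i/C with v = v_p − v_n and i the through-current."""

    def __init__(self, name: str, c: float, v_init: float = 0.0, doc: str = ""):
        self.c = float(c)
        self.v_init = float(v_init)
        super().__init__(name, doc or "ideal capacitor")

    def _declare_local(self) -> None:
        self.declare_pin("p", "positive")
        self.declare_pin("n", "negative")
        self.declare_variable("v", "mV", "voltage across the capacitor")
        self.declare_variable("i", "µA/cm²", "through-current (n → p)")
        self.declare_parameter("c", self.c, "µF/cm²", "capacitance")
        self.declare_equation("charge_law", "differential", "dv/dt = i/c")

    @property
    def element_kind(self) -> str:
        return "capacitive"

    def capacitance(self) -> float:
        return self.c

    def initial_voltage(self) -> float:
        return self.v_init


class Conductor(Component):
    """Linear conductor: i = g·(v − v_eq)."""

    def __init__(self, name: str, g: float, v_eq: float = 0.0, doc: str = ""):
        self.g = float(g)
        self.v_eq = float(v_eq)
        super().__init__(name, doc or "linear conductor")

    def _declare_local(self) -> None:
        self.declare_pin("p", "positive")
        self.declare_pin("n", "negative")
        self.declare_variable("v", "mV")
        self.declare_variable("i", "µA/cm²")
        self.declare_parameter("g", self.g, "mS/cm²", "conductance")
        self.declare_parameter("v_eq", self.v_eq, "mV", "equilibrium potential")
        self.declare_equation("ohm_law", "algebraic", "i = g(v − v_eq)")

    @property
    def element_kind(self) -> str:
        return "branch"

    def branch_current(self, v: float, states: Mapping[str, float], temp: float | None) -> float:
        return self.g * (v - self.v_eq)

    def conductance(self, states: Mapping[str, float]) -> float:
        return self.g


class CurrentSource(Component):
    """Ideal source forcing a constant through-current (n → p)."""

    def __init__(self, name: str, i_const: float, doc: str = ""):
        self.i_const = float(i_const)
        super().__init__(name, doc or "constant current source")

    def _declare_local(self) -> None:
        self.declare_pin("p", "positive")
        self.declare_pin("n", "negative")
        self.declare_parameter("i_const", self.i_const, "µA/cm²", "source current")
        self.declare_equation("source_law", "algebraic", "i = i_const")

    @property
    def element_kind(self) -> str:
        return "branch"

    def branch_current(self, v: float, states: Mapping[str, float], temp: float | None) -> float:
        return self.i_const
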