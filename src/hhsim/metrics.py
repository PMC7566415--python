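"""Cognitive-load accounting: item counts per component and reduction factor.

The understandability proxy counted here is the number of items a reader
must hold in working memory at once.  The counting convention:

* only *locally declared* items count for a class — inherited items were
  already processed while reading the base class;
* every connector instance (electrical pin or signal port) is one variable,
  as is every subcomponent instance and every stored replaceable rate
  function;
* alias definitions (pure renamings such as ``v = p.v - n.v``) and
  initialization rules are not counted as equations;
* connect statements are tallied separately from equations.

The worst-case simultaneous load of a modular model combines the largest
local variable/parameter set with the largest local equation set a reader
encounters while moving from component to component.  Dividing the flat
formulation's total item count by this number gives the reduction factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .circuit_core import CircuitModel, Component
from .monolithic import MONOLITHIC_DECLARATION

__all__ = [
    "ItemCount",
    "LoadProfile",
    "item_count",
    "item_count_for_class",
    "model_load_profile",
    "monolithic_count",
    "reduction_factor",
    "profile_table",
]


@dataclass(frozen=True)
class ItemCount:
    """Tally of variables, parameters, equations and connects of one unit."""

    component_name: str
    n_variables: int
    n_parameters: int
    n_equations: int
    n_connects: int = 0
    partial: bool = False

    @property
    def n_vars_params(self) -> int:
        return self.n_variables + self.n_parameters

    @property
    def total(self) -> int:
        """Simultaneous items of this unit: variables + parameters + equations."""
        return self.n_variables + self.n_parameters + self.n_equations


@dataclass(frozen=True)
class LoadProfile:
    """Per-component counts plus model-wide load statistics."""

    per_component: tuple[ItemCount, ...]
    max_equations: int
    max_vars_params: int
    max_simultaneous: int
    total: int

    def __getitem__(self, name: str) -> ItemCount:
        for item in self.per_component:
            if item.component_name == name:
                return item
        raise KeyError(name)


def item_count_for_class(component: Component, class_name: str) -> ItemCount:
    """Items declared by one class level of a component's hierarchy."""
    n_vars = sum(1 for v in component.variables.values() if v.origin == class_name)
    n_params = sum(1 for p in component.parameters.values() if p.origin == class_name)
    n_eqs = sum(
        1
        for e in component.equations
        if e.origin == class_name and e.kind != "alias"
    )
    cls = next((c for c in type(component).__mro__ if c.__name__ == class_name), None)
    is_partial = bool(getattr(cls, "partial", False)) if cls is not None else False
    # internal connects are only ever declared by the most-derived class
    n_connects = 0
    if class_name == type(component).__name__:
        n_connects = len(component.internal_electrical) + len(component.internal_signal)
    return ItemCount(class_name, n_vars, n_params, n_eqs, n_connects, is_partial)


def item_count(component: Component) -> ItemCount:
    """Locally declared items of a component (its most-derived class level)."""
    return item_count_for_class(component, type(component).__name__)


def model_load_profile(model: CircuitModel) -> LoadProfile:
    """Per-class item counts of a connected model plus load maxima.

    A reader processes each *class* once (base classes first, then each
    concrete component), so counts are grouped by declaring class and
    deduplicated across instances.  The top-level model is one more unit
    whose variables are its components and whose connects are the model's
    connect statements.  Partial base classes are listed but excluded from
    the maxima, since they are never faced as stand-alone components.
    """
    per: list[ItemCount] = []
    seen: set[str] = set()
    for comp in model.all_components():
        for cls in reversed(type(comp).__mro__):
            name = cls.__name__
            if name in ("object", "Component") or name in seen:
                continue
            if "_declare_local" not in cls.__dict__:
                continue
            seen.add(name)
            per.append(item_count_for_class(comp, name))
    per.append(
        ItemCount(
            component_name=model.name,
            n_variables=len(model.components),
            n_parameters=0,
            n_equations=0,
            n_connects=model.count_connects(),
        )
    )
    concrete = [c for c in per if not c.partial]
    max_eq = max((c.n_equations for c in concrete), default=0)
    max_vp = max((c.n_vars_params for c in concrete), default=0)
    return LoadProfile(
        per_component=tuple(per),
        max_equations=max_eq,
        max_vars_params=max_vp,
        max_simultaneous=max_eq + max_vp,
        total=sum(c.total for c in per),
    )


def monolithic_count(params=None, declaration=MONOLITHIC_DECLARATION) -> ItemCount:
    """Tally the annotated enumeration of the flat formulation.

    The count is purely structural; ``params`` is accepted for interface
    symmetry with the simulation entry points but does not influence it.
    """
    roles = [entry.role for entry in declaration]
    return ItemCount(
        component_name="monolithic",
        n_variables=roles.count("variable"),
        n_parameters=roles.count("parameter"),
        n_equations=roles.count("equation"),
    )


def reduction_factor(mono: ItemCount, profile: LoadProfile) -> float:
    """Flat total item count divided by the modular worst-case load."""
    if profile.max_simultaneous <= 0:
        raise ValueError("degenerate load profile: max_simultaneous is zero")
    return mono.total / profile.max_simultaneous


def profile_table(profile: LoadProfile) -> pd.DataFrame:
    """Load profile as a tidy table (one row per counted unit)."""
    return pd.DataFrame(
        {
            "component": [c.component_name for c in profile.per_component],
            "variables": [c.n_variables for c in profile.per_component],
            "parameters": [c.n_parameters for c in profile.per_component],
            "equations": [c.n_equations for c in profile.per_component],
            "connects": [c.n_connects for c in profile.per_component],
            "partial": [c.partial for c in profile.per_component],
        }
    )
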