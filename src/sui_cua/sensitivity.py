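"""Deterministic one-way and multiway sensitivity analysis on cost components.

A scenario is an ordered list of component modifications — scale a cost
component by a factor, or exclude it — applied identically to both arms.
QALY gains are untouched (cost-side sensitivity only); the incremental
result is recomputed per scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .costs import COST_COMPONENTS, CostBreakdown
from .errors import ConfigError, ValidationError
from .incremental import GroupSummary, IncrementalResult, incremental

ACTIONS = ("scale", "exclude")


@dataclass(frozen=True)
class Modification:
    """One component modification: scale by ``factor`` or exclude (zero out)."""

    component: str
    action: str
    factor: float | None = None

    def __post_init__(self) -> None:
        if self.component not in COST_COMPONENTS:
            raise ConfigError(
                f"unknown cost component {self.component!r}; known: {COST_COMPONENTS}"
            )
        if self.action not in ACTIONS:
            raise ConfigError(f"action must be one of {ACTIONS}, got {self.action!r}")
        if self.action == "scale":
            if self.factor is None or self.factor <= 0:
                raise ConfigError(
                    f"scale requires factor > 0, got {self.factor!r}"
                )


@dataclass(frozen=True)
class Scenario:
    """A named, ordered list of modifications defining one sensitivity case."""

    name: str
    modifications: tuple[Modification, ...] = ()

    @classmethod
    def from_dict(cls, d: Mapping) -> "Scenario":
        mods = tuple(
            Modification(
                component=m["component"],
                action=m["action"],
                factor=m.get("factor"),
            )
            for m in d.get("modifications", [])
        )
        return cls(name=str(d["name"]), modifications=mods)


def apply_scenario(breakdown: CostBreakdown, scenario: Scenario) -> CostBreakdown:
    """Apply each modification in order; untouched components are unchanged."""
    out = breakdown
    for mod in scenario.modifications:
        current = getattr(out, mod.component)
        if mod.action == "exclude":
            out = out.with_component(mod.component, 0.0)
        else:
            out = out.with_component(mod.component, current * mod.factor)
    return out


@dataclass(frozen=True)
class SensitivityRow:
    scenario: str
    cost_intervention: float
    cost_comparator: float
    qaly_gain_intervention: float
    qaly_gain_comparator: float
    result: IncrementalResult


@dataclass(frozen=True)
class SensitivityTable:
    """Base case plus one row per scenario, each with its incremental result."""

    rows: tuple[SensitivityRow, ...]

    def row(self, name: str) -> SensitivityRow:
        for r in self.rows:
            if r.scenario == name:
                return r
        raise KeyError(name)

    def icers(self) -> dict[str, float | None]:
        return {r.scenario: r.result.icer for r in self.rows}

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for r in self.rows:
            records.append(
                {
                    "scenario": r.scenario,
                    "cost_intervention": r.cost_intervention,
                    "cost_comparator": r.cost_comparator,
                    "qaly_gain_intervention": r.qaly_gain_intervention,
                    "qaly_gain_comparator": r.qaly_gain_comparator,
                    "delta_cost": r.result.delta_cost,
                    "delta_qaly": r.result.delta_qaly,
                    "icer": r.result.icer,
                    "quadrant": r.result.quadrant,
                }
            )
        return pd.DataFrame.from_records(records)


def run_sensitivity(
    base_intervention: CostBreakdown,
    base_comparator: CostBreakdown,
    qaly_gain_intervention: float,
    qaly_gain_comparator: float,
    scenarios: Sequence[Scenario],
    intervention_arm: str = "app",
    comparator_arm: str = "control",
) -> SensitivityTable:
    """Recompute the incremental result under the base case and every scenario."""
    if not scenarios:
        raise ValidationError("scenario list must be non-empty")
    all_scenarios = [Scenario(name="base")] + [
        s for s in scenarios if s.name != "base"
    ]
    rows = []
    for scen in all_scenarios:
        bd_i = apply_scenario(base_intervention, scen)
        bd_c = apply_scenario(base_comparator, scen)
        res = incremental(
            GroupSummary(intervention_arm, bd_i.total, qaly_gain_intervention),
            GroupSummary(comparator_arm, bd_c.total, qaly_gain_comparator),
        )
        rows.append(
            SensitivityRow(
                scenario=scen.name,
                cost_intervention=bd_i.total,
                cost_comparator=bd_c.total,
                qaly_gain_intervention=qaly_gain_intervention,
                qaly_gain_comparator=qaly_gain_comparator,
                result=res,
            )
        )
    return SensitivityTable(rows=tuple(rows))


def scenarios_from_dicts(items: Sequence[Mapping]) -> list[Scenario]:
    return [Scenario.from_dict(d) for d in items]


def default_scenarios() -> list[Scenario]:
    """The four bundled scenarios: training time halved, laundry (goods) cost
    halved, laundry time excluded, and the multiway combination."""
    text = (
        resources.files("sui_cua").joinpath("data/sensitivity_scenarios.yaml")
        .read_text()
    )
    return scenarios_from_dicts(yaml.safe_load(text)["scenarios"])
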