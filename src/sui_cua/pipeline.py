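"""End-to-end cost-utility analysis: scoring -> utilities -> QALYs -> costs -> ICER.

Two input modes are supported:

* **participant mode** — a long-format participant table; questionnaires are
  scored, utilities and costs computed per participant, and completer arm
  means feed the incremental analysis.
* **group-mean mode** — arm-level annual amounts (cost-table layout) or
  per-component euro costs, together with arm QALY gains, are supplied
  directly; this reproduces a published deterministic analysis exactly.

All computation is unrounded; the CSV table writers round for display
(costs to 1 decimal, QALYs to 5, ICERs to 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .costs import (
    ARMS,
    COST_COMPONENTS,
    AnnualizationPolicy,
    CostBreakdown,
    PriceConfig,
    ResourceUse,
    breakdown_from_annual_amounts,
    breakdown_from_costs,
    annualize_constant,
    annualize_pfmt,
    default_policies,
    total_annual_cost,
)
from .errors import ValidationError
from .incremental import GroupSummary, incremental, judge_willingness_to_pay
from .qaly import build_trajectory, qaly_auc
from .questionnaires import (
    LUTSQOL_ITEM_NAMES,
    QuestionnaireResponse,
    UtilityIndexConfig,
    response_utility,
    score_lutsqol,
)
from .sensitivity import Scenario, default_scenarios, run_sensitivity

#: Swedish "low incremental cost" threshold, 100,000 SEK at the 2013 rate.
DEFAULT_WTP_THRESHOLD = 11_200.0


@dataclass(frozen=True)
class AnalysisSettings:
    horizon: float = 1.0
    t_followup: float = 0.25
    aids_timepoint: str = "baseline"  # cost-table footnote: aids from baseline
    intervention_arm: str = "app"
    comparator_arm: str = "control"
    wtp_threshold: float = DEFAULT_WTP_THRESHOLD


def response_from_row(row: Mapping) -> QuestionnaireResponse | None:
    """Build a response from a table row; None when any QoL item is missing."""
    items = {}
    for name in LUTSQOL_ITEM_NAMES:
        v = row[name]
        if pd.isna(v):
            return None
        items[name] = int(v)
    uisf = None
    if all(pd.notna(row[c]) for c in ("uisf_freq", "uisf_amount", "uisf_impact")):
        uisf = (int(row["uisf_freq"]), int(row["uisf_amount"]), int(row["uisf_impact"]))
    return QuestionnaireResponse(
        participant_id=str(row["participant_id"]),
        timepoint=str(row["timepoint"]),
        lutsqol_items=items,
        uisf_items=uisf,
    )


@dataclass(frozen=True)
class ArmAnalysis:
    """Completer arm means feeding the incremental analysis."""

    arm: str
    n_completers: int
    n_qol_analyzable: int
    mean_breakdown: CostBreakdown
    mean_annual_amounts: dict[str, float]
    mean_utility_baseline: float
    mean_utility_followup: float
    mean_qaly_total: float
    mean_qaly_gain: float


def analyze_arm(
    df: pd.DataFrame,
    arm: str,
    utility_config: UtilityIndexConfig,
    prices: PriceConfig,
    policy: AnnualizationPolicy,
    settings: AnalysisSettings,
) -> ArmAnalysis:
    """Per-participant costs and QALYs for one arm, averaged over completers."""
    sub = df[df["arm"] == arm]
    base = sub[sub["timepoint"] == "baseline"].set_index("participant_id")
    fu = sub[sub["timepoint"] == "month3"].set_index("participant_id")
    completers = [pid for pid in base.index if pid in fu.index]
    if not completers:
        raise ValidationError(f"arm {arm!r} has no completers")

    breakdowns = []
    amounts = {"pfmt_hours": [], "laundry_hours": [], "aids": [], "laundry_loads": []}
    for pid in completers:
        aids_source = base if settings.aids_timepoint == "baseline" else fu
        resource = ResourceUse(
            pfmt_hours_4wk=float(fu.loc[pid, "pfmt_hours_4wk"]),
            laundry_hours_4wk=float(fu.loc[pid, "laundry_hours_4wk"]),
            aids_4wk=float(aids_source.loc[pid, "aids_4wk"]),
            laundry_loads_4wk=float(fu.loc[pid, "laundry_loads_4wk"]),
        )
        breakdowns.append(
            total_annual_cost(resource, policy, str(base.loc[pid, "education"]), prices)
        )
        amounts["pfmt_hours"].append(annualize_pfmt(resource.pfmt_hours_4wk, policy))
        amounts["laundry_hours"].append(
            annualize_constant(resource.laundry_hours_4wk, policy.periods_per_year)
        )
        amounts["aids"].append(
            annualize_constant(resource.aids_4wk, policy.periods_per_year)
        )
        amounts["laundry_loads"].append(
            annualize_constant(resource.laundry_loads_4wk, policy.periods_per_year)
        )
    mean_breakdown = CostBreakdown(
        **{
            name: float(np.mean([getattr(b, name) for b in breakdowns]))
            for name in COST_COMPONENTS
        }
    )

    u0s, u1s, gains, totals = [], [], [], []
    for pid in completers:
        r0 = response_from_row({"participant_id": pid, **base.loc[pid].to_dict()})
        r1 = response_from_row({"participant_id": pid, **fu.loc[pid].to_dict()})
        if r0 is None or r1 is None:
            continue  # QoL-incomplete completer: excluded from the utility analysis
        u0 = response_utility(r0, utility_config)
        u1 = response_utility(r1, utility_config)
        res = qaly_auc(
            build_trajectory(u0, u1, settings.t_followup, settings.horizon)
        )
        u0s.append(u0)
        u1s.append(u1)
        gains.append(res.qaly_gain)
        totals.append(res.qaly_total)
    if not gains:
        raise ValidationError(f"arm {arm!r} has no QoL-analyzable completers")

    return ArmAnalysis(
        arm=arm,
        n_completers=len(completers),
        n_qol_analyzable=len(gains),
        mean_breakdown=mean_breakdown,
        mean_annual_amounts={k: float(np.mean(v)) for k, v in amounts.items()},
        mean_utility_baseline=float(np.mean(u0s)),
        mean_utility_followup=float(np.mean(u1s)),
        mean_qaly_total=float(np.mean(totals)),
        mean_qaly_gain=float(np.mean(gains)),
    )


@dataclass(frozen=True)
class GroupMeanInputs:
    """Arm-level inputs reproducing a published deterministic analysis.

    Exactly one of ``annual_amounts`` (priced through the cost model) or
    ``component_costs`` (euro components taken as given) must be supplied.
    """

    qaly_gains: Mapping[str, float]
    annual_amounts: Mapping[str, Mapping[str, float]] | None = None
    component_costs: Mapping[str, Mapping[str, float]] | None = None
    education_stratum: str = "university_3plus"

    def __post_init__(self) -> None:
        if (self.annual_amounts is None) == (self.component_costs is None):
            raise ValidationError(
                "supply exactly one of annual_amounts or component_costs"
            )

    def breakdowns(self, prices: PriceConfig) -> dict[str, CostBreakdown]:
        out = {}
        if self.annual_amounts is not None:
            for arm, a in self.annual_amounts.items():
                out[arm] = breakdown_from_annual_amounts(
                    pfmt_hours=a["pfmt_hours"],
                    laundry_hours=a["laundry_hours"],
                    aids=a["aids"],
                    laundry_loads=a["laundry_loads"],
                    prices=prices,
                    education_stratum=self.education_stratum,
                )
        else:
            for arm, comps in self.component_costs.items():
                out[arm] = breakdown_from_costs(comps)
        return out


def _cost_table_records(
    breakdowns: Mapping[str, CostBreakdown],
    amounts: Mapping[str, Mapping[str, float]] | None,
    prices: PriceConfig,
    intervention: str,
    comparator: str,
) -> list[dict]:
    """Cost-table rows: component, price per unit, per-arm amounts and costs."""
    amount_key = {
        "pfmt_time": "pfmt_hours",
        "laundry_time": "laundry_hours",
        "aids": "aids",
        "laundry_loads": "laundry_loads",
    }
    unit_price = {
        "assessment": prices.assessment_cost,
        "treatment_delivery": 0.0,
        "pfmt_time": prices.wage_by_education.get("university_3plus"),
        "laundry_time": prices.wage_by_education.get("university_3plus"),
        "aids": prices.aid_unit_price,
        "laundry_loads": prices.laundry_load_price,
    }
    rows = []
    for comp in COST_COMPONENTS:
        row = {
            "component": comp,
            "price_per_unit": unit_price[comp],
            f"amount_{intervention}": None,
            f"amount_{comparator}": None,
            f"cost_{intervention}": getattr(breakdowns[intervention], comp),
            f"cost_{comparator}": getattr(breakdowns[comparator], comp),
        }
        if comp == "assessment":
            row[f"amount_{intervention}"] = row[f"amount_{comparator}"] = 1.0
        elif amounts is not None and comp in amount_key:
            row[f"amount_{intervention}"] = amounts[intervention][amount_key[comp]]
            row[f"amount_{comparator}"] = amounts[comparator][amount_key[comp]]
        rows.append(row)
    rows.append(
        {
            "component": "total",
            "price_per_unit": None,
            f"amount_{intervention}": None,
            f"amount_{comparator}": None,
            f"cost_{intervention}": breakdowns[intervention].total,
            f"cost_{comparator}": breakdowns[comparator].total,
        }
    )
    return rows


def run_cua(
    participants: pd.DataFrame | None = None,
    group_means: GroupMeanInputs | None = None,
    utility_config: UtilityIndexConfig | None = None,
    prices: PriceConfig | None = None,
    policies: Mapping[str, AnnualizationPolicy] | None = None,
    scenarios: Sequence[Scenario] | None = None,
    settings: AnalysisSettings | None = None,
) -> dict:
    """Run the full cost-utility analysis and return a JSON-serializable report."""
    settings = settings or AnalysisSettings()
    prices = prices or PriceConfig()
    policies = policies or default_policies()
    scenarios = list(scenarios) if scenarios is not None else default_scenarios()
    iv, cp = settings.intervention_arm, settings.comparator_arm

    if (participants is None) == (group_means is None):
        raise ValidationError("supply exactly one of participants or group_means")

    qaly_diag: dict[str, dict] = {}
    if participants is not None:
        if utility_config is None:
            raise ValidationError("participant mode requires a utility_config")
        arms = {
            arm: analyze_arm(
                participants, arm, utility_config, prices, policies[arm], settings
            )
            for arm in (iv, cp)
        }
        breakdowns = {arm: a.mean_breakdown for arm, a in arms.items()}
        gains = {arm: a.mean_qaly_gain for arm, a in arms.items()}
        amounts = {arm: a.mean_annual_amounts for arm, a in arms.items()}
        for arm, a in arms.items():
            traj = build_trajectory(
                a.mean_utility_baseline,
                a.mean_utility_followup,
                settings.t_followup,
                settings.horizon,
            )
            res = qaly_auc(traj)
            qaly_diag[arm] = {
                "n_completers": a.n_completers,
                "n_qol_analyzable": a.n_qol_analyzable,
                "mean_utility_baseline": a.mean_utility_baseline,
                "mean_utility_followup": a.mean_utility_followup,
                "trajectory_points": [
                    [t, u] for t, u in zip(traj.times, traj.utilities)
                ],
                "mean_qaly_total": a.mean_qaly_total,
                "mean_qaly_gain": a.mean_qaly_gain,
                "days_equivalent": a.mean_qaly_gain * 365.25,
            }
        mode = "participant"
    else:
        breakdowns = group_means.breakdowns(prices)
        gains = dict(group_means.qaly_gains)
        amounts = (
            {a: dict(v) for a, v in group_means.annual_amounts.items()}
            if group_means.annual_amounts is not None
            else None
        )
        for arm in (iv, cp):
            qaly_diag[arm] = {
                "mean_qaly_gain": gains[arm],
                "days_equivalent": gains[arm] * 365.25,
            }
        mode = "group_mean"

    base_result = incremental(
        GroupSummary(iv, breakdowns[iv].total, gains[iv]),
        GroupSummary(cp, breakdowns[cp].total, gains[cp]),
    )
    table = run_sensitivity(
        breakdowns[iv], breakdowns[cp], gains[iv], gains[cp], scenarios, iv, cp
    )

    report = {
        "mode": mode,
        "settings": {
            "horizon_years": settings.horizon,
            "t_followup_years": settings.t_followup,
            "intervention_arm": iv,
            "comparator_arm": cp,
            "wtp_threshold_eur_per_qaly": settings.wtp_threshold,
        },
        "cost_table": _cost_table_records(breakdowns, amounts, prices, iv, cp),
        "arms": {
            arm: {
                "total_cost": breakdowns[arm].total,
                "components": breakdowns[arm].as_dict(),
                "qaly_gain": gains[arm],
            }
            for arm in (iv, cp)
        },
        "incremental": {
            "delta_cost": base_result.delta_cost,
            "delta_qaly": base_result.delta_qaly,
            "icer": base_result.icer,
            "quadrant": base_result.quadrant,
            "note": base_result.note,
            "acceptable_at_threshold": judge_willingness_to_pay(
                base_result, settings.wtp_threshold
            ),
        },
        "sensitivity": [
            {
                "scenario": r.scenario,
                f"cost_{iv}": r.cost_intervention,
                f"cost_{cp}": r.cost_comparator,
                "delta_cost": r.result.delta_cost,
                "delta_qaly": r.result.delta_qaly,
                "icer": r.result.icer,
                "quadrant": r.result.quadrant,
            }
            for r in table.rows
        ],
        "qaly_diagnostics": qaly_diag,
    }
    return _jsonify(report)


def _jsonify(obj):
    """Coerce numpy scalars so the report is plain-JSON round-trippable."""
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_report(report: dict, outdir) -> dict[str, Path]:
    """Write the machine-readable JSON plus display-rounded CSV tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    json_path = outdir / "report.json"
    json_path.write_text(json.dumps(report, indent=2))
    paths["json"] = json_path

    iv = report["settings"]["intervention_arm"]
    cp = report["settings"]["comparator_arm"]

    cost = pd.DataFrame(report["cost_table"])
    for col in (f"cost_{iv}", f"cost_{cp}"):
        cost[col] = cost[col].round(1)
    cost_path = outdir / "cost_table.csv"
    cost.to_csv(cost_path, index=False)
    paths["cost_table"] = cost_path

    inc = report["incremental"]
    inc_df = pd.DataFrame(
        [
            {
                "group": cp,
                "total_cost": round(report["arms"][cp]["total_cost"], 1),
                "qaly_gain": round(report["arms"][cp]["qaly_gain"], 5),
            },
            {
                "group": iv,
                "total_cost": round(report["arms"][iv]["total_cost"], 1),
                "qaly_gain": round(report["arms"][iv]["qaly_gain"], 5),
            },
            {
                "group": f"{iv} vs {cp}",
                "delta_cost": round(inc["delta_cost"], 1),
                "delta_qaly": round(inc["delta_qaly"], 5),
                "icer": None if inc["icer"] is None else round(inc["icer"], 1),
            },
        ]
    )
    inc_path = outdir / "incremental_table.csv"
    inc_df.to_csv(inc_path, index=False)
    paths["incremental_table"] = inc_path

    sens = pd.DataFrame(report["sensitivity"])
    for col in (f"cost_{iv}", f"cost_{cp}", "delta_cost", "icer"):
        sens[col] = sens[col].round(1)
    sens["delta_qaly"] = sens["delta_qaly"].round(5)
    sens_path = outdir / "sensitivity_table.csv"
    sens.to_csv(sens_path, index=False)
    paths["sensitivity_table"] = sens_path
    return paths
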