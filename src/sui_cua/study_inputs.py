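"""Arm-level inputs of the evaluated trial, as printed in its cost table.

These are *inputs* to the group-mean analysis mode: unit prices, arm-mean
annual amounts, the per-component euro costs, and the arm QALY gains.  The
pipeline recomputes totals, deltas, and ICERs from them; no result quantity
is stored here.
"""

from __future__ import annotations

from .costs import PriceConfig
from .pipeline import GroupMeanInputs

#: Arm-mean annual resource amounts (hours of training/laundry, aid and
#: laundry-load counts) — the "Amount used" columns of the cost table.
ANNUAL_AMOUNTS: dict[str, dict[str, float]] = {
    "app": {
        "pfmt_hours": 15.66,
        "laundry_hours": 1.30,
        "aids": 114.40,
        "laundry_loads": 10.40,
    },
    "control": {
        "pfmt_hours": 9.91,
        "laundry_hours": 3.38,
        "aids": 169.60,
        "laundry_loads": 27.04,
    },
}

#: Per-component annual euro costs as printed (1 decimal).
COMPONENT_COSTS: dict[str, dict[str, float]] = {
    "app": {
        "assessment": 6.4,
        "treatment_delivery": 0.0,
        "pfmt_time": 463.7,
        "laundry_time": 38.5,
        "aids": 15.4,
        "laundry_loads": 23.0,
    },
    "control": {
        "assessment": 6.4,
        "treatment_delivery": 0.0,
        "pfmt_time": 293.4,
        "laundry_time": 100.1,
        "aids": 22.7,
        "laundry_loads": 59.8,
    },
}

#: Annual QALY gains per arm (area-under-the-curve, 1-year horizon).
QALY_GAINS: dict[str, float] = {"app": 0.01006, "control": 0.00158}


def default_prices() -> PriceConfig:
    """The trial's unit prices (2013 euro): assessment 6.4, wage 29.61/h,
    aids 0.134/unit, laundry loads 2.21/load."""
    return PriceConfig()


def amounts_mode_inputs() -> GroupMeanInputs:
    """Group-mean inputs in "amount used" mode (amounts priced by the cost model)."""
    return GroupMeanInputs(qaly_gains=QALY_GAINS, annual_amounts=ANNUAL_AMOUNTS)


def cost_mode_inputs() -> GroupMeanInputs:
    """Group-mean inputs taking the printed per-component euro costs as given."""
    return GroupMeanInputs(qaly_gains=QALY_GAINS, component_costs=COMPONENT_COSTS)
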