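"""Incremental cost-effectiveness: ΔCost, ΔQALY, the ICER, and dominance.

The ICER is ΔCost/ΔQALY between the intervention and the comparator.  The
sign pair of the deltas places the result on the cost-effectiveness plane:

* NE — more costly, more effective: the ICER is the price of a QALY.
* SE — cheaper, more effective: the intervention dominates.
* NW — more costly, less effective: the intervention is dominated.
* SW — cheaper, less effective: the ICER is the saving per QALY forgone.

A negative ICER is ambiguous between SE and NW, so dominance is always
reported alongside the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

QUADRANTS = ("NE", "SE", "NW", "SW")


@dataclass(frozen=True)
class GroupSummary:
    """One arm's mean annual cost and mean annual QALY gain per participant."""

    arm: str
    mean_cost: float
    mean_qaly_gain: float

    def __post_init__(self) -> None:
        if self.mean_cost < 0:
            raise ValidationError(f"mean_cost must be >= 0, got {self.mean_cost}")
        if abs(self.mean_qaly_gain) > 1.0:
            raise ValidationError(
                f"|mean_qaly_gain| must be <= 1 year, got {self.mean_qaly_gain}"
            )


@dataclass(frozen=True)
class IncrementalResult:
    """Deltas, the ICER (None when ΔQALY = 0), the plane quadrant, and a sign note."""

    delta_cost: float
    delta_qaly: float
    icer: float | None
    quadrant: str
    note: str = ""

    @property
    def dominant(self) -> bool:
        return self.quadrant == "SE"

    @property
    def dominated(self) -> bool:
        return self.quadrant == "NW"


def _quadrant(delta_cost: float, delta_qaly: float) -> str:
    # Boundary convention: a zero delta counts as "not more costly" /
    # "not more effective", so identical arms land in SW.
    if delta_qaly > 0:
        return "NE" if delta_cost > 0 else "SE"
    return "NW" if delta_cost > 0 else "SW"


def incremental(
    intervention: GroupSummary, comparator: GroupSummary
) -> IncrementalResult:
    """Incremental result of the intervention vs. the comparator."""
    delta_cost = intervention.mean_cost - comparator.mean_cost
    delta_qaly = intervention.mean_qaly_gain - comparator.mean_qaly_gain
    quadrant = _quadrant(delta_cost, delta_qaly)
    if delta_qaly == 0.0:
        icer = None
        note = "ICER undefined: zero QALY difference"
    else:
        icer = delta_cost / delta_qaly
        note = ""
        if icer < 0:
            note = (
                "negative ICER: intervention dominates (cheaper, more effective)"
                if quadrant == "SE"
                else "negative ICER: intervention dominated (costlier, less effective)"
            )
    return IncrementalResult(
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        icer=icer,
        quadrant=quadrant,
        note=note,
    )


def judge_willingness_to_pay(result: IncrementalResult, threshold: float) -> bool:
    """Is the intervention acceptable at a willingness-to-pay threshold (€/QALY)?

    SE (dominant) is always acceptable and NW (dominated) never.  In NE the
    ICER must not exceed the threshold; in SW the saving per QALY forgone
    must be at least the threshold (the symmetric rule).
    """
    if threshold <= 0:
        raise ValidationError(f"threshold must be > 0, got {threshold}")
    if result.quadrant == "SE":
        return True
    if result.quadrant == "NW":
        return False
    if result.icer is None:
        # Zero QALY difference: decided on cost alone.
        return result.delta_cost <= 0
    if result.quadrant == "NE":
        return result.icer <= threshold
    return result.icer >= threshold  # SW: ratio of two negatives
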