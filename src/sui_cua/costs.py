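"""Annual societal cost model: unit prices, wages, and arm-specific annualization.

Resource use is self-reported over the last 4 weeks before the 3-month
follow-up.  Everything except the intervention arm's training time is assumed
to stay constant over the year, so 4-week quantities scale by 365.25/28.
The intervention arm trains at the prescribed rate (3 sessions/day) during
the 3 treatment months and is assumed to drop to the prescribed maintenance
rate (2-3 sessions/week) afterwards, so its reported training time is scaled
by the session-rate ratio over the post-treatment months.

Participants' time is valued at the gross hourly wage of Swedish women with
the same educational level (societal perspective); goods at per-unit prices.
All prices are 2013 year-end euro (1 EUR = 8.94 SEK).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

from .errors import ConfigError, ValidationError

#: 4-week periods per year: the annualization factor for quantities assumed constant.
FOUR_WEEK_PERIODS_PER_YEAR = 365.25 / 28.0

SEK_PER_EUR_2013 = 8.94

#: Ordered cost components of a breakdown (field names of :class:`CostBreakdown`).
COST_COMPONENTS = (
    "assessment",
    "treatment_delivery",
    "pfmt_time",
    "laundry_time",
    "aids",
    "laundry_loads",
)

ARMS = ("app", "control")

DEFAULT_WAGE_EUR_PER_HOUR = 29.61
DEFAULT_ASSESSMENT_COST = 6.4
DEFAULT_AID_UNIT_PRICE = 0.134
DEFAULT_LAUNDRY_LOAD_PRICE = 2.21


@dataclass(frozen=True)
class PriceConfig:
    """Unit prices and the education-stratified wage table (2013 euro)."""

    assessment_cost: float = DEFAULT_ASSESSMENT_COST
    wage_by_education: Mapping[str, float] = field(
        default_factory=lambda: {
            # The source trial reports a single mean wage; both strata default
            # to it and real stratified wages can be supplied from config.
            "university_3plus": DEFAULT_WAGE_EUR_PER_HOUR,
            "other": DEFAULT_WAGE_EUR_PER_HOUR,
        }
    )
    aid_unit_price: float = DEFAULT_AID_UNIT_PRICE
    laundry_load_price: float = DEFAULT_LAUNDRY_LOAD_PRICE
    currency_note: str = f"2013 year-end EUR; 1 EUR = {SEK_PER_EUR_2013} SEK"

    def __post_init__(self) -> None:
        for name, value in (
            ("assessment_cost", self.assessment_cost),
            ("aid_unit_price", self.aid_unit_price),
            ("laundry_load_price", self.laundry_load_price),
        ):
            if value < 0:
                raise ConfigError(f"{name} must be >= 0, got {value}")
        for stratum, wage in self.wage_by_education.items():
            if wage < 0:
                raise ConfigError(f"wage for {stratum!r} must be >= 0, got {wage}")

    def wage(self, education_stratum: str) -> float:
        try:
            return self.wage_by_education[education_stratum]
        except KeyError:
            raise ConfigError(
                f"unknown education stratum {education_stratum!r}; "
                f"known: {sorted(self.wage_by_education)}"
            ) from None


@dataclass(frozen=True)
class ResourceUse:
    """Self-reported resource use over the last 4 weeks."""

    pfmt_hours_4wk: float
    laundry_hours_4wk: float
    aids_4wk: float
    laundry_loads_4wk: float

    def __post_init__(self) -> None:
        for name in (
            "pfmt_hours_4wk",
            "laundry_hours_4wk",
            "aids_4wk",
            "laundry_loads_4wk",
        ):
            value = getattr(self, name)
            if value < 0:
                raise ValidationError(f"{name} must be >= 0, got {value}")


@dataclass(frozen=True)
class AnnualizationPolicy:
    """How 4-week quantities extend to a year for one trial arm.

    The control arm's training time is held constant.  The intervention
    ("app") arm trains at ``sessions_per_week_treatment`` during the
    ``treatment_months`` treatment period and is assumed to follow the
    maintenance prescription of ``sessions_per_week_maintenance`` afterwards,
    scaling its reported time by the session-rate ratio for the remaining
    months.
    """

    arm: str
    treatment_months: float = 3.0
    sessions_per_week_treatment: float = 21.0  # 3 per day
    sessions_per_week_maintenance: float = 2.5  # "2 or 3 per week"
    periods_per_year: float = FOUR_WEEK_PERIODS_PER_YEAR

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ConfigError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if not 0 < self.treatment_months <= 12:
            raise ConfigError(
                f"treatment_months must lie in (0, 12], got {self.treatment_months}"
            )
        for name in ("sessions_per_week_treatment", "sessions_per_week_maintenance"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.periods_per_year <= 0:
            raise ConfigError("periods_per_year must be > 0")

    @property
    def pfmt_annualization_factor(self) -> float:
        """Multiplier taking 4-week training hours to annual hours."""
        if self.arm == "control":
            return self.periods_per_year
        f_treat = self.treatment_months / 12.0
        maintenance_ratio = (
            self.sessions_per_week_maintenance / self.sessions_per_week_treatment
        )
        return self.periods_per_year * (f_treat + (1.0 - f_treat) * maintenance_ratio)


def default_policies() -> dict[str, AnnualizationPolicy]:
    return {arm: AnnualizationPolicy(arm=arm) for arm in ARMS}


def annualize_pfmt(hours_4wk: float, policy: AnnualizationPolicy) -> float:
    """Annual training hours under the arm's annualization rule."""
    if hours_4wk < 0:
        raise ValidationError(f"hours_4wk must be >= 0, got {hours_4wk}")
    return hours_4wk * policy.pfmt_annualization_factor


def annualize_constant(
    quantity_4wk: float, periods_per_year: float = FOUR_WEEK_PERIODS_PER_YEAR
) -> float:
    """Annual quantity assuming the 4-week level stays constant all year."""
    if quantity_4wk < 0:
        raise ValidationError(f"quantity_4wk must be >= 0, got {quantity_4wk}")
    return quantity_4wk * periods_per_year


def time_cost(
    annual_hours: float, education_stratum: str, prices: PriceConfig
) -> float:
    """Euro value of a participant's time at the stratum's gross hourly wage."""
    return annual_hours * prices.wage(education_stratum)


def goods_cost(annual_units: float, unit_price: float) -> float:
    """Euro cost of consumed goods."""
    if annual_units < 0 or unit_price < 0:
        raise ValidationError("units and price must be >= 0")
    return annual_units * unit_price


@dataclass(frozen=True)
class CostBreakdown:
    """Per-component annual euro costs.  ``total`` is always the component sum."""

    assessment: float
    treatment_delivery: float
    pfmt_time: float
    laundry_time: float
    aids: float
    laundry_loads: float

    def __post_init__(self) -> None:
        for name in COST_COMPONENTS:
            if getattr(self, name) < 0:
                raise ValidationError(f"cost component {name} must be >= 0")

    @property
    def total(self) -> float:
        return sum(getattr(self, name) for name in COST_COMPONENTS)

    def with_component(self, name: str, value: float) -> "CostBreakdown":
        if name not in COST_COMPONENTS:
            raise ConfigError(
                f"unknown cost component {name!r}; known: {COST_COMPONENTS}"
            )
        return replace(self, **{name: value})

    def as_dict(self) -> dict[str, float]:
        d = {name: getattr(self, name) for name in COST_COMPONENTS}
        d["total"] = self.total
        return d


def total_annual_cost(
    resource: ResourceUse,
    policy: AnnualizationPolicy,
    education_stratum: str,
    prices: PriceConfig,
) -> CostBreakdown:
    """Annual societal cost breakdown for one participant.

    Assessment is a fixed per-participant cost; no treatment-delivery costs
    were identified for the app, so that component is identically zero.
    """
    annual_pfmt_h = annualize_pfmt(resource.pfmt_hours_4wk, policy)
    annual_laundry_h = annualize_constant(
        resource.laundry_hours_4wk, policy.periods_per_year
    )
    annual_aids = annualize_constant(resource.aids_4wk, policy.periods_per_year)
    annual_loads = annualize_constant(
        resource.laundry_loads_4wk, policy.periods_per_year
    )
    return CostBreakdown(
        assessment=prices.assessment_cost,
        treatment_delivery=0.0,
        pfmt_time=time_cost(annual_pfmt_h, education_stratum, prices),
        laundry_time=time_cost(annual_laundry_h, education_stratum, prices),
        aids=goods_cost(annual_aids, prices.aid_unit_price),
        laundry_loads=goods_cost(annual_loads, prices.laundry_load_price),
    )


def breakdown_from_annual_amounts(
    pfmt_hours: float,
    laundry_hours: float,
    aids: float,
    laundry_loads: float,
    prices: PriceConfig,
    education_stratum: str = "university_3plus",
) -> CostBreakdown:
    """Group-mean "amount used" mode: annual amounts priced directly.

    Mirrors the published cost-table layout where arm-mean annual amounts and
    unit prices are reported; no annualization is applied.
    """
    return CostBreakdown(
        assessment=prices.assessment_cost,
        treatment_delivery=0.0,
        pfmt_time=time_cost(pfmt_hours, education_stratum, prices),
        laundry_time=time_cost(laundry_hours, education_stratum, prices),
        aids=goods_cost(aids, prices.aid_unit_price),
        laundry_loads=goods_cost(laundry_loads, prices.laundry_load_price),
    )


def breakdown_from_costs(components: Mapping[str, float]) -> CostBreakdown:
    """Group-mean cost mode: per-component euro costs supplied directly.

    Unlisted components default to 0; a ``total`` key, if present, is checked
    against the component sum within rounding slack (0.5 euro, i.e. printed
    1-decimal components).
    """
    unknown = set(components) - set(COST_COMPONENTS) - {"total"}
    if unknown:
        raise ConfigError(f"unknown cost component(s): {sorted(unknown)}")
    values = {name: float(components.get(name, 0.0)) for name in COST_COMPONENTS}
    bd = CostBreakdown(**values)
    if "total" in components and abs(bd.total - float(components["total"])) > 0.5:
        raise ValidationError(
            f"declared total {components['total']} inconsistent with "
            f"component sum {bd.total:.4f}"
        )
    return bd
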