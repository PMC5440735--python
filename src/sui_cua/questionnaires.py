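"""Scoring of the two incontinence questionnaires and the preference-based utility index.

Two instruments are handled:

* ICIQ-UI SF — three items (leakage frequency, amount, overall impact on
  everyday life) summing to a 0-21 severity score, banded into
  none / slight / moderate / severe / very severe.
* ICIQ-LUTSqol — nineteen condition-specific quality-of-life items, each
  scored 1-4 (higher = more impact), overall score 19-76.

A preference-based index maps nine of the nineteen LUTSqol items to a
"health state" and then to a utility weight in [0, 1] by subtracting
per-item, per-level decrements from a base value.  The published
coefficients of that index are not reproduced here; the shipped default is
an explicitly labelled placeholder and real coefficients are supplied via
:class:`UtilityIndexConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ConfigError, ValidationError

N_LUTSQOL_ITEMS = 19
LUTSQOL_ITEM_NAMES: tuple[str, ...] = tuple(f"item{i:02d}" for i in range(1, 20))
LUTSQOL_MIN_LEVEL = 1
LUTSQOL_MAX_LEVEL = 4
LUTSQOL_MIN_SCORE = N_LUTSQOL_ITEMS * LUTSQOL_MIN_LEVEL  # 19
LUTSQOL_MAX_SCORE = N_LUTSQOL_ITEMS * LUTSQOL_MAX_LEVEL  # 76

#: Per-item maxima of the ICIQ-UI SF (frequency, amount, impact).
UISF_ITEM_MAXIMA: tuple[int, int, int] = (5, 6, 10)
UISF_MAX_SCORE = sum(UISF_ITEM_MAXIMA)  # 21

#: Severity bands on the ICIQ-UI SF total; a total of 0 is "none".
SEVERITY_BANDS: tuple[tuple[int, int, str], ...] = (
    (0, 0, "none"),
    (1, 5, "slight"),
    (6, 12, "moderate"),
    (13, 18, "severe"),
    (19, 21, "very severe"),
)

TIMEPOINTS = ("baseline", "month3")


@dataclass(frozen=True)
class QuestionnaireResponse:
    """One participant's questionnaire answers at one timepoint.

    ``lutsqol_items`` maps item names (``item01`` .. ``item19``) to integer
    levels 1-4.  ``uisf_items`` optionally carries the three ICIQ-UI SF
    answers as ``(frequency, amount, qol_impact)``.
    """

    participant_id: str
    timepoint: str
    lutsqol_items: Mapping[str, int]
    uisf_items: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(
                f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}"
            )
        missing = [n for n in LUTSQOL_ITEM_NAMES if n not in self.lutsqol_items]
        if missing:
            raise ValidationError(f"missing LUTSqol item(s): {', '.join(missing)}")
        extra = set(self.lutsqol_items) - set(LUTSQOL_ITEM_NAMES)
        if extra:
            raise ValidationError(f"unknown LUTSqol item(s): {sorted(extra)}")
        for name in LUTSQOL_ITEM_NAMES:
            level = self.lutsqol_items[name]
            if not isinstance(level, (int,)) or isinstance(level, bool):
                raise ValidationError(f"{name}: level must be an integer, got {level!r}")
            if not LUTSQOL_MIN_LEVEL <= level <= LUTSQOL_MAX_LEVEL:
                raise ValidationError(
                    f"{name}: level {level} outside "
                    f"[{LUTSQOL_MIN_LEVEL}, {LUTSQOL_MAX_LEVEL}]"
                )
        if self.uisf_items is not None:
            score_uisf(*self.uisf_items)  # validates ranges


def score_lutsqol(response: QuestionnaireResponse) -> int:
    """Overall ICIQ-LUTSqol score: the sum of the 19 item levels (19-76)."""
    return int(sum(response.lutsqol_items[n] for n in LUTSQOL_ITEM_NAMES))


def score_uisf(
    frequency: int,
    amount: int,
    qol_impact: int,
    maxima: tuple[int, int, int] = UISF_ITEM_MAXIMA,
) -> int:
    """Total ICIQ-UI SF score: sum of the three items, in [0, 21]."""
    names = ("frequency", "amount", "qol_impact")
    for name, value, upper in zip(names, (frequency, amount, qol_impact), maxima):
        if not isinstance(value, int) or isinstance(value, bool):
            raise ValidationError(f"uisf {name}: must be an integer, got {value!r}")
        if not 0 <= value <= upper:
            raise ValidationError(f"uisf {name}: {value} outside [0, {upper}]")
    return frequency + amount + qol_impact


def categorize_severity(uisf_total: int) -> str:
    """Severity band of an ICIQ-UI SF total (none/slight/moderate/severe/very severe)."""
    if not 0 <= uisf_total <= UISF_MAX_SCORE:
        raise ValidationError(
            f"ICIQ-UI SF total {uisf_total} outside [0, {UISF_MAX_SCORE}]"
        )
    for lo, hi, label in SEVERITY_BANDS:
        if lo <= uisf_total <= hi:
            return label
    raise AssertionError("severity bands are exhaustive")  # pragma: no cover


@dataclass(frozen=True)
class UtilityIndexConfig:
    """Coefficients of the preference-based utility index.

    The index selects nine LUTSqol items as a health-state classification and
    computes ``u = max(clamp_floor, base_value - sum of decrements)``, one
    decrement per (item, level).  Decrements at level 1 are zero and must be
    non-decreasing with level so that utility is monotone non-increasing in
    every item.
    """

    selected_items: tuple[str, ...]
    base_value: float
    decrements: Mapping[str, Mapping[int, float]]
    clamp_floor: float = 0.0
    name: str = "custom"

    def __post_init__(self) -> None:
        if len(self.selected_items) != 9:
            raise ConfigError(
                f"exactly 9 selected items required, got {len(self.selected_items)}"
            )
        if len(set(self.selected_items)) != 9:
            raise ConfigError("selected items must be distinct")
        unknown = set(self.selected_items) - set(LUTSQOL_ITEM_NAMES)
        if unknown:
            raise ConfigError(f"unknown LUTSqol item(s) in selection: {sorted(unknown)}")
        if self.base_value > 1.0:
            raise ConfigError(f"base_value must be <= 1, got {self.base_value}")
        if self.clamp_floor < 0.0:
            raise ConfigError(f"clamp_floor must be >= 0, got {self.clamp_floor}")
        for item in self.selected_items:
            if item not in self.decrements:
                raise ConfigError(f"no decrements declared for {item}")
            per_level = self.decrements[item]
            prev = None
            for level in range(LUTSQOL_MIN_LEVEL, LUTSQOL_MAX_LEVEL + 1):
                if level not in per_level:
                    raise ConfigError(f"{item}: missing decrement for level {level}")
                d = per_level[level]
                if d < 0:
                    raise ConfigError(f"{item} level {level}: negative decrement {d}")
                if prev is not None and d < prev:
                    raise ConfigError(
                        f"{item}: decrements must be non-decreasing with level"
                    )
                prev = d
            if per_level[LUTSQOL_MIN_LEVEL] != 0:
                raise ConfigError(f"{item}: decrement at level 1 must be 0")


@dataclass(frozen=True)
class HealthState:
    """Nine item levels, in the item order of the generating config."""

    levels: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.levels) != 9:
            raise ValidationError(f"health state needs 9 levels, got {len(self.levels)}")
        for level in self.levels:
            if not LUTSQOL_MIN_LEVEL <= level <= LUTSQOL_MAX_LEVEL:
                raise ValidationError(f"health-state level {level} outside [1, 4]")


def classify_health_state(
    response: QuestionnaireResponse, config: UtilityIndexConfig
) -> HealthState:
    """Project a LUTSqol response onto the config's nine selected items."""
    try:
        levels = tuple(response.lutsqol_items[item] for item in config.selected_items)
    except KeyError as exc:  # pragma: no cover - responses always carry all 19
        raise ValidationError(f"response lacks selected item {exc}") from exc
    return HealthState(levels)


def utility_weight(state: HealthState, config: UtilityIndexConfig) -> float:
    """Utility weight of a health state: base value minus decrements, clamped to [0, 1]."""
    total_decrement = sum(
        config.decrements[item][level]
        for item, level in zip(config.selected_items, state.levels)
    )
    u = max(config.clamp_floor, config.base_value - total_decrement)
    return min(u, 1.0)


def response_utility(
    response: QuestionnaireResponse, config: UtilityIndexConfig
) -> float:
    """Convenience: classify and weight in one step."""
    return utility_weight(classify_health_state(response, config), config)


def placeholder_utility_config() -> UtilityIndexConfig:
    """PLACEHOLDER coefficient set, not the published preference index.

    Selects items 3-11 (daily-life domains) with a uniform decrement ladder.
    It exists so the pipeline runs end-to-end; substantive analyses must load
    the real coefficients from file.
    """
    items = tuple(f"item{i:02d}" for i in range(3, 12))
    ladder = {1: 0.0, 2: 0.010, 3: 0.025, 4: 0.045}
    return UtilityIndexConfig(
        selected_items=items,
        base_value=1.0,
        decrements={item: dict(ladder) for item in items},
        clamp_floor=0.0,
        name="placeholder",
    )


def uniform_step_utility_config(
    selected_items: Sequence[str],
    step: float,
    base_value: float = 0.95,
    clamp_floor: float = 0.0,
    name: str = "uniform-step",
) -> UtilityIndexConfig:
    """Index where every one-level increase on any selected item costs ``step``."""
    decs = {
        item: {level: step * (level - 1) for level in range(1, 5)}
        for item in selected_items
    }
    return UtilityIndexConfig(
        selected_items=tuple(selected_items),
        base_value=base_value,
        decrements=decs,
        clamp_floor=clamp_floor,
        name=name,
    )
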