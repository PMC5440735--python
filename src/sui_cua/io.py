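"""Reading participant CSVs and YAML/JSON configuration objects.

The participant table is long format: one row per participant x timepoint
with columns ``participant_id, arm, timepoint, education, item01..item19,
uisf_freq, uisf_amount, uisf_impact, pfmt_hours_4wk, laundry_hours_4wk,
aids_4wk, laundry_loads_4wk``.  Lines starting with ``#`` are metadata
comments (the synthetic generator records its seed there).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .costs import ARMS, PriceConfig, AnnualizationPolicy
from .errors import ParticipantDataError, ValidationError
from .questionnaires import (
    LUTSQOL_ITEM_NAMES,
    UISF_ITEM_MAXIMA,
    UtilityIndexConfig,
)

REQUIRED_COLUMNS = (
    ["participant_id", "arm", "timepoint", "education"]
    + list(LUTSQOL_ITEM_NAMES)
    + [
        "uisf_freq",
        "uisf_amount",
        "uisf_impact",
        "pfmt_hours_4wk",
        "laundry_hours_4wk",
        "aids_4wk",
        "laundry_loads_4wk",
    ]
)

_UISF_COLS = ("uisf_freq", "uisf_amount", "uisf_impact")
_RESOURCE_COLS = (
    "pfmt_hours_4wk",
    "laundry_hours_4wk",
    "aids_4wk",
    "laundry_loads_4wk",
)


def read_participants(path) -> pd.DataFrame:
    """Load and validate a participant CSV; raise with all row errors at once.

    Row numbers in error messages are 1-based data rows (the header is row 1;
    comment lines are not counted).
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing column(s): {', '.join(missing)}")

    errors: list[tuple[int, str]] = []
    for pos, (_, row) in enumerate(df.iterrows()):
        rownum = pos + 2
        if row["arm"] not in ARMS:
            errors.append((rownum, f"arm: invalid value {row['arm']!r}"))
        if row["timepoint"] not in ("baseline", "month3"):
            errors.append((rownum, f"timepoint: invalid value {row['timepoint']!r}"))
        for col in LUTSQOL_ITEM_NAMES:
            v = row[col]
            if pd.isna(v):
                continue  # item-level missingness is allowed
            if float(v) != int(v) or not 1 <= int(v) <= 4:
                errors.append((rownum, f"{col}: level {v} outside {{1,2,3,4}}"))
        for col, upper in zip(_UISF_COLS, UISF_ITEM_MAXIMA):
            v = row[col]
            if pd.isna(v):
                continue
            if float(v) != int(v) or not 0 <= int(v) <= upper:
                errors.append((rownum, f"{col}: value {v} outside [0, {upper}]"))
        for col in _RESOURCE_COLS:
            v = row[col]
            if pd.notna(v) and float(v) < 0:
                errors.append((rownum, f"{col}: negative value {v}"))
    if errors:
        raise ParticipantDataError(errors)
    return df


def load_config_file(path) -> dict:
    """Load a YAML or JSON mapping (YAML is a superset of JSON)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a mapping at top level")
    return data


def price_config_from_dict(d: Mapping) -> PriceConfig:
    kwargs = {}
    for key in (
        "assessment_cost",
        "wage_by_education",
        "aid_unit_price",
        "laundry_load_price",
        "currency_note",
    ):
        if key in d:
            kwargs[key] = d[key]
    return PriceConfig(**kwargs)


def price_config_to_dict(cfg: PriceConfig) -> dict:
    return {
        "assessment_cost": cfg.assessment_cost,
        "wage_by_education": dict(cfg.wage_by_education),
        "aid_unit_price": cfg.aid_unit_price,
        "laundry_load_price": cfg.laundry_load_price,
        "currency_note": cfg.currency_note,
    }


def annualization_from_dict(d: Mapping) -> AnnualizationPolicy:
    return AnnualizationPolicy(**d)


def utility_config_from_dict(d: Mapping) -> UtilityIndexConfig:
    decrements = {
        item: {int(level): float(dec) for level, dec in per_level.items()}
        for item, per_level in d["decrements"].items()
    }
    return UtilityIndexConfig(
        selected_items=tuple(d["selected_items"]),
        base_value=float(d["base_value"]),
        decrements=decrements,
        clamp_floor=float(d.get("clamp_floor", 0.0)),
        name=str(d.get("name", "custom")),
    )


def utility_config_to_dict(cfg: UtilityIndexConfig) -> dict:
    return {
        "name": cfg.name,
        "selected_items": list(cfg.selected_items),
        "base_value": cfg.base_value,
        "clamp_floor": cfg.clamp_floor,
        "decrements": {
            item: {int(level): float(dec) for level, dec in per_level.items()}
            for item, per_level in cfg.decrements.items()
        },
    }


def load_utility_config(path) -> UtilityIndexConfig:
    return utility_config_from_dict(load_config_file(path))


def load_price_config(path) -> PriceConfig:
    return price_config_from_dict(load_config_file(path))


def save_yaml(data: Mapping, path) -> None:
    Path(path).write_text(yaml.safe_dump(dict(data), sort_keys=False))
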