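"""Synthetic two-arm trial generator.

Emulates the design the analysis assumes: community-dwelling women with
stress urinary incontinence randomized to app-delivered pelvic floor muscle
training (n=62) or no treatment (n=61), with questionnaires and 4-week
resource-use recall at baseline and a 3-month follow-up.

Generative model
----------------
Each participant carries a latent severity ``s ~ N(mu_arm, sigma_latent)``.
The 19 LUTSqol item levels are drawn conditionally independently given ``s``
from an ordered-logit model with shared cutpoints, so the overall score and
any 9-item health state co-vary plausibly.  ``mu_arm`` is solved numerically
so the expected overall score equals the configured arm mean; at follow-up
the latent severity shifts by an arm-specific amount solved so the expected
score reduction equals the configured treatment effect.  The 3-item severity
questionnaire is derived from the same latent variable.  Resource-use
quantities are gamma-distributed (non-negative, right-skewed) with
configured means; aid and laundry-load counts are rounded to integers.
Dropout is missing-completely-at-random (one participant per arm by
default); a configurable number of intervention-arm completers additionally
lack follow-up quality-of-life items.

A calibrated mode (:func:`generate_calibrated_trial`) moment-matches the
realized completer arm means to configured annual resource amounts and QALY
gains, for deterministic end-to-end reproduction of a group-mean analysis;
see docs/methods.md for the procedure.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .costs import (
    FOUR_WEEK_PERIODS_PER_YEAR,
    AnnualizationPolicy,
    default_policies,
)
from .errors import ConfigError, ValidationError
from .qaly import DEFAULT_FOLLOWUP_YEARS, DEFAULT_HORIZON_YEARS
from .questionnaires import (
    LUTSQOL_ITEM_NAMES,
    LUTSQOL_MAX_SCORE,
    LUTSQOL_MIN_SCORE,
    UISF_ITEM_MAXIMA,
    UtilityIndexConfig,
    uniform_step_utility_config,
)

ARMS = ("app", "control")

#: Ordered-logit cutpoints and scale of the latent item model.
ITEM_CUTPOINTS = (-1.0, 0.5, 2.0)
ITEM_SCALE = 0.8

RESOURCE_COLUMNS = (
    "pfmt_hours_4wk",
    "laundry_hours_4wk",
    "aids_4wk",
    "laundry_loads_4wk",
)
INTEGER_RESOURCES = ("aids_4wk", "laundry_loads_4wk")


def _default_resource_means() -> dict[str, dict[str, float]]:
    """Arm-mean 4-week resource use consistent with the annual cost-table amounts.

    Annual hours of training divide by the arm's annualization factor
    (the intervention arm's reported time is what the maintenance-adjusted
    annualization scales up to the annual amount); all other quantities
    divide by 365.25/28.
    """
    policies = default_policies()
    annual = {
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
    out: dict[str, dict[str, float]] = {}
    for arm in ARMS:
        f_pfmt = policies[arm].pfmt_annualization_factor
        a = annual[arm]
        out[arm] = {
            "pfmt_hours_4wk": a["pfmt_hours"] / f_pfmt,
            "laundry_hours_4wk": a["laundry_hours"] / FOUR_WEEK_PERIODS_PER_YEAR,
            "aids_4wk": a["aids"] / FOUR_WEEK_PERIODS_PER_YEAR,
            "laundry_loads_4wk": a["laundry_loads"] / FOUR_WEEK_PERIODS_PER_YEAR,
        }
    return out


@dataclass(frozen=True)
class TrialConfig:
    """Study conditions of the emulated trial (defaults mirror the source design)."""

    n_app: int = 62
    n_control: int = 61
    dropout_per_arm: int = 1
    missing_lutsqol_app: int = 3
    baseline_lutsqol_mean: Mapping[str, float] = field(
        default_factory=lambda: {"app": 34.1, "control": 34.8}
    )
    baseline_lutsqol_sd: float = 6.1
    effect: Mapping[str, float] = field(
        default_factory=lambda: {"app": 4.8, "control": 0.7}
    )
    resource_means_4wk: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_resource_means
    )
    resource_cv: float = 0.8  # coefficient of variation of gamma draws
    education_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"app": 0.84, "control": 0.75}
    )
    uisf_baseline_mean: Mapping[str, float] = field(
        default_factory=lambda: {"app": 11.1, "control": 11.0}
    )
    sigma_latent: float = 0.55
    sigma_followup: float = 0.30
    uisf_slope: float = 2.2
    uisf_noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        for arm in ARMS:
            n = getattr(self, f"n_{arm}")
            if n <= self.dropout_per_arm:
                raise ConfigError(f"arm size {n} must exceed dropout {self.dropout_per_arm}")
            mean = self.baseline_lutsqol_mean[arm]
            if not LUTSQOL_MIN_SCORE < mean < LUTSQOL_MAX_SCORE:
                raise ConfigError(
                    f"baseline LUTSqol mean {mean} outside "
                    f"({LUTSQOL_MIN_SCORE}, {LUTSQOL_MAX_SCORE})"
                )
            target_fu = mean - self.effect[arm]
            if not LUTSQOL_MIN_SCORE < target_fu < LUTSQOL_MAX_SCORE:
                raise ConfigError(f"follow-up mean {target_fu} infeasible for arm {arm}")
            if not 0.0 <= self.education_fraction[arm] <= 1.0:
                raise ConfigError("education_fraction must lie in [0, 1]")
            for col in RESOURCE_COLUMNS:
                if self.resource_means_4wk[arm][col] < 0:
                    raise ConfigError(f"resource mean {col} ({arm}) must be >= 0")
        if self.resource_cv < 0 or self.sigma_latent < 0 or self.sigma_followup < 0:
            raise ConfigError("dispersions must be >= 0")
        if self.missing_lutsqol_app + self.dropout_per_arm >= self.n_app:
            raise ConfigError("too much missingness for the intervention arm size")


@dataclass(frozen=True)
class SyntheticTrial:
    """Long-format participant table plus generation provenance.

    ``data`` has one row per participant x timepoint with columns
    participant_id, arm, timepoint, education, item01..item19, uisf_freq,
    uisf_amount, uisf_impact, and the four 4-week resource-use columns.
    Dropouts lack the month3 row entirely.
    """

    data: pd.DataFrame
    config: TrialConfig
    provenance: Mapping[str, object] = field(default_factory=dict)

    def arm_ids(self, arm: str) -> list[str]:
        return sorted(self.data.loc[self.data["arm"] == arm, "participant_id"].unique())

    def completer_ids(self, arm: str) -> list[str]:
        d = self.data
        month3 = set(d.loc[d["timepoint"] == "month3", "participant_id"])
        return [pid for pid in self.arm_ids(arm) if pid in month3]

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# synthetic trial; seed={self.config.seed}\n")
            self.data.to_csv(fh, index=False)


def _expected_total(mu: float, sigma: float) -> float:
    """E[LUTSqol total] under the latent ordered-logit item model."""
    nodes, weights = np.polynomial.hermite.hermgauss(61)
    s = mu + np.sqrt(2.0) * sigma * nodes
    p_ge = expit((s[:, None] - np.asarray(ITEM_CUTPOINTS)[None, :]) / ITEM_SCALE)
    e_level = 1.0 + p_ge.sum(axis=1)
    return 19.0 * float((weights / np.sqrt(np.pi)) @ e_level)


def _solve_latent_mean(target_total: float, sigma: float) -> float:
    lo, hi = -12.0, 12.0
    if not _expected_total(lo, sigma) < target_total < _expected_total(hi, sigma):
        raise ConfigError(f"target LUTSqol mean {target_total} unreachable")
    return float(brentq(lambda m: _expected_total(m, sigma) - target_total, lo, hi))


def _draw_items(s: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw (n, 19) item levels in {1..4} given latent severities ``s``."""
    p_ge = expit(
        (s[:, None, None] - np.asarray(ITEM_CUTPOINTS)[None, None, :]) / ITEM_SCALE
    )
    u = rng.random((s.shape[0], 19, 1))
    return 1 + (u < p_ge).sum(axis=2)


def _split_uisf(total: int) -> tuple[int, int, int]:
    """Split a 0-21 total into (frequency, amount, impact) within item maxima."""
    f_max, a_max, i_max = UISF_ITEM_MAXIMA
    freq = min(f_max, round(total * f_max / 21))
    amount = min(a_max, round(total * a_max / 21))
    impact = total - freq - amount
    while impact > i_max:
        if freq < f_max:
            freq += 1
        else:
            amount += 1
        impact -= 1
    while impact < 0:
        if freq > 0:
            freq -= 1
        else:
            amount -= 1
        impact += 1
    return freq, amount, impact


def generate_trial(config: TrialConfig) -> SyntheticTrial:
    """Draw a reproducible synthetic trial from the configured conditions."""
    rng = np.random.default_rng(config.seed)
    sigma_b = config.sigma_latent
    sigma_f = float(np.hypot(config.sigma_latent, config.sigma_followup))
    rows: list[dict] = []
    for arm in ARMS:
        n = getattr(config, f"n_{arm}")
        mu = _solve_latent_mean(config.baseline_lutsqol_mean[arm], sigma_b)
        target_fu = config.baseline_lutsqol_mean[arm] - config.effect[arm]
        mu_fu = _solve_latent_mean(target_fu, sigma_f)
        shift = mu - mu_fu

        ids = [f"{arm}-{i + 1:03d}" for i in range(n)]
        education = np.where(
            rng.random(n) < config.education_fraction[arm], "university_3plus", "other"
        )
        s_base = rng.normal(mu, sigma_b, n)
        s_fu = s_base - shift + rng.normal(0.0, config.sigma_followup, n)
        items = {"baseline": _draw_items(s_base, rng), "month3": _draw_items(s_fu, rng)}

        uisf_mu = config.uisf_baseline_mean[arm]
        uisf = {}
        for tp, s in (("baseline", s_base), ("month3", s_fu)):
            totals = np.clip(
                np.rint(
                    uisf_mu
                    + config.uisf_slope * (s - mu)
                    + rng.normal(0.0, config.uisf_noise_sd, n)
                ),
                0,
                21,
            ).astype(int)
            uisf[tp] = [_split_uisf(int(t)) for t in totals]

        resources = {}
        cv = config.resource_cv
        for tp in ("baseline", "month3"):
            cols = {}
            for col in RESOURCE_COLUMNS:
                mean = config.resource_means_4wk[arm][col]
                if mean == 0 or cv == 0:
                    draws = np.full(n, mean)
                else:
                    shape = 1.0 / cv**2
                    draws = rng.gamma(shape, mean * cv**2, n)
                if col in INTEGER_RESOURCES:
                    draws = np.rint(draws).astype(int)
                cols[col] = draws
            resources[tp] = cols

        dropouts = set(rng.choice(n, size=config.dropout_per_arm, replace=False))
        remaining = [i for i in range(n) if i not in dropouts]
        n_missing = config.missing_lutsqol_app if arm == "app" else 0
        missing_qol = set(
            rng.choice(remaining, size=n_missing, replace=False)
        ) if n_missing else set()

        for i in range(n):
            for tp in ("baseline", "month3"):
                if tp == "month3" and i in dropouts:
                    continue
                lutsqol_missing = tp == "month3" and i in missing_qol
                row = {
                    "participant_id": ids[i],
                    "arm": arm,
                    "timepoint": tp,
                    "education": education[i],
                }
                for j, name in enumerate(LUTSQOL_ITEM_NAMES):
                    row[name] = np.nan if lutsqol_missing else int(items[tp][i, j])
                fr, am, im = uisf[tp][i]
                row.update({"uisf_freq": fr, "uisf_amount": am, "uisf_impact": im})
                for col in RESOURCE_COLUMNS:
                    row[col] = float(resources[tp][col][i])
                rows.append(row)

    data = pd.DataFrame(rows)
    return SyntheticTrial(data=data, config=config, provenance={"seed": config.seed})


def recover_parameters(trial: SyntheticTrial) -> dict[str, dict[str, float]]:
    """Completer arm means: scores, score changes, and 4-week resource use."""
    d = trial.data
    out: dict[str, dict[str, float]] = {}
    item_cols = list(LUTSQOL_ITEM_NAMES)
    for arm in ARMS:
        ids = trial.arm_ids(arm)
        if not ids:
            raise ValidationError(f"empty arm {arm!r}")
        completers = trial.completer_ids(arm)
        base = d[(d["arm"] == arm) & (d["timepoint"] == "baseline")].set_index(
            "participant_id"
        )
        fu = d[(d["arm"] == arm) & (d["timepoint"] == "month3")].set_index(
            "participant_id"
        )
        base_scores = base[item_cols].sum(axis=1, min_count=19)
        fu_scores = fu[item_cols].sum(axis=1, min_count=19)
        paired = pd.concat(
            {"base": base_scores.loc[completers], "fu": fu_scores.loc[completers]},
            axis=1,
        ).dropna()
        uisf_base = base[["uisf_freq", "uisf_amount", "uisf_impact"]].sum(axis=1)
        out[arm] = {
            "n_randomized": float(len(ids)),
            "n_completers": float(len(completers)),
            "n_qol_analyzable": float(len(paired)),
            "baseline_lutsqol_mean": float(base_scores.mean()),
            "baseline_lutsqol_sd": float(base_scores.std(ddof=1)),
            "lutsqol_change_mean": float((paired["base"] - paired["fu"]).mean()),
            "uisf_baseline_mean": float(uisf_base.mean()),
            "pfmt_hours_4wk_mean": float(fu.loc[completers, "pfmt_hours_4wk"].mean()),
            "laundry_hours_4wk_mean": float(
                fu.loc[completers, "laundry_hours_4wk"].mean()
            ),
            "aids_4wk_baseline_mean": float(base.loc[completers, "aids_4wk"].mean()),
            "laundry_loads_4wk_mean": float(
                fu.loc[completers, "laundry_loads_4wk"].mean()
            ),
        }
    return out


@dataclass(frozen=True)
class CalibrationTargets:
    """Arm-level targets for the moment-matched (deterministic) mode."""

    annual_amounts: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
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
    )
    qaly_gains: Mapping[str, float] = field(
        default_factory=lambda: {"app": 0.01006, "control": 0.00158}
    )
    t_followup: float = DEFAULT_FOLLOWUP_YEARS
    horizon: float = DEFAULT_HORIZON_YEARS
    base_utility: float = 0.95
    nominal_step: float = 0.005
    selected_items: tuple[str, ...] = tuple(f"item{i:02d}" for i in range(3, 12))
    aids_timepoint: str = "baseline"


def _match_integer_total(
    values: np.ndarray, target_mean: float, rng: np.random.Generator
) -> np.ndarray:
    """Rescale non-negative integer counts so their mean hits ``target_mean``
    up to total-count rounding (adjusting random entries by +/-1)."""
    v = np.asarray(values, dtype=float)
    realized = v.mean()
    if realized > 0:
        v = v * (target_mean / realized)
    else:
        v = np.full_like(v, target_mean)
    v = np.rint(v).astype(int)
    v = np.maximum(v, 0)
    target_sum = int(round(target_mean * len(v)))
    guard = 0
    while v.sum() != target_sum:
        idx = int(rng.integers(len(v)))
        if v.sum() < target_sum:
            v[idx] += 1
        elif v[idx] > 0:
            v[idx] -= 1
        guard += 1
        if guard > 100_000:  # pragma: no cover
            raise ConfigError("integer mean matching failed to converge")
    return v


def generate_calibrated_trial(
    config: TrialConfig, targets: CalibrationTargets | None = None
) -> tuple[SyntheticTrial, UtilityIndexConfig]:
    """Trial whose completer arm means reproduce the configured annual amounts
    and QALY gains exactly (up to integer-count quantization).

    Returns the calibrated trial together with the uniform-step utility index
    solved so the intervention arm's mean QALY gain matches its target; the
    comparator arm is matched to the nearest step quantum.
    """
    targets = targets or CalibrationTargets()
    trial = generate_trial(config)
    df = trial.data.copy()
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31) + 1)
    policies = default_policies()

    for arm in ARMS:
        completers = trial.completer_ids(arm)
        amounts = targets.annual_amounts[arm]
        month3 = (df["arm"] == arm) & (df["timepoint"] == "month3")
        m3_completers = month3 & df["participant_id"].isin(completers)
        # continuous columns: exact multiplicative match of the completer mean
        for col, annual_key, factor in (
            ("pfmt_hours_4wk", "pfmt_hours", policies[arm].pfmt_annualization_factor),
            ("laundry_hours_4wk", "laundry_hours", FOUR_WEEK_PERIODS_PER_YEAR),
        ):
            target_4wk = amounts[annual_key] / factor
            realized = df.loc[m3_completers, col].mean()
            if realized > 0:
                df.loc[m3_completers, col] *= target_4wk / realized
            else:
                df.loc[m3_completers, col] = target_4wk
        # integer counts: match the completer total
        aids_tp = targets.aids_timepoint
        aids_mask = (
            (df["arm"] == arm)
            & (df["timepoint"] == aids_tp)
            & df["participant_id"].isin(completers)
        )
        df.loc[aids_mask, "aids_4wk"] = _match_integer_total(
            df.loc[aids_mask, "aids_4wk"].to_numpy(),
            amounts["aids"] / FOUR_WEEK_PERIODS_PER_YEAR,
            rng,
        )
        df.loc[m3_completers, "laundry_loads_4wk"] = _match_integer_total(
            df.loc[m3_completers, "laundry_loads_4wk"].to_numpy(),
            amounts["laundry_loads"] / FOUR_WEEK_PERIODS_PER_YEAR,
            rng,
        )

    # --- utility-side calibration ---------------------------------------
    # Solve the per-level-step decrement d from the intervention arm's target
    # mean utility change, then adjust follow-up item levels by unit steps so
    # each arm's total 9-item level reduction equals its integer target.
    geom = targets.horizon - targets.t_followup / 2.0
    sel = list(targets.selected_items)
    du = {arm: targets.qaly_gains[arm] / geom for arm in ARMS}

    analyzable: dict[str, list[str]] = {}
    for arm in ARMS:
        ids = []
        for pid in trial.completer_ids(arm):
            fu_row = df[
                (df["participant_id"] == pid) & (df["timepoint"] == "month3")
            ].iloc[0]
            if not pd.isna(fu_row[sel[0]]):
                ids.append(pid)
        analyzable[arm] = ids

    n_app = len(analyzable["app"])
    k_app = max(1, int(round(du["app"] * n_app / targets.nominal_step)))
    step = du["app"] * n_app / k_app
    k_targets = {"app": k_app}
    for arm in ARMS:
        if arm != "app":
            k_targets[arm] = max(0, int(round(du[arm] * len(analyzable[arm]) / step)))

    for arm in ARMS:
        ids = analyzable[arm]
        base_idx = df.index[
            (df["timepoint"] == "baseline") & df["participant_id"].isin(ids)
        ]
        fu_idx = df.index[
            (df["timepoint"] == "month3") & df["participant_id"].isin(ids)
        ]
        base_levels = (
            df.loc[base_idx].set_index("participant_id").loc[ids, sel].to_numpy()
        )
        fu = df.loc[fu_idx].set_index("participant_id").loc[ids, sel].to_numpy().astype(float)
        target_k = k_targets[arm]
        guard = 0
        while True:
            s_now = int((base_levels - fu).sum())
            if s_now == target_k:
                break
            i = int(rng.integers(fu.shape[0]))
            j = int(rng.integers(fu.shape[1]))
            if s_now < target_k and fu[i, j] > 1:
                fu[i, j] -= 1
            elif s_now > target_k and fu[i, j] < 4:
                fu[i, j] += 1
            guard += 1
            if guard > 1_000_000:  # pragma: no cover
                raise ConfigError("utility calibration failed to converge")
        fu_frame = df.loc[fu_idx].set_index("participant_id")
        fu_frame.loc[ids, sel] = fu.astype(int)
        df.loc[fu_idx, sel] = fu_frame[sel].to_numpy()

    uconfig = uniform_step_utility_config(
        targets.selected_items,
        step=step,
        base_value=targets.base_utility,
        name="calibrated-uniform-step",
    )
    calibrated = SyntheticTrial(
        data=df,
        config=config,
        provenance={
            "seed": config.seed,
            "calibrated": True,
            "utility_step": step,
            "step_targets": k_targets,
        },
    )
    return calibrated, uconfig
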