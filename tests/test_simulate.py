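"""Synthetic trial generator: determinism, recovery, and calibration."""

import numpy as np
import pandas as pd
import pytest

from sui_cua.errors import ConfigError
from sui_cua.questionnaires import LUTSQOL_ITEM_NAMES
from sui_cua.simulate import (
    CalibrationTargets,
    TrialConfig,
    generate_calibrated_trial,
    generate_trial,
    recover_parameters,
)


@pytest.fixture(scope="module")
def default_trial():
    return generate_trial(TrialConfig(seed=7))


class TestGeneration:
    def test_seed_determinism(self, default_trial):
        again = generate_trial(TrialConfig(seed=7))
        pd.testing.assert_frame_equal(default_trial.data, again.data)

    def test_seed_isolation(self, default_trial):
        other = generate_trial(TrialConfig(seed=8))
        assert not default_trial.data.equals(other.data)

    def test_item_levels_valid(self, default_trial):
        items = default_trial.data[list(LUTSQOL_ITEM_NAMES)]
        present = items.stack()
        assert present.isin([1, 2, 3, 4]).all()

    def test_arm_sizes_and_dropout(self, default_trial):
        d = default_trial.data
        assert len(d[(d.arm == "app") & (d.timepoint == "baseline")]) == 62
        assert len(d[(d.arm == "control") & (d.timepoint == "baseline")]) == 61
        assert len(default_trial.completer_ids("app")) == 61
        assert len(default_trial.completer_ids("control")) == 60

    def test_survivors_have_followup_resources(self, default_trial):
        d = default_trial.data
        fu = d[d.timepoint == "month3"]
        assert fu["pfmt_hours_4wk"].notna().all()
        assert fu["aids_4wk"].notna().all()

    def test_infeasible_mean_rejected(self):
        with pytest.raises(ConfigError):
            TrialConfig(baseline_lutsqol_mean={"app": 80.0, "control": 34.8})

    def test_infeasible_effect_rejected(self):
        with pytest.raises(ConfigError):
            TrialConfig(effect={"app": 20.0, "control": 0.7},
                        baseline_lutsqol_mean={"app": 25.0, "control": 34.8})


class TestRecovery:
    def test_baseline_mean_recovery_at_10x(self):
        config = TrialConfig(n_app=620, n_control=610, seed=11)
        rec = recover_parameters(generate_trial(config))
        for arm, target in (("app", 34.1), ("control", 34.8)):
            n = rec[arm]["n_randomized"]
            se = rec[arm]["baseline_lutsqol_sd"] / np.sqrt(n)
            assert abs(rec[arm]["baseline_lutsqol_mean"] - target) < 2 * se

    def test_effect_recovery_at_10x(self):
        config = TrialConfig(n_app=620, n_control=610, seed=11)
        rec = recover_parameters(generate_trial(config))
        assert rec["app"]["lutsqol_change_mean"] == pytest.approx(4.8, abs=0.8)
        assert rec["control"]["lutsqol_change_mean"] == pytest.approx(0.7, abs=0.8)

    def test_resource_mean_recovery(self):
        config = TrialConfig(n_app=620, n_control=610, seed=11)
        trial = generate_trial(config)
        rec = recover_parameters(trial)
        for arm in ("app", "control"):
            mean = config.resource_means_4wk[arm]["pfmt_hours_4wk"]
            # gamma with cv 0.8: SE of the mean = 0.8 * mean / sqrt(n)
            se = 0.8 * mean / np.sqrt(rec[arm]["n_completers"])
            assert abs(rec[arm]["pfmt_hours_4wk_mean"] - mean) < 2 * se

    def test_null_effect_configuration(self):
        config = TrialConfig(
            n_app=400, n_control=400, effect={"app": 0.0, "control": 0.0}, seed=3
        )
        rec = recover_parameters(generate_trial(config))
        diff = rec["app"]["lutsqol_change_mean"] - rec["control"]["lutsqol_change_mean"]
        # between-arm change difference ~ N(0, 2 * var/n); bound with 3 SE
        se = np.sqrt(2.0) * 3.0 / np.sqrt(400)
        assert abs(diff) < 3 * se

    def test_single_participant_arms(self):
        config = TrialConfig(
            n_app=1, n_control=1, dropout_per_arm=0, missing_lutsqol_app=0, seed=5
        )
        trial = generate_trial(config)
        rec = recover_parameters(trial)
        d = trial.data
        row = d[(d.arm == "app") & (d.timepoint == "month3")].iloc[0]
        assert rec["app"]["pfmt_hours_4wk_mean"] == row["pfmt_hours_4wk"]

    def test_zero_resource_use(self):
        means = {
            arm: {c: 0.0 for c in (
                "pfmt_hours_4wk", "laundry_hours_4wk", "aids_4wk", "laundry_loads_4wk"
            )}
            for arm in ("app", "control")
        }
        trial = generate_trial(TrialConfig(resource_means_4wk=means, seed=2))
        assert (trial.data[["pfmt_hours_4wk", "aids_4wk"]] == 0).all().all()

    def test_empty_arm_errors(self, default_trial):
        from sui_cua.simulate import SyntheticTrial
        no_app = SyntheticTrial(
            data=default_trial.data[default_trial.data.arm == "control"],
            config=default_trial.config,
        )
        with pytest.raises(Exception):
            recover_parameters(no_app)


@pytest.fixture(scope="module")
def calibrated():
    return generate_calibrated_trial(TrialConfig(seed=7))


class TestCalibration:
    def test_continuous_means_match_exactly(self, calibrated):
        trial, _ = calibrated
        targets = CalibrationTargets()
        rec = recover_parameters(trial)
        from sui_cua.costs import default_policies, FOUR_WEEK_PERIODS_PER_YEAR
        policies = default_policies()
        for arm in ("app", "control"):
            f = policies[arm].pfmt_annualization_factor
            assert rec[arm]["pfmt_hours_4wk_mean"] * f == pytest.approx(
                targets.annual_amounts[arm]["pfmt_hours"], abs=1e-9
            )
            assert (
                rec[arm]["laundry_hours_4wk_mean"] * FOUR_WEEK_PERIODS_PER_YEAR
            ) == pytest.approx(targets.annual_amounts[arm]["laundry_hours"], abs=1e-9)

    def test_count_means_match_within_quantization(self, calibrated):
        trial, _ = calibrated
        targets = CalibrationTargets()
        rec = recover_parameters(trial)
        from sui_cua.costs import FOUR_WEEK_PERIODS_PER_YEAR
        for arm in ("app", "control"):
            annual_aids = rec[arm]["aids_4wk_baseline_mean"] * FOUR_WEEK_PERIODS_PER_YEAR
            assert annual_aids == pytest.approx(
                targets.annual_amounts[arm]["aids"], abs=0.2
            )

    def test_counts_remain_integers(self, calibrated):
        trial, _ = calibrated
        aids = trial.data["aids_4wk"].dropna()
        assert (aids == aids.round()).all()
        assert (aids >= 0).all()

    def test_calibrated_utility_step_positive(self, calibrated):
        _, uconfig = calibrated
        step = uconfig.decrements[uconfig.selected_items[0]][2]
        assert 0 < step < 0.05
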