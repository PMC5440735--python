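"""CSV/report I/O, the full pipeline in both modes, and the CLI."""

import json

import pandas as pd
import pytest
from click.testing import CliRunner

from sui_cua.cli import main as cli_main
from sui_cua.errors import ParticipantDataError, ValidationError
from sui_cua.io import (
    read_participants,
    utility_config_from_dict,
    utility_config_to_dict,
)
from sui_cua.pipeline import GroupMeanInputs, run_cua, write_report
from sui_cua.questionnaires import placeholder_utility_config
from sui_cua.simulate import TrialConfig, generate_calibrated_trial, generate_trial
from sui_cua.study_inputs import amounts_mode_inputs, cost_mode_inputs


@pytest.fixture(scope="module")
def trial_csv(tmp_path_factory):
    path = tmp_path_factory.mktemp("data") / "trial.csv"
    generate_trial(TrialConfig(seed=7)).to_csv(path)
    return path


class TestReadParticipants:
    def test_roundtrip_record_count(self, trial_csv):
        df = read_participants(trial_csv)
        assert df["participant_id"].nunique() == 123
        # one dropout per arm lacks the follow-up row
        assert len(df) == 2 * 123 - 2

    def test_empty_file_with_header(self, tmp_path, trial_csv):
        header = pd.read_csv(trial_csv, comment="#", nrows=0)
        path = tmp_path / "empty.csv"
        header.to_csv(path, index=False)
        assert len(read_participants(path)) == 0

    def test_invalid_level_names_row_and_column(self, tmp_path, trial_csv):
        df = pd.read_csv(trial_csv, comment="#")
        df.loc[0, "item07"] = 5
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ParticipantDataError, match=r"row 2.*item07"):
            read_participants(path)

    def test_missing_column_rejected(self, tmp_path, trial_csv):
        df = pd.read_csv(trial_csv, comment="#").drop(columns=["aids_4wk"])
        path = tmp_path / "short.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="aids_4wk"):
            read_participants(path)


class TestUtilityConfigIO:
    def test_dict_roundtrip(self):
        cfg = placeholder_utility_config()
        assert utility_config_from_dict(utility_config_to_dict(cfg)) == cfg


class TestRunCua:
    def test_group_mean_amounts_mode(self):
        report = run_cua(group_means=amounts_mode_inputs())
        assert report["arms"]["app"]["total_cost"] == pytest.approx(547.0, abs=0.2)
        assert report["incremental"]["icer"] == pytest.approx(7615.5, rel=0.01)
        assert report["incremental"]["acceptable_at_threshold"]

    def test_group_mean_cost_mode(self):
        report = run_cua(group_means=cost_mode_inputs())
        assert report["incremental"]["icer"] == pytest.approx(7615.5, rel=0.002)

    def test_participant_mode_smoke(self):
        trial, uconfig = generate_calibrated_trial(TrialConfig(seed=7))
        report = run_cua(participants=trial.data, utility_config=uconfig)
        for arm in ("app", "control"):
            comp = report["arms"][arm]["components"]
            assert comp["total"] == pytest.approx(
                sum(v for k, v in comp.items() if k != "total"), abs=1e-9
            )
            assert comp["treatment_delivery"] == 0.0
        # sensitivity base row agrees with the headline incremental result
        base_row = next(r for r in report["sensitivity"] if r["scenario"] == "base")
        assert base_row["icer"] == pytest.approx(report["incremental"]["icer"])

    def test_zero_effect_degenerate(self):
        inputs = GroupMeanInputs(
            qaly_gains={"app": 0.01, "control": 0.01},
            component_costs={
                "app": {"assessment": 6.4, "pfmt_time": 100.0},
                "control": {"assessment": 6.4, "pfmt_time": 50.0},
            },
        )
        report = run_cua(group_means=inputs)
        assert report["incremental"]["icer"] is None
        assert "undefined" in report["incremental"]["note"]

    def test_both_or_neither_input_modes_rejected(self):
        with pytest.raises(ValidationError):
            run_cua()

    def test_report_json_roundtrip(self, tmp_path):
        report = run_cua(group_means=amounts_mode_inputs())
        paths = write_report(report, tmp_path)
        reread = json.loads(paths["json"].read_text())
        assert reread == report
        for key in ("cost_table", "incremental_table", "sensitivity_table"):
            assert paths[key].exists()


class TestCli:
    def test_simulate_score_cua_chain(self, tmp_path):
        runner = CliRunner()
        csv = tmp_path / "trial.csv"
        ucfg = tmp_path / "utility.yaml"
        res = runner.invoke(
            cli_main,
            ["simulate", "--seed", "7", "--calibrate", "--out", str(csv),
             "--utility-config-out", str(ucfg)],
        )
        assert res.exit_code == 0, res.output

        scored = tmp_path / "scores.csv"
        res = runner.invoke(
            cli_main,
            ["score", "--input", str(csv), "--utility-config", str(ucfg),
             "--out", str(scored)],
        )
        assert res.exit_code == 0, res.output
        assert pd.read_csv(scored)["lutsqol_score"].dropna().between(19, 76).all()

        outdir = tmp_path / "report"
        res = runner.invoke(
            cli_main,
            ["cua", "--input", str(csv), "--utility-config", str(ucfg),
             "--outdir", str(outdir)],
        )
        assert res.exit_code == 0, res.output
        assert (outdir / "report.json").exists()

    def test_group_mean_cua(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["cua", "--group-mean-mode", "costs", "--outdir", str(tmp_path / "r")],
        )
        assert res.exit_code == 0, res.output
        assert "ICER 7617.9" in res.output

    def test_invalid_csv_nonzero_exit(self, tmp_path, trial_csv=None):
        runner = CliRunner()
        csv = tmp_path / "trial.csv"
        generate_trial(TrialConfig(seed=7)).to_csv(csv)
        df = pd.read_csv(csv, comment="#")
        df.loc[0, "item01"] = 9
        df.to_csv(csv, index=False)
        res = runner.invoke(
            cli_main, ["cua", "--input", str(csv), "--outdir", str(tmp_path / "r")]
        )
        assert res.exit_code != 0
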