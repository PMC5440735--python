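#!/usr/bin/env python
"""Score the questionnaires and derive utility weights per participant.

Reads the synthetic trial written by 01_simulate_trial.py, scores the
19-item QoL questionnaire (19-76) and the 3-item severity questionnaire
(0-21, banded), maps the 9-item health state to a utility weight, and
writes one scored row per participant and timepoint.
"""

from pathlib import Path

import pandas as pd

from sui_cua.io import load_utility_config, read_participants
from sui_cua.pipeline import response_from_row
from sui_cua.questionnaires import categorize_severity, response_utility, score_lutsqol, score_uisf

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    df = read_participants(RESULTS / "synthetic_trial.csv")
    uconfig = load_utility_config(RESULTS / "utility_index.yaml")
    records = []
    for _, row in df.iterrows():
        resp = response_from_row(row)
        rec = {
            "participant_id": row["participant_id"],
            "arm": row["arm"],
            "timepoint": row["timepoint"],
            "lutsqol_score": None,
            "utility": None,
            "uisf_total": None,
            "severity": None,
        }
        if resp is not None:
            rec["lutsqol_score"] = score_lutsqol(resp)
            rec["utility"] = response_utility(resp, uconfig)
            if resp.uisf_items is not None:
                total = score_uisf(*resp.uisf_items)
                rec["uisf_total"] = total
                rec["severity"] = categorize_severity(total)
        records.append(rec)
    scores = pd.DataFrame(records)
    scores.to_csv(RESULTS / "questionnaire_scores.csv", index=False)

    summary = (
        scores.dropna(subset=["lutsqol_score"])
        .groupby(["arm", "timepoint"])[["lutsqol_score", "utility", "uisf_total"]]
        .mean()
    )
    print("arm-mean scores and utilities:")
    print(summary.round(3).to_string())
    print(f"\nseverity at baseline:\n"
          f"{scores[scores.timepoint == 'baseline'].groupby(['arm', 'severity']).size().to_string()}")
    print(f"wrote {RESULTS / 'questionnaire_scores.csv'}")


if __name__ == "__main__":
    main()
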