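#!/usr/bin/env python
"""Base-case ICER and deterministic sensitivity analysis.

Combines the per-component arm costs with the arm QALY gains, computes
ΔCost, ΔQALY and the ICER, judges acceptability at the Swedish low-cost
willingness-to-pay threshold (11,200 EUR/QALY), and re-runs the analysis
under the four bundled scenarios (training time halved, laundry goods cost
halved, laundry time excluded, and all three at once).
"""

from pathlib import Path

from sui_cua.pipeline import run_cua, write_report
from sui_cua.study_inputs import cost_mode_inputs

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    report = run_cua(group_means=cost_mode_inputs())
    write_report(report, RESULTS / "incremental")

    inc = report["incremental"]
    print("base case (app vs control):")
    print(f"  delta cost  {inc['delta_cost']:8.1f} EUR")
    print(f"  delta QALY  {inc['delta_qaly']:8.5f}")
    print(f"  ICER        {inc['icer']:8.1f} EUR/QALY  ({inc['quadrant']})")
    wtp = report["settings"]["wtp_threshold_eur_per_qaly"]
    verdict = "acceptable" if inc["acceptable_at_threshold"] else "not acceptable"
    print(f"  {verdict} at the {wtp:,.0f} EUR/QALY threshold")

    print("\nsensitivity scenarios:")
    for row in report["sensitivity"]:
        icer = "undefined" if row["icer"] is None else f"{row['icer']:10.1f}"
        print(
            f"  {row['scenario']:22s} app {row['cost_app']:6.1f}  "
            f"control {row['cost_control']:6.1f}  ICER {icer} ({row['quadrant']})"
        )
    icers = [r["icer"] for r in report["sensitivity"] if r["icer"] is not None]
    print(f"\nICER range across scenarios: {min(icers):,.1f} to {max(icers):,.1f} EUR/QALY")
    print(f"wrote {RESULTS / 'incremental'}")


if __name__ == "__main__":
    main()
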