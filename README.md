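# sui-cua

Deterministic cost-utility analysis of app-delivered pelvic floor muscle
training (PFMT) for stress urinary incontinence (SUI), with a 1-year
societal perspective.

SUI — urine leakage on coughing, sneezing or exertion — affects 10-35% of
women, and first-line treatment is PFMT, which suits self-management through
a mobile app. This package implements the full economic evaluation of such
an app against no treatment, for health economists and trialists who want
the analysis as reusable, tested code rather than a spreadsheet:

* **Questionnaire scoring** — ICIQ-UI SF (severity, 0-21, banded) and
  ICIQ-LUTSqol (condition-specific quality of life, 19 items, 19-76).
* **Utility index** — a pluggable preference-based index mapping a 9-item
  health state to a utility weight `u = base − Σ decrements`, clamped to
  [0, 1].
* **QALYs** — area under the piecewise-linear utility trajectory over 1
  year; the gain is the area above the baseline utility held constant:
  `gain = (u_3mo − u_0) · (1 − 0.25/2)`.
* **Cost model** — six annual societal components (assessment, delivery,
  PFMT time, laundry time, aids, laundry loads) from 4-week resource-use
  recall, with arm-specific annualization: constant extrapolation
  (× 365.25/28) for the control arm, a maintenance-prescription adjustment
  for the app arm.
* **Incremental analysis** — ΔCost, ΔQALY, ICER = ΔCost/ΔQALY, dominance
  quadrant, willingness-to-pay judgement.
* **Sensitivity engine** — deterministic one-way/multiway scenarios
  (scale or exclude cost components), recomputing the ICER per scenario.
* **Synthetic trial generator** — a two-arm RCT (62 vs 61 women) with a
  latent-severity item model, gamma resource use, dropout, and an optional
  moment-matched calibration so the full pipeline reproduces a group-mean
  analysis deterministically.

See `docs/methods.md` for the model, assumptions, and numerical choices.

## Worked example

The base case combines each arm's annual cost with its QALY gain
(2013 euro):

```python
from sui_cua import GroupSummary, incremental, judge_willingness_to_pay

app     = GroupSummary("app",     mean_cost=547.0, mean_qaly_gain=0.01006)
control = GroupSummary("control", mean_cost=482.4, mean_qaly_gain=0.00158)
res = incremental(app, control)
print(f"delta cost {res.delta_cost:.1f} EUR, delta QALY {res.delta_qaly:.5f}, "
      f"ICER {res.icer:.1f} EUR/QALY ({res.quadrant})")
print("acceptable at 11,200 EUR/QALY:", judge_willingness_to_pay(res, 11_200))
```

```
delta cost 64.6 EUR, delta QALY 0.00848, ICER 7617.9 EUR/QALY (NE)
acceptable at 11,200 EUR/QALY: True
```

The app arm costs 64.6 € more per woman per year (mostly her own training
time) and yields 0.00848 more QALYs, i.e. about 7,618 € per QALY gained —
northeast quadrant (more costly, more effective) and well below the Swedish
"low incremental cost" threshold of 11,200 €/QALY. Halving PFMT time (it
can be done while doing other things) makes the app arm *cheaper and more
effective* (dominant, negative ICER):

```bash
$ sui-cua sensitivity --outdir results/incremental
base: ICER 7617.9 EUR/QALY (NE)
pfmt_time_halved: ICER -2423.3 EUR/QALY (SE)
laundry_cost_halved: ICER 9787.7 EUR/QALY (NE)
laundry_time_excluded: ICER 14882.1 EUR/QALY (NE)
multiway: ICER 7010.6 EUR/QALY (NE)
```

The numbered scripts under `analysis/` run the full narrative — simulate a
calibrated trial, score questionnaires, build the cost table, compute the
base case and sensitivity analysis — writing their tables under `results/`:

```bash
python analysis/01_simulate_trial.py
python analysis/02_score_questionnaires.py
python analysis/03_cost_analysis.py
python analysis/04_incremental_and_sensitivity.py
```

A `sui-cua` CLI exposes the same stages (`simulate`, `score`, `cost`,
`cua`, `sensitivity`); see `sui-cua --help`.

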