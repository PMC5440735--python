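# Methods

## Scope and model

`sui_cua` implements a deterministic, trial-based cost-utility analysis with
a 1-year societal perspective, comparing app-delivered pelvic floor muscle
training (PFMT) for stress urinary incontinence against no treatment. The
pipeline has five stages — questionnaire scoring, a preference-based utility
index, area-under-the-curve (AUC) QALYs, a unit-price cost model, and an
incremental analysis with deterministic sensitivity scenarios — plus a
synthetic two-arm trial generator so every stage runs end-to-end without
external data.

The analysis is deterministic in the health-economics sense: it operates on
arm means (costs and QALY gains per participant per year), not on sampling
distributions. No discounting is applied (1-year horizon) and no
probabilistic sensitivity analysis is performed; the sensitivity engine
varies cost inputs one at a time and jointly.

## Questionnaires and the utility index

Two instruments are scored:

* **ICIQ-UI SF** — three items (frequency 0-5, amount 0-6, impact 0-10)
  summing to 0-21, banded 1-5 slight, 6-12 moderate, 13-18 severe, 19-21
  very severe. A total of 0 is labelled "none": the published bands start at
  1, and a zero total means no reported leakage.
* **ICIQ-LUTSqol** — nineteen items scored 1-4, overall score 19-76, higher
  = more impact on everyday life.

The utility index selects nine of the nineteen QoL items as a health-state
classification and maps it to a weight in [0, 1] by the standard additive
form of preference-based indices:

    u = clamp( base_value − Σ_i decrement(item_i, level_i), floor, 1 )

with zero decrement at level 1 and decrements non-decreasing in level (so
utility is monotone non-increasing in every item). The published
coefficients of the index this design follows are not in the public domain
of this package's sources, so the coefficient set is **pluggable
configuration** (`UtilityIndexConfig`, YAML/JSON-loadable). The shipped
default (`placeholder_utility_config`) selects items 3-11 with a uniform
decrement ladder (0 / 0.010 / 0.025 / 0.045) on a base of 1.0 and is
explicitly labelled a placeholder: it exercises the pipeline but carries no
valuation evidence. Substantive analyses must supply real coefficients.

## QALYs by area under the curve

Utility is assessed at baseline and at the 3-month follow-up
(`t_followup = 0.25` years, configurable) and assumed to change linearly
between assessments and to stay constant from follow-up to the 1-year
horizon. QALYs are the trapezoidal area under this piecewise-linear curve.
The **QALY gain** is defined against the baseline utility held constant —
the area between the trajectory and the baseline-level line:

    gain = qaly_total − u_baseline × horizon
         = (u_followup − u_baseline) × (horizon − t_followup / 2)   (two-assessment shape)

This is the reading under which year-scale gains of order 0.01 arise from a
3-month utility change of order 0.01, consistent with the evaluated trial's
figures. `implied_utility_change` inverts the closed form for diagnostics.
Gains convert to days at 365.25 days/year; note the trial's discussion quotes
"3.9 days" for the intervention arm where 0.01006 × 365.25 ≈ 3.67 — the
package reports the 365.25-day conversion and flags the discrepancy here
rather than reproducing it.

Numerically, a flat trajectory short-circuits to `u × horizon` so the gain
is exactly zero (avoiding float cancellation); otherwise plain trapezoids
are used. Trajectory invariants (times ascending from 0, utilities in
[0, 1], last time ≤ horizon) are enforced at construction.

## Cost model

Six components per participant per year, all in 2013 year-end euro
(1 EUR = 8.94 SEK):

| component | rule | default price |
|---|---|---|
| assessment | fixed per participant | 6.4 € |
| treatment delivery | identically 0 (no delivery costs identified) | — |
| PFMT time | annual hours × wage | 29.61 €/h |
| laundry time | annual hours × wage | 29.61 €/h |
| incontinence aids | annual units × unit price | 0.134 €/unit |
| extra laundry loads | annual loads × load price | 2.21 €/load |

Resource use is recalled over the 4 weeks before follow-up; quantities
assumed constant over the year scale by **365.25/28 ≈ 13.045** (configurable).
The intervention arm's training time instead follows the prescription: full
reported level during the 3 treatment months, then the maintenance rate for
the remaining 9 months, giving the annualization

    annual = h_4wk × 13.045 × [ f_treat + (1 − f_treat) × m ],
    f_treat = 3/12,  m = 2.5 / 21  (maintenance vs prescribed sessions/week).

The session-ratio form is this package's reading of "follow the maintenance
prescription"; because participant-level raw data do not exist publicly, the
group-mean **"amount used" mode** accepts annual arm-mean amounts directly
and is the mode that reproduces the published cost table. Time is valued at
gross hourly wages by education stratum (societal perspective). The trial
reports a single mean wage, so both default strata carry 29.61 €/h; the
lookup is a plain table and extends to real stratified wages from config.
Aid consumption is taken from the baseline assessment by default (the
published table's convention); the timepoint is configurable per component.

## Incremental analysis and sensitivity

ΔCost and ΔQALY are differences of arm means; ICER = ΔCost/ΔQALY when
ΔQALY ≠ 0, otherwise flagged undefined (never ±∞). The sign pair places the
result on the cost-effectiveness plane (NE/SE/NW/SW); a zero delta counts as
"not more costly"/"not more effective", so identical arms land in SW — the
boundary convention only matters for degenerate inputs. Negative ICERs are
always reported with a dominance note, since the bare ratio is ambiguous
between dominance (SE) and being dominated (NW). Willingness-to-pay
judgement: SE always acceptable, NW never, NE acceptable iff ICER ≤
threshold, SW by the symmetric rule (saving per QALY forgone ≥ threshold).
The default threshold is 11,200 €/QALY (100,000 SEK, the Swedish "low
incremental cost" level).

Sensitivity scenarios are ordered lists of component modifications (scale by
a positive factor, or exclude), applied identically to both arms; QALY gains
are untouched. "Cost for laundry halved" scales the laundry-loads goods
component, distinct from the participant's laundry *time* — verified
arithmetically against the published rows (e.g. 482.4 − 59.8/2 = 452.5).
The four published scenarios ship as a bundled YAML; user scenarios load
from the same schema. All computation is unrounded; the CSV writers round
for display (costs 1 dp, QALYs 5 dp, ICERs 1 dp).

Reproduction note: printed inputs are rounded to 1-2 decimals, and the
source analysis carried unrounded intermediates (its printed ΔQALY 0.00849
vs the component difference 0.01006 − 0.00158 = 0.00848). Rebuilding arm
costs from printed per-component euro values reproduces every published
ICER within 0.2%; rebuilding them from printed amounts × prices shifts
totals by ≲0.1 € and the small-magnitude scenario ICER by ~0.3%.

## Synthetic trial generator

The generator emulates the study conditions: 62 vs 61 women, baseline
QoL-impact scores 34.1/34.8 (SD ≈ 6), follow-up score reductions 4.8
(intervention) vs 0.7 (control), one dropout per arm, three additional
intervention-arm completers missing follow-up QoL items, university
education fractions 0.84/0.75, and arm-mean resource use consistent with
the published annual amounts.

* **Items**: a latent severity `s ~ N(mu_arm, 0.55)` drives all nineteen
  items through an ordered-logit model (cutpoints −1.0/0.5/2.0, scale 0.8),
  so totals and any 9-item health state co-vary. `mu_arm` is solved by
  Brent's method with Gauss-Hermite quadrature so E[total] equals the
  configured mean exactly; the follow-up latent shift is solved the same way
  for the configured reduction. `sigma_latent = 0.55` yields a total SD of
  ≈ 6.3, close to the reported 6.1.
* **Resource use**: gamma draws (nonnegative, right-skewed) with configured
  means and coefficient of variation 0.8 — the trial reports no dispersions,
  so the CV is an assumption of this package. Aid and load counts are
  rounded to integers.
* **Severity questionnaire**: totals derived linearly from the same latent
  variable (slope 2.2, noise SD 1.5 — chosen to give a plausible 0-21 spread
  around the reported means ≈ 11) and split into the three items within
  their maxima.

Everything is reproducible from a single integer seed.

### Calibrated mode

Sampling error at n ≈ 60/arm is far larger than the 1%-scale agreement a
deterministic reproduction needs, so `generate_calibrated_trial` moment-
matches completer arm means to the targets after drawing:

1. continuous resource columns are rescaled multiplicatively so the
   completer mean annualizes exactly to the target annual amount;
2. integer counts are rescaled, re-rounded, and nudged by ±1 on random
   records until the arm **total** equals `round(target_mean × n)` (residual
   mean error ≤ 0.5/n);
3. the per-level utility step `d` is solved from the intervention arm's
   target gain — `d = Δu × n / K` with `K = round(Δu × n / 0.005)` steps —
   and follow-up item levels are nudged by unit steps until each arm's total
   9-item level reduction equals its integer step target. The comparator
   arm's gain is then matched to the nearest step quantum (relative error
   ~2% on a gain of 0.0016, ~0.3% on ΔQALY).

The resulting uniform-step utility index (base 0.95, step ≈ 0.005) is
returned alongside the trial. With defaults the full participant-level
pipeline lands within ~0.2 € of the published arm totals and within ~0.8%
of the published base-case ICER, independent of seed (the matched moments
are deterministic; only which records get nudged varies).

What the generator does **not** emulate: recruitment and randomization
mechanics, item-level response styles, informative dropout, within-woman
correlation between resource-use components, or seasonal variation in
training adherence. Passing tests therefore show the pipeline's arithmetic
and contracts are right under the stated conditions, not that the model
would fit any particular real dataset.

## Problem sizes and numerics

Tests run the generator at the trial's own size (123 participants) and at
10× replication (1,230) for parameter recovery; the AUC oracle compares 200
random trajectories against dense-grid integration at step 1e-4 (agreement
within 1e-6). The whole suite and the acceptance script each complete in
seconds. Brent root-finding uses bracket [−12, 12] on the latent scale;
61-node Gauss-Hermite quadrature makes the expected-score solve accurate to
well below 1e-6 score points. Calibration loops are guarded against
non-convergence and raise `ConfigError` rather than spin.

## Known limitations

* The shipped utility coefficients are placeholders; published ICERs are
  reproduced through the group-mean modes, not from raw item data.
* The intervention arm's maintenance annualization cannot be validated
  against the published annual hours without raw data; the session-ratio
  form is one literal reading.
* The comparator's QALY gain calibration is quantized at one utility step
  per arm-total; exact joint matching of both arms' gains with a single
  uniform-step index is not possible.
* Education-stratified wages default to a single rate; stratified analyses
  need real wage tables.
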