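# Methods

## Decision problem and model structure

The model compares two axillary staging strategies for clinically
node-negative early breast cancer in a cohort with the profile of the
Australian SNAC trial population (start age 58, node-positive risk 26.9%):

* **ALND**: every patient undergoes axillary dissection; staging is assumed
  error-free.
* **SLNB**: every patient undergoes sentinel node biopsy. Mapping fails in
  6% of patients, who proceed to ALND. Among node-positive patients, 5.5%
  receive a false-negative (FN) result and are managed as node-negative;
  detected positives proceed to completion ALND. True negatives and false
  negatives avoid ALND.

The FN probability is applied to *all* node-positive patients (FN stratum
weight `p·fn`; the detected branch carries `p·(1−f−fn)`). The alternative —
applying it only to successfully mapped patients — changes the FN stratum
weight by 6%, and the reported outcomes by about as much.

Each arm is decomposed into strata (pathway × nodal status), which then run
through a shared time-inhomogeneous Markov process over 20 annual cycles
with six conceptual health states: disease-free, local recurrence, axillary
recurrence, distant metastases (DM), cancer death, other-cause death.
Structural rules:

* Recurrences are one-year acute states. Survivors return to disease-free
  but permanently retain the elevated post-recurrence annual DM probability
  (0.1246/0.0772 after local recurrence, 0.2063/0.2259 after axillary
  recurrence, node-positive/negative). This permanence is what reproduces
  the cohort's cumulative DM incidence (~173/1000 at 20 years in the ALND
  arm); a "reset to baseline" variant underestimates it by ~17%.
* First-event recurrence probabilities halve after year 5 and halve again
  after year 10 (multiplier 1, ½, ¼), reflecting the decline of recurrence
  hazards with time since primary treatment. First-event DM probabilities
  are not time-varying.
* The FN-elevated axillary hazard (0.016/yr, calibrated so that
  `1−(1−0.016)^5 ≈ 7.7%` of FN patients recur within 5 years) applies only
  until the first axillary recurrence; treated patients then follow the
  node-positive post-recurrence profile. A local recurrence does not end
  the elevation (the axilla remains undissected).
* Cancer death occurs only from DM (annual probability 0.297). Other-cause
  death can occur from any alive state at the age-specific background rate.
* Where histories combine, the higher-risk profile wins: once
  post-axillary-recurrence, the axillary DM rate applies even if a later
  local recurrence occurs. Repeat recurrences from post-recurrence
  disease-free states are allowed at the same halved first-event rates.
  Both choices affect <0.1% of cohort mass.

Internally the engine expands disease-free and local recurrence into
recurrence-history layers (never / post-local / post-axillary; 10 states),
so these rules are exact within a cohort trace; the exported trace
aggregates back to the six conceptual states. One approximation remains:
the "local recurrence" incidence counter counts all entries including
repeat local recurrences (order 1e-5 of the cohort); axillary, DM and death
counters are exact first-event counts.

## Lymphoedema

Moderate–severe arm lymphoedema is assigned once at baseline and is
permanent. Its probability follows the axillary surgery actually received:
patients undergoing ALND — directly, after a positive SLNB, or after a
failed SLNB — have probability 0.176; patients staged negative by SLNB have
0.119. The realised SLNB-arm prevalence is therefore a mixture (~0.136 at
base case), not the trial-arm-level 0.119; this pathway attribution is what
makes the lymphoedema-related thresholds (ALND lymphoedema ~14%, disutility
~0.012) come out where they do, and it is also the clinically coherent
reading: lymphoedema is caused by the surgery performed, not by the
randomisation label.

Rather than doubling the state space, lymphoedema enters in expectation: a
fraction `p_lymph` of each stratum's alive occupancy accrues the utility
decrement (0.03/yr, range 0.01–0.05) and the annual management cost
($1 198.60). This is exact for expected QALYs and costs because lymphoedema
affects no transition probability.

## Accounting conventions

* **Cycle accrual**: utilities and annual state costs (follow-up $254.10
  for disease-free and recurrence states; $24 340.11 for DM) accrue on
  half-cycle-corrected occupancy, the mean of the occupancies bounding the
  cycle. One-off transition costs (local recurrence $7 658.40, axillary
  recurrence $24 555.97, cancer death $29 615.97, other death $8 659.10)
  apply to the entrant flow of the cycle without correction.
* **Discounting**: end-of-cycle factors `(1.05)^(−t)`, t = 1…20, applied to
  all cycle accruals. Upfront costs accrue before the first cycle,
  undiscounted. With a zero rate, discounted and undiscounted results are
  identical by construction.
* **Upfront costs**: pathway surgical cost (ALND $5 576.45; SLNB-negative
  $4 206.38; SLNB-positive-then-ALND $7 771.28, which embeds the ~79%
  reoperation pattern as a single pathway cost; SLNB-fail-then-ALND
  $5 576.45) plus the arm's expected adjuvant therapy cost.
* **Adjuvant therapy** (radiotherapy $5 130.40 at 86% uptake, first-line
  chemotherapy $16 160.43 at 30%, five years of endocrine therapy
  $10 960.95 at 81%, one year of trastuzumab $64 032.80 at 29%) is accrued
  identically in both arms at base case. The small between-arm uptake
  differences reported by the source trial (radiotherapy 89%, chemotherapy
  31% in the SLNB arm) reflect post-randomisation treatment variation, not
  a consequence of the staging strategy; charging them to the incremental
  cost would overstate SLNB's cost by ≈$315/patient. They remain available
  as config overrides (`uptake_radiotherapy_slnb`, `uptake_chemo_slnb`).
* **Competing risks**: annual probabilities within a state are applied
  additively as printed marginal probabilities, with a feasibility check
  that each row sums to ≤1 (violations raise an error naming cycle and
  state). No rate conversion is performed; the values are small enough that
  the difference is negligible.

## Background mortality

Other-cause mortality approximates early-2000s Australian female all-cause
mortality with breast-cancer deaths excluded, as a Gompertz schedule
`q(age) = A·exp(B·(age−58))` over ages 58–78. The two constants are
calibrated (once, then frozen; see `scripts/calibrate_mortality.py`) so the
ALND arm accrues 18.4 other-cause deaths per 1000 by year 5 and 160.1 per
1000 by year 20, giving q(58) ≈ 0.0030 rising to q(77) ≈ 0.0217. Absolute
arm totals (life years, QALYs, costs) inherit the accuracy of this
approximation; the incremental SLNB−ALND quantities and all thresholds are
insensitive to it because background mortality is identical across arms.

## Sensitivity machinery

* **One-way thresholds** are roots of the 20-year discounted incremental
  outcome (QALYs for effectiveness thresholds, cost for cost thresholds) in
  one parameter with everything else at base case, found by Brent's method
  (parameter tolerance 1e−8) after verifying a sign change across the
  search bounds; absent a sign change a non-converged result is returned
  with the endpoint values. Search bounds extend beyond the plausible
  ranges where the switch point lies outside them (node-positive risk is
  searched on [0.05, 0.80]). The FN axillary-recurrence risk is searched on
  the 5-year cumulative scale and mapped to the annual probability via
  `annual = 1 − (1 − cum5)^(1/5)`. A 201-point grid scan provides an
  independent check in the test suite.
* **Preference planes**: for nodal-risk scenarios 27% and 50%, 3×3 panels
  over (FN rate level) × (5-year recurrence-given-FN level), each mapping
  the QALY-preferred strategy over a default 41×41 grid of ALND lymphoedema
  probability × lymphoedema disutility. Ties (|ΔQALY| < 1e−10 per 1000) are
  a distinct value; infeasible cells are flagged, not fatal. The published
  figure's exact axis ranges are not available, so axes default to the
  plausible parameter ranges (0.1312–0.2112 and 0.01–0.05) and are fully
  configurable. Panel levels default to the plausible low/base/high of the
  FN rate and, for the recurrence axis, the low/base annual values mapped
  to the 5-year scale plus the conservative 30% upper level. Under these
  defaults the low/low panel prefers SLNB in ~98% of cells (the
  minimal-benefit corner can still flip) and the high/high panel prefers
  ALND everywhere.
* **Tornado**: one-way swings of the incremental outcome over each
  probability/utility range and over the ±20% multiplier band applied to
  every cost item, sorted by swing.

## Microsimulation oracle

`slnb_cea.microsim` draws individual patients through the same decision
tree and yearly rules, implemented independently of the engine (per-patient
history flags versus the engine's expanded matrix layers), so agreement is
evidence both encode the same process rather than a shared bug. Events are
realised at year end and accruals use the end-of-year state without
half-cycle correction; means therefore converge to a cohort run with
`half_cycle_correction=False` (exact in expectation), and differ from the
corrected run by at most the half-cycle re-weighting. The test suite
asserts 3-standard-error agreement at 200 000 patients for the base case
and five random parameter sets, both arms.

`draw_parameter_sets` samples independent uniforms over each parameter's
plausible range (uniform chosen because the sources give ranges, not
distributions) and ±20% multipliers per cost item, with feasibility
checking and bounded redraws. It exists to exercise the sensitivity and
validation machinery; the model's own results are deterministic.

### What the simulation does and does not emulate

The microsimulation realises exactly the stochastic process the cohort
model takes expectations over: staging misclassification, lymphoedema
assignment, recurrence/progression/death with the printed annual
probabilities. Passing tests therefore demonstrate internal consistency of
the two implementations and correct accounting — they cannot validate the
model against real patients. In particular, real data would exhibit
patient-level heterogeneity in hazards, correlated risks (e.g. between
nodal status and distant-metastasis risk beyond the two printed levels),
non-annual event timing, and treatment changes over calendar time, none of
which the model represents.

## Numerical choices

* Cohort mass is conserved to 1e−12 per cycle (asserted); transition
  matrices are validated row-stochastic at construction.
* Stratum weights must sum to 1 within 1e−12; the staging tree rejects
  `f + fn > 1`.
* Threshold ties in preference planes use an absolute 1e−10 per-1000
  tolerance; bisection convergence requires the residual incremental
  outcome below 10× the stated tolerance (default 1e−3 per 1000).
* All computations are double precision; the full two-arm comparison runs
  in ~2 ms, a 41×41×9-panel plane set in under a minute on one CPU.

## Known limitations

* The cost perspective is the Australian health system only; patient and
  societal costs of lymphoedema are excluded and likely understate its
  burden.
* Anxiety and treatment-delay harms of staged surgery are not modelled.
* No contralateral or second primary cancers, and no treatment-sequence
  modelling beyond the printed state costs.
* The published cost-threshold block (e.g. "cost of ALND below which SLNB
  is no longer cheaper") appears to be expressed against a total treatment
  cost including an unprinted component common to both arms; this package
  reports cost thresholds against its own explicit cost fields, so those
  particular threshold values are not comparable with the published ones,
  although the effectiveness thresholds are.
* Utilities derive from a standard-gamble study in a breast-cancer
  population; the lymphoedema decrement (0.03) is an assumption anchored to
  the smallest clinically important utility difference, and the results are
  sensitive to it — which is precisely what the threshold analyses
  quantify.
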