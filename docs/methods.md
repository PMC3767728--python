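# Methods

## Model structure

`bloodsim` is an individual-patient Monte-Carlo model. Each simulated
patient receives a fixed profile (procedure stratum, age, sex, weight,
estimated blood volume, baseline hemoglobin, comorbidity flags, drawn
surgical blood loss) and is then cloned into three management arms that
share that profile bit for bit. The arms differ only in the preoperative
hemoglobin preparation; surgery, transfusion, events, stay and costs follow
identical rules downstream. All money flows are euros from the hospital
perspective for a single admission; there is no discounting, no QALY
computation, no post-discharge resource use and no modelling of epoetin
adverse events or fluid management.

### Patient creation

1. A population-mix table (one row per procedure stratum × age band × sex
   cell, with a probability mass per cell) is indexed at random.
2. Age is drawn as a uniform integer within the cell's band. The source
   structure assigns only bands; uniform-within-band is the
   least-informative completion and is configurable by replacing the table.
3. Weight ~ Normal(cell mean, cell SD), clamped below at 35 kg; estimated
   blood volume is weight × 65 ml/kg.
4. Baseline Hb ~ location + scale·Weibull(shape), sex-specific, clamped to
   the physiological range 6–18 g/dl.
5. Comorbidities are independent Bernoulli draws: revision surgery and
   ASA ≥ III at cell-level probabilities, rheumatoid arthritis at a
   procedure-specific probability, cardiac history at a population-wide one.
6. Surgical blood loss (in g/dl Hb) ~ Normal(procedure mean, SD) truncated
   at 0, multiplied by 1.05 if ASA ≥ III, 1.05 if age ≥ 75 and 1.25 for
   revision. The modifiers compose multiplicatively: the sources quote each
   as an independent percentage increase, and a symmetric composition is
   the only order-free choice; the zero-correlation scenario sets all three
   factors to 1.0, bounding the (unknown) covariance between them from
   below.

### Arms

* **ABT** passes the baseline Hb through unchanged.
* **PAD** (baseline Hb ≥ 11 g/dl only) banks two autologous units and draws
  a single cumulative Hb decrement for both donations. The decrement is
  `max(0, Normal(μ*, σ))` where `μ*` is solved (Brent's method, cached) so
  that the *realized* mean equals the configured mean effect (−1.2 g/dl
  base case, σ = 0.83). Rationale: the headline "PAD effect on
  preoperative Hb" is a mean effect size; a naive folded or clamped normal
  centred at 1.2 would bias the realized mean upward by 0.03–0.06 g/dl,
  and donation should never raise Hb. Ineligible patients proceed exactly
  as in ABT, with no units and no charge.
* **EPO** applies a check-then-dose loop on the running Hb: while it is
  below the termination threshold and the injection count is below the
  regimen maximum, one dose is given and a truncated-at-zero normal
  increment (mean 1.0, SD 0.6 g/dl per injection) is added, scaled by 0.8
  for rheumatoid arthritis (epoetin hyporesponsiveness; magnitude not
  published, configurable). Under the Weber protocol variant the final
  scheduled dose falls on the day of surgery: it is charged but cannot act
  on the Hb at incision, so it increments the dose count only. The
  increment parameters were chosen so that patients entering in the
  10–13 g/dl band average about two injections and a cumulative rise of
  roughly 2 g/dl, matching the trial regimen the dosing rule encodes.

### Surgery and events

Post-operative Hb = arm-adjusted preoperative Hb − blood loss, floored at 0.
The effective trigger is the configured trigger (8.5 g/dl base case) plus
1 g/dl for cardiac history, applied whatever the base trigger. A patient
strictly below the trigger receives ⌈deficit / (Hb per unit)⌉ units (1 g/dl
per unit by default), banked autologous units first; a patient exactly at
the trigger already "meets" it and receives nothing (the equality semantics
of the source description are contradictory; the boundary is exposed as the
config switch `transfuse_at_equality`, default off). Infection
(2%/4% by transfusion status; acts only through the stay) and pneumonia
(0.8%/1.6%; direct €5,000 charge) are sampled independently. Length of stay
is the stratum's base stay times 1.2 (transfusion only), 1.6 (infection
only) or 1.9 (both), kept fractional for costing; an old-age stay
multiplier exists but defaults to 1.0 (the source mentions an age
adjustment without a magnitude).

### Costing and contrasts

Per-episode cost = doses × €200 + allogeneic units × €320 + €500 flat for
every PAD-applicable patient (whether or not the banked units are
reinfused; autologous units carry no per-unit charge) + days × €300 +
€5,000 per pneumonia event. Incremental costs are paired: the arms are
clones of the same patients, so the contrast is the mean and SE of
per-patient differences, which removes between-patient variance from the
comparison.

## Random-number architecture

Every draw comes from a PCG64 generator keyed by
`SeedSequence((seed, patient_id, arm, event))`. Characteristics use one
stream per patient; PAD/EPO preparation, infection and pneumonia each use
their own per-arm sub-stream. Consequences: (a) the whole pipeline is a
pure function of the seed, reproducible file for file; (b) all scenarios
run on identical patient populations (common random numbers), so scenario
deltas are parameter effects; (c) changing one arm's parameters never
perturbs another arm's event draws.

## Synthetic population fixture

The bundled generator emulates the German elective arthroplasty case mix:
57% hip, 62% female, age mass centred near 71 years, 10.4% revision risk,
≈40% ASA ≥ III, base stays of 12.5–15 days across four procedure strata,
and sex-specific baseline-Hb Weibulls — female (shape 9.5, scale 14.3),
male (10.5, 15.67) — calibrated in closed form so that 23.2% of patients
fall in the 10–13 g/dl reporting band with ≈80% of them female. What it
does **not** emulate: real DRG codes and their per-stratum risk structure,
any correlation between comorbidities, stratum-specific revision risks, or
the empirical (non-Weibull) shape of a chart-review Hb distribution.
Passing tests therefore demonstrate the mechanism and its orderings
(transfusion-rate gradients, arm dominance, cost signs), not numeric
agreement with any particular hospital's case mix; all table columns and
distribution parameters are replaceable via CSV + config.

## Reporting conventions

Bands are half-open `[lo, lo+0.5)` from 10.0 to 13.0 g/dl; a patient at
exactly 11.0 belongs to `[11.0, 11.5)`. PAD columns and the PAD−EPO
contrast are suppressed below 11.0 g/dl, where donation is not indicated.
Every cell is `mean (SE; SD)` with SE = SD/√n; "units per transfusion"
averages over transfused patients only; percentage cells are statistics of
the 0/100 patient indicator, so their SD is the binomial spread. Empty
bands are written as missing markers, never zeros. The revision-only
scenario filters records to revision patients before stratification.

## Structural properties worth knowing

* Transfusion probability falls strictly across Hb bands in the ABT and
  PAD arms — their post-operative Hb shifts one-for-one with baseline. In
  the EPO arm the injection loop retargets every treated patient toward
  the same termination Hb, flattening the mid-band transfusion rates;
  only the overall first-to-last band decline is structural, and the
  test suite asserts exactly that.
* With common draws, EPO can only reduce a patient's units relative to
  ABT (increments are non-negative), so EPO transfusion rates are
  dominated by ABT rates per band.
* Scaling all five unit costs jointly rescales every cost component and
  every incremental contrast exactly, given fixed event draws.

## Problem sizes and numerical choices

Default runs simulate 50,000 patients (≈15 s on one core); the test suite
uses a shared 10,000-patient base run for structural assertions, 10⁵ draws
for distribution-recovery checks and 10⁶ draws for the pneumonia rates,
sizes at which the binomial/CLT error is several times smaller than each
asserted tolerance. Ceiling computations subtract 10⁻⁹ before rounding up
to keep exact unit multiples from tipping over by float noise; the PAD
truncation location is solved to machine precision and cached per
(mean, SD) pair; stays and costs are kept fractional internally and
formatted only in reports.

## Known limitations

Infection probabilities, the rheumatoid epoetin attenuation, the Hb gain
per RBC unit and the per-injection increment distribution are not published
at the source and are exposed as configurable defaults chosen for
plausibility; absolute cost levels therefore carry those assumptions even
though the orderings are robust to them. Comorbidities are drawn
independently, arms share no hospital capacity constraints, and mortality,
thromboembolic events and reimbursement are out of scope.
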