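# Methods

## Decision model

The analysis compares two erythropoiesis-stimulating agents (ESAs) in
chronic haemodialysis patients: epoetin beta (EpoB) given three times a week
and CERA given once a month, in a two-phase crossover design (six months on
each agent, 75 patients). The decision model is a two-arm tree: each arm is
a chance node whose branches are treatment success — phase-mean haemoglobin
(Hb) inside the target range — and failure, with probability equal to the
arm's clinical success rate (CSR). The success leaf pays effectiveness 1,
the failure leaf 0; leaf costs are the mean annual drug-acquisition cost
within the corresponding Hb group. Rolling back yields E[cost] =
p·c_success + (1−p)·c_fail and E[effectiveness] = p. When per-group costs
are unavailable (they are not published), both leaves carry the arm-mean
annual cost, so rollback returns the arm mean exactly; the tree structure
is kept so that patient-level runs use genuine per-group leaf costs.

Assumptions inherited from the study design: payer perspective; drug
acquisition is the only cost (hospitalisation, visits and monitoring are
taken as equal across arms); one-year horizon with all costs in year 0, so
the 3% annual discount rate is implemented and tested but inert in the base
case; a 6-month phase cost annualises by doubling (two identical half-year
blocks). Published annual means (3288.49, 3030.19 $) are not exactly twice
the rounded 6-month means (1644.2, 1515.5 $); we take the annual figures as
doublings of unrounded means and never re-derive one printed number from
another.

## Effectiveness and classification

A patient-phase is classified by the mean of its six monthly Hb values
against the target range, default 10.5–12 g/dL as a **closed** interval
(the protocol targets Hb "within" the range; a config flag gives the
half-open variant). CSR is the in-range proportion; below- and above-range
patients are pooled as failures. Two effectiveness definitions coexist and
are never substituted silently:

* `CSR` — the computed success proportion (0.6533 / 0.7067 at the published
  counts 49/75 and 53/75); used for patient-level runs.
* `TABLE` — the published model's "average effectiveness" (0.55 / 0.59),
  whose derivation from CSR is not stated; used to replay the published
  base case. Back-dividing the published ACERs implies unrounded values
  ≈0.547/0.586, so full-precision ACERs computed here (5979.07, 5135.92 $)
  differ from the printed 6013.86/5173.64 $; the ICER, which the published
  table computes from the printed inputs, reproduces exactly (−6457.5).

Report percentages round half-up to one decimal, with a trailing `.0`
dropped, matching the published tables' mixed precision.

## Incremental analysis and the threshold decision

ΔC and ΔE are CERA minus EpoB; ICER = ΔC/ΔE keeps its sign and is flagged
undefined (NaN) at ΔE = 0, and is always reported with the
cost-effectiveness-plane quadrant, because a negative ratio alone cannot
distinguish dominance (cheaper, more effective) from being dominated. The
ICER is computed on the proportion scale (ΔE = 0.04), matching the
published arithmetic; a per-percentage-point rescale (÷100) is exposed as a
clearly labelled report property.

The willingness-to-pay threshold is λ = 3 × per-capita GDP = 3 × 3092 =
9276 $ per unit effectiveness (a literal override is available; we compute
3×GDP rather than adopting any independently printed constant). The
decision is net monetary benefit: cost-effective iff λ·ΔE − ΔC ≥ 0. This
reduces to the familiar ICER ≤ λ rule in the north-east quadrant and to
ICER ≥ λ in the south-west quadrant (savings must outweigh the
effectiveness forgone); dominant results are always accepted and dominated
ones always rejected. An ICER-only rule is ambiguous in the south-west
quadrant, which ±10% effectiveness variations actually reach, so the NMB
form is the design choice here.

## Deterministic sensitivity analysis

One-way and two-way analyses vary the four base inputs (per-arm annual cost
and effectiveness) **multiplicatively**, default ±10%. Every scenario
re-runs the full incremental analysis and records dominance and whether the
threshold decision flips. Effectiveness products are clamped to [0, 1] with
a warning. With the published base inputs no single ±10% bound changes the
conclusion, which the test suite asserts for all eight bounds.

## Probabilistic sensitivity analysis

Per draw, the four inputs are sampled independently and pushed through the
same engine (no re-derivation of the formulas): log-normal distributions
for costs and normal for effectiveness, per the model's convention.
Published PSA distribution parameters are not available, so the defaults
are a documented reconstruction: costs LogNormal(arithmetic mean = arm mean
annual cost, SD = annual SD/√75, the standard error of the mean) and
effectiveness Normal(CSR, binomial standard error), every value
overridable. The log-normal is parameterized by arithmetic mean/SD,
converted internally (σ² = ln(1 + s²/m²), μ = ln m − σ²/2). Effectiveness
draws are truncated to [0, 1].

Summaries: quadrant shares on the CE plane (axis draws assigned to the
adjacent quadrant clockwise, deterministically, so the four shares always
sum to 1); ICER quantiles (2.5/50/97.5%) over draws with ΔE ≠ 0, zero-ΔE
draws reported in an "undefined" bucket; the share of per-draw ICERs within
±10% of the base ICER (band endpoints ordered numerically, so a negative
base gives [1.1·base, 0.9·base]); and the cost-effectiveness acceptability
curve, P(λ·ΔE − ΔC > 0) over a λ grid (strictly positive: a zero-NMB draw
does not count as acceptable).

Under any independent sampling of the published standard deviations the
dominant-quadrant share is far below 1 (≈0.64 with the default
reconstruction); a claimed 100% concentration is reachable only in the
degenerate all-fixed limit, which is implemented and tested as such. The
package reports whatever its configured specification yields.

## Synthetic cohort generator

No patient-level data exist for this design, so a generator emulates the
75-patient crossover cohort; it is first-class, tested code.

* **Hb dynamics.** Per patient-phase, a latent setpoint ~ Normal(phase
  mean, setpoint SD); monthly Hb = setpoint + stationary AR(1) deviation
  (marginal SD 0.4 g/dL, lag-1 correlation 0.5 — chosen as typical
  month-to-month laboratory variability with moderate persistence). The
  6-month mean is then exactly normal, and the setpoint SD is calibrated by
  root-finding so that P(phase mean ∈ [10.5, 12]) equals the arm's target
  CSR (defaults 49/75 and 53/75). Simulated success counts are therefore
  Binomial(75, target) by construction, which is what the
  parameter-recovery tests exercise at targets 0.3/0.65/0.9. At the
  defaults the calibrated setpoint SDs (≈0.76 and 0.65 g/dL) come out close
  to the observed phase SDs 0.73/0.63, an independent consistency check.
* **Doses and titration.** Starting doses are drawn from the observed arm
  distributions (EpoB 6104 ± 3178 IU/week; CERA 106.4 ± 50.1 µg/month;
  floored at 5% of the mean). Each month the protocol titration applies:
  −25% after an Hb rise > 1 g/dL/month, +25% after a fall > 1 g/dL/month,
  at most one adjustment per month. The EpoB→CERA conversion table
  (<8000 IU → 120 µg; 8000–16000 IU inclusive → 200 µg — both endpoints in
  the middle tier, the only reading consistent with all three clauses;
  >16000 IU → 360 µg) is available via `cera_dose_mode="protocol"`; the
  default `"observed"` mode samples steady-state CERA doses directly,
  because the observed phase means already reflect the post-conversion
  down-titration and a conversion-table start would inflate CERA costs by
  roughly a third.
* **Iron rule.** IV iron starts when ferritin < 100 ng/mL or TSAT < 20%,
  stops when ferritin > 800 ng/mL or TSAT > 50%; contradictory triggers
  resolve stop-first (safety).
* **Costs.** Monthly cost = dose × unit price; EpoB weekly doses are costed
  at 13/3 weeks per month so a 6-month phase spans 26 weeks (a quarter is
  13 weeks; a config override exists). Unit prices are back-solved from the
  observed means: 10.36 $/1000 IU = 1644.2/(6104·26/1000) and
  2.374 $/µg = 1515.5/(106.4·6), verified by direct multiplication.
* **Dose feedback.** `dose_response` (g/dL per dose unit above the arm
  mean) defaults to 0: Hb is exogenous and the titration tracks it without
  altering it, as at observational steady state. This keeps the CSR
  calibration exact; with feedback enabled the calibration is approximate.
* **Reproducibility.** One seed per run; each patient-phase gets an
  independent substream keyed by (seed, arm, patient index), so
  trajectories are invariant to cohort size and ordering.

What the generator does **not** emulate: within-patient correlation between
the two phases (phases are independent), correlation between dose and Hb
level, dose quantisation to vial sizes, transfusions and adverse events,
and any pharmacokinetics of CERA's long half-life. Passing tests therefore
show that the pipeline is correct and calibrated to the observed summary
statistics, not that the generator reproduces real patient physiology.

## Numerical choices

* Currency arithmetic at full float precision; rounding (half-up) only at
  report time.
* Degenerate inputs: zero effectiveness makes the ACER NaN (flagged, not
  raised); ΔE = 0 makes the ICER undefined; an arm with no successes has an
  undefined (None) success-leaf cost; empty arms are errors.
* Axis ties: for the incremental result's dominance label, DOMINANT /
  DOMINATED require strict inequalities and axis points fall to the
  adjoining trade-off label; PSA quadrant shares use the clockwise rule
  above.
* Cohort CSVs are written with 17 significant digits and read with
  round-trip float parsing, so write→read is bit-identical.
* Brentq on a bracket [1e−9, 100] for the CSR calibration; targets must lie
  strictly in (0, 1) and the phase mean strictly inside the target range.

## Problem sizes

The default PSA runs 50 000 iterations (matching the published analysis);
unit tests use 500–20 000 draws where distributional agreement is already
decisive at that size. Simulator calibration checks use the full 75-patient
cohort over 200 replicate seeds per target.

## Known limitations

* Two arms only; no Markov/state-transition extension, no QALYs (the study
  measured neither utilities nor survival), no EVPI.
* The inflation adjustment is a single multiplicative factor (index values
  are not published; default 1.0).
* The published "average effectiveness" cannot be re-derived from the
  published CSR; both are carried, and ACERs computed at full precision
  differ slightly from the printed ones (see above).
* PSA parameter correlation (e.g. paired bootstrap) is declared in the
  interface but only independent sampling is implemented; the published
  analysis states no correlation structure.
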