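# Methods

`ahc_cua` is a decision-analytic cost–utility model comparing two primary-care
strategies for adults with intellectual disability (ID) followed from age 40
until death: **annual health checks (AHC)** — yearly structured check-ups in
general practice — versus **standard care**. The outcome is the incremental
cost per quality-adjusted life year (QALY) gained, from a health-service
perspective in 2016 GBP, with costs and QALYs discounted at 3.5% per year to
age 40.

## Model structure

The analysis is a set of independent, condition-specific annual-cycle cohort
models whose discounted incremental costs and QALYs are summed, plus the
present value of the yearly check itself:

ΔC = PV(intervention) + Σ_c ΔC_c,  ΔQ = Σ_c ΔQ_c,  ICER = ΔC / ΔQ.

Eight conditions are modelled. Five are state-transition Markov models run
through a shared cohort engine:

| condition | start age | states beyond Well/Dead | arm difference |
|---|---|---|---|
| hypertension | 40 | undetected / managed / unmanaged, stroke and CHD with first-year tunnels | probability identified-and-managed × adherence 75% |
| glaucoma | 40 | undetected, treated and untreated mild/moderate/severe, visual impairment | eye-exam referral 90% vs 58.9% |
| osteoporosis | 50 | undetected / treated / untreated, hip fracture two-year tunnel, post-fracture | investigation (DXA) 85–95% vs 66.2–86.8% |
| bowel screening | 60 | bowel cancer | FOBT participation +4.1–7.8 pp |
| breast screening | 50 | breast cancer (women only) | mammography participation 54.3–59.3% vs 47–52% |

Three conditions are **cascades**: their published evidence arrives as
branch probabilities plus present-value lifetime cost/QALY deltas, so the
models propagate survival-weighted incident (or at-risk) fractions and
assign the deltas at the cycle of benefit — diabetes (closer monitoring of
incident cases, lifetime deltas by obesity stratum), cataract (referral →
glasses or surgery with a one-off QALY gain), and hearing (wax removal with
a one-off utility gain; hearing-aid provision with an annual utility gain
and follow-on cost while alive).

Within a cycle, competing risks are ordered death → disease event →
identification, and residual probability is always assigned explicitly to
the stay state — the engine refuses any transition row that does not sum to
one, naming the age and state, rather than re-normalising silently.

### Cohort engine conventions

- Cycle length one year; cohorts run to an absorbing cap at age 100
  (survivorship beyond is negligible and the cap bounds runtime).
- Half-cycle correction is trapezoidal: the accrual of cycle *k* uses the
  average of the occupancies at its start and end. One-off costs and QALY
  deltas (diagnosis, tests, surgery, lifetime deltas) attach to transitions
  and are not half-cycle corrected.
- All present values are discounted to the common base age 40; models
  starting at 50/60 carry a discount offset of 10/20 years and are scaled by
  the probability of surviving from 40 to their start age.
- The intervention annuity pays the yearly check cost while alive,
  half-cycle corrected consistently with the engine. Every alive cohort
  member is costed (the published per-person figure is treated as gross of
  uptake).

### Mortality

Background mortality comes from a single-year life table. The packaged
synthetic table is a Gompertz law, qx(age) = 1 − exp(−a·e^{b·age}) with
b = 0.095 and a solved so period life expectancy at birth is 81 years
(England-like). The threefold excess mortality of adults with ID is applied
as probability scaling min(1, 3·qx) (a hazard-scaling alternative,
1−(1−qx)^3, is available for sensitivity checks). Condition-specific death
(the managed-hypertension death relative risk, the bowel-screening absolute
death-risk reduction, breast-cancer death) acts on top of background
mortality inside the condition models; background qx is not decremented for
those causes — a small, documented double-count.

## Parameters

Every model input is registered by name with the range it was published
with, a category, and provenance. Percent entries are normalised to
proportions at load. The base case resolves each range to its **midpoint**
unless an explicit point was published (adherence 75%, obesity 33.5%,
prescription 99.6%, over-diagnosis RR 1.19, referral 90%, bowel
death-risk reduction 1.01 pp). Six inputs the source tables do not print are
shipped as loudly tagged assumptions: standard-care FOBT participation
(49–59%), the cohort's female proportion (0.5), the annual breast-cancer
death probability (2–5%), the treated hip-fracture relative risk (0.5–0.7),
the visual-impairment utility (0.47–0.61), and the diabetes/hypertension
overlap adjustment (0).

### Distributions for probabilistic analysis

Families follow standard practice: beta for probabilities, proportions and
utilities (method of moments; an infeasible SD is shrunk to the largest
feasible value and logged), gamma for non-negative costs, lognormal for
relative risks, truncated normal for signed differences, and a point mass
for degenerate ranges. Where a mean (SD) was published (diabetes management
69.9%±34.2 / 56.8%±29.4, eye referral 58.9%±0.24) the published SD is used
directly. Fitted means always equal the base-case point; for truncated
normals the location is re-solved so the *truncated* mean matches. Signed
deltas whose published range does not cross zero are truncated at zero —
a published "utility gain" cannot flip sign in sampling.

How a published range maps to a spread is configurable
(`interpretation`): `half_range_sd` (range = mean ± 1 SD, the default),
`ci95` (range = central 95% interval), `minmax` (range = hard support,
scaled beta). The default was identified from the published probabilistic
results themselves: the printed SDs of incremental cost and QALYs are
almost exactly twice what the ci95 reading produces and match the ±1 SD
reading, so the latter evidently reflects the dispersion the original
analysis propagated. All draws are mutually independent (no correlation
structure was published).

## Sensitivity analysis

The PSA draws every parameter once per iteration and evaluates all eight
condition models and the intervention annuity with that single draw; both
strategy arms always see the same draw (common random numbers), so arm
differences never reflect sampling noise. One root seed spawns one
counter-derived substream per draw, making every draw reproducible from
(seed, index) alone. Summaries report means, SDs and 2.5/97.5 percentile
intervals of incremental cost and QALYs, the cost-effectiveness
acceptability probabilities at £20,000 and £30,000 per QALY, and **both**
ICER statistics: the ratio of means, and the mean of per-draw ratios over
draws with positive QALY gain (excluded-draw count logged). The headline
figure is the mean of per-draw ratios, which exceeds the ratio of means
under positive skew (Jensen); the published mean ICER is consistent with
that convention. One-way sensitivity analysis pins one parameter at a grid
of values, keeps all other parameters at their PSA distributions, and reuses
the common seed across rows, so differences between rows are exact.

## Structural choices where the design was open

- **Repeated identification.** Identification/referral probabilities are
  re-applied to the undetected pool every cycle in both arms (an annual
  check re-screens; standard care also eventually finds cases). This makes
  the arms differ in *when* conditions are addressed rather than whether,
  and is conservative relative to a one-shot reading.
- **Hearing pool dynamics.** The 2–13.4% figure is treated as the annual
  probability that a person without an addressed problem presents an
  unaddressed hearing problem. Completed cascades (wax removed, assessed
  without aid need, aid fitted or declined) leave the at-risk pool;
  non-referred and non-attending people remain and retry.
- **Bowel cascade costs.** Screening-yield costs (kits, colonoscopy, polyp
  removal, bleeding, screen-detected treatment) follow the published
  conditional cascade on the cancer-free state; incident cancers in
  non-participants incur the clinically-detected treatment cost at
  transition. Screening is applied every annual cycle (the national
  two-yearly schedule is not modelled; a schedule interval would scale
  participation).
- **Cataract glasses branch** is cost-only (test and diagnosis costs; no
  published utility gain or glasses cost).
- **Baseline well utility** (0.704–0.909, the published general-population
  weight) is reused as the well-state weight in every state model so that
  mortality differences are valued consistently; absolute well-state
  utilities cancel in the increments except through survival differences.

## Synthetic data and what passing tests show

The synthetic life table reproduces the *level* and age-slope of England-like
mortality but none of its cohort effects or cause structure; the parameter
fixture reproduces published ranges, not patient-level heterogeneity; and
all parameters are sampled independently. Tests passing on these inputs
demonstrate that the machinery is correct and that the published summary
statistics are recovered under the stated readings of the inputs — not that
the model predicts outcomes for any real cohort.

## Numerical choices

Transition-row sums are enforced to 1e-9; occupancy conservation drifts
below 1e-9 over 60 cycles. Present values use exact power discounting, no
approximation. Intervention component costs are rounded to whole pounds
before summation so the published £258/year is reproduced exactly from its
time-and-rate build-up. ICER dominance is reported through flags, never
exceptions, so PSA draws cannot abort a run.

## Problem sizes

The shipped analyses use 1,000 Monte Carlo draws (the published experiment
size); at that size the full PSA plus a one-way row evaluates 32,000 cohort
models and completes in a few minutes on one CPU. Engine validation uses
100,000–200,000-individual micro-simulations against random 3–5-state
models.

## Known limitations

- The original authors' exact base-case points live in an out-of-print
  technical report; the midpoint rule is a stand-in, and the calibration
  targets are therefore interval, not point, reproductions.
- Six undocumented inputs are assumptions (tagged in the fixture).
- No correlation between parameters; no value-of-information analysis;
  no carer costs, care-home admission, or societal perspective; excluded
  conditions (dementia, epilepsy, COPD, mental health, …) are out of scope.
- The probability of being cost-effective at £20,000 with a £50 check
  (published 70.1%) evaluates 2–5 points lower here across seeds: the
  aggregate QALY-gain distribution is right-skewed through the
  multiplicative hearing cascade, so slightly less mass clears the
  net-benefit threshold than a symmetric distribution with the same mean
  and SD would give. The corresponding mean ICER at £50 sits inside its
  published interval.
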