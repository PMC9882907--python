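# Methods

## Pathway model

The diagnostic pathway is a chain of three stages — symptom onset to GP
presentation (`s2gp`), GP referral to first neurology appointment
(`gp2neuro`), and neurology appointment to confirmed diagnosis
(`neuro2diagnosis`) — with two probabilistic detours: a delay before the
patient consults a GP at all (`gp_delay`, probability `p_gp_delay`) and
a delay when the consultation does not yield a referral (`ref_delay`,
probability `p_ref_delay`). Patients progress strictly sequentially;
re-presentation loops, diagnoses made outside neurology, private care
and competing risks are out of scope. The total time to diagnosis is
the sum of the stage durations that occur.

Each stage duration is `minimum + Gamma(shape, scale)`. `mean` and `sd`
parameterise the gamma part only (they exclude the minimum offset):
`shape = (mean/sd)²`, `scale = sd²/mean`. Anchoring by a minimum shifts
the support, which is the only reading under which the anchor changes
what durations are feasible. `sd = 0` is admitted as an explicit point
mass at `minimum + mean`; this never arises in realistic configurations
but makes closed-form tests exact. Durations are real-valued days; no
rounding rule is applied anywhere.

A simulated patient is classified as an **emergency presentation** when
`total ≥ survival_median − emergency_window` (closed inequality; the
boundary convention is fixed so the rule is exactly testable). Defaults:
`survival_median = 548` days — eighteen 30.44-day months, reflecting
that nearly half of people with MND die within 18 months of symptom
onset — and `emergency_window = 30` days. A mixture of subtype-specific
survival medians is supported (per-patient stratum draw) but ships
disabled because no subtype-level medians are published for this rule.
Patients who pass the threshold are not removed from the cohort; all
summary statistics are over all simulated patients.

The detour convention is `delay occurs iff r < p_delay` with `r`
uniform on [0, 1]; `p_gp_delay`/`p_ref_delay` are therefore stated
everywhere as the probability **of** the delay happening.

## Sampling and common random numbers

`simulate_cohort(config, n, seed)` draws one fixed-layout block of
uniforms (n × 7: five stage columns plus the two detour columns) and
maps stage columns through the gamma quantile function. Consequences:

* a given `(n, seed)` reuses identical uniforms for *any* parameter
  values, so scenario comparisons and calibration objectives are
  common-random-number comparisons by construction;
* results are bit-reproducible for a fixed seed;
* dilating a stage multiplies each of its sampled durations exactly,
  making the scenario-dominance properties hold patient by patient.

Inverse-CDF sampling costs ≈0.5 s per 100,000-patient cohort, which
keeps the full test suite and all shipped analyses in seconds to a few
minutes.

## Survey fitting

Waiting-time questions in the care survey offer seven ordered duration
categories (<1 month, 1–3, 3–6, 6–9, 9–12 months, 1–2 years, ≥2 years;
month = 30.44 d, year = 365.25 d, stated once as the calendar-average
convention). Per-category counts were never published — only usable
totals (621 and 646 of 699 respondents) — so all fitting is exercised
on synthetic tables that emulate the structure: gamma-distributed truth,
interval censoring, non-response.

The fit follows the expand-then-fit idea: sample 100,000 durations
consistent with the category counts, then fit a gamma (maximum
likelihood with the location fixed at the stated minimum; moment
matching available as an alternative). The open-ended top category is
sampled on `[lower, lower + top_width]` with `top_width` configurable
(default 365 days; bounded support is required to sample within the
bin).

Filling bins *uniformly* overstates the mean whenever the density
decays across the bins — for Gamma(2, 90) binned into the seven
categories the uniform-filled mean is 189.3 d against a true 180 d, a
+5% bias that no amount of sampling removes. The default fit therefore
iterates: after the uniform first pass, within-bin values are redrawn
from the current gamma conditional on their bin (holding the underlying
uniforms fixed) and the gamma refit, until the moments stabilise. The
fixed point approximates the interval-censored MLE; on the example
above it returns mean 180.0, shape 1.99, agreeing with an independent
interval-censored fit to the same table. Uniform expansion remains
available (`refine=False`) and is itself the first iterate.

## Pandemic scenarios

A scenario names a care tier — primary (`s2gp`, `gp_delay`), secondary
(`gp2neuro`, `ref_delay`, `neuro2diagnosis`) or both — and a delay
fraction f ∈ {0.25, 0.5, 0.75}. "Prolongation by f" is implemented as
uniform time dilation: mean, sd and minimum all multiplied by (1 + f),
equivalent to stretching every sampled duration and preserving the
gamma family (shape unchanged, scale scaled). Whether the minimum
anchor should dilate too is a modelling choice, made here for its
simplicity and pathwise monotonicity; it is documented, not asserted as
the only reading. Scenario detour probabilities *replace* the baseline
ones (they do not compound): 0.48 for GP avoidance and 0.50 for the
referral drop, taken from published service-activity reports for the
first UK lockdown.

## Calibration and the shipped baseline

No stage-level means, SDs, minimums or baseline detour probabilities
are published, while three pre-pandemic summary statistics are: median
time to diagnosis 399 days, 5.2% emergency presentations, 44.1%
diagnosed within 12 months. `calibrate_baseline` searches named
parameters (dotted paths with finite bounds) to minimise the sum of
squared standardised residuals of those statistics, evaluated on a
fixed-seed cohort so the objective is deterministic and smooth;
Nelder–Mead (with one fresh-simplex restart) is the default, seeded
differential evolution the fallback. Evaluations below n = 10,000
trigger a warning because Monte Carlo noise then rivals tight
tolerances.

The problem is under-determined — three targets, about a dozen free
parameters — so the package ships **one** documented solution, frozen
in `synthetic.py` (`default-calibrated`): minimums 7 / 14 / 14 days for
the three core stages (0 for the detours), core means 68.4 / 122.2 /
103.2 days with SDs ≈ 13–14 days, detour delays 136.9 ± 18.7 and
62.2 ± 20.1 days, and probabilities 0.479 / 0.118. The targets force
this broad structure: a fairly tight core distribution summing to
≈325 days, a high-probability GP-attendance detour supplying the mass
between the median and the emergency threshold, and a small joint
probability of both detours so that only ≈5% of patients cross that
threshold. The probability bounds were capped at 0.48 — the pandemic
estimate — on the reasoning that pandemic conditions should not make
the detours *less* likely than baseline. At n = 100,000 the shipped
config reproduces the three targets within ±2.1 days and ±0.15 / ±0.26
percentage points across arbitrary seeds.

Because other parameter vectors match the same three statistics,
pandemic-scenario *point* predictions (e.g. the median under
"both +75%") inherit the calibration choice and are reported as
qualitative; the orderings — worse with larger fractions, secondary
worse than primary, both worst, every scenario worse than baseline —
are invariant under common random numbers and are what the test suite
asserts.

## Synthetic data

`generate_survey` draws respondent-level durations from a chosen
`StepSpec`, drops a non-response fraction (tallied, mirroring the
survey's excluded "did not see them"/"can't remember" answers) and bins
the remainder. It emulates only the statistical structure the analysis
assumes — gamma truth, categorical censoring, independent non-response —
not respondent behaviour, survey weighting or the real (unpublished)
category counts; test fixtures built from it are fixtures, not facts.
Config profiles: `default-calibrated` (above), `fast-test` (degenerate
10/20/30-day chain, exact totals for unit tests), `heavy-tail`
(coefficient of variation > 1) and `jittered` (seeded ±10% perturbation
for closure tests).

## Numerical choices and limitations

* Sample median is numpy's midpoint-interpolated median; "within 12
  months" is `total ≤ 365` (inclusive).
* Gamma MLE guards exact zeros at 1e-9 days; bins with negligible mass
  under the current iterate fall back to uniform filling.
* Problem sizes: shipped analyses use n = 100,000 patients; tests use
  n = 20,000 where a 3-standard-error Monte Carlo argument suffices and
  n = 100,000 for the validation statistics.
* What passing tests show is internal consistency and recovery of
  *synthetic* truth under the model's own assumptions (gamma stages,
  independent detours, a single survival threshold). They cannot
  validate the pathway structure against real patient-level data, which
  remains unpublished.
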