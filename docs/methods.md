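# Methods

## Model structure

A closed-cohort Markov model with seven states: five pruritus-severity
states banded on the total 5-D Itch score (none ≤ 8, mild 9–11, moderate
12–17, severe 18–21, very severe ≥ 22), a kidney-transplant state, and
death. A transplant is treated as definitive for pruritus, so the
transplant state is absorbing except for death. Entry is restricted to
moderate/severe/very severe, matching the licensed population.

Time runs as a 12-week run-in of three 4-week cycles followed by 52-week
cycles to the horizon (default 42 years). End-of-cycle accrual and
discounting are the default; a half-cycle correction (average of start-
and end-of-cycle occupancy, mid-cycle discounting) is available as a flag.
The year-on-dialysis clock used to index the survival schedule starts at
model entry (prior dialysis vintage is not modelled); the annual cycle
ending at time 12/52 + y years draws on schedule year ⌈12/52 + y⌉.

## Transition estimation

For each arm, records are stratified by baseline severity. With Δ̄ₛ the
stratum mean week-12 score change and σ the change SD (default: pooled
within-stratum sample SD), a patient with baseline score b contributes the
destination vector of N(b + Δ̄ₛ, σ) mass over the bands, integrated
between half-integer boundaries (8.5, 11.5, 17.5, 21.5) because scores are
integers; tail mass goes to the extreme bands. The stratum row is the
average over its patients. This construction uses exactly the available
statistic (stratified mean change) and reduces to intuitive limits: the
identity matrix as Δ̄ₛ → 0, σ → 0, and first-order stochastically
"better" rows as Δ̄ₛ becomes more negative.

The none/mild rows cannot be estimated from entry data (no one enters
there); they reuse the moderate stratum's change model applied at the
band midpoint (6.5 and 10), so patients who improve into those states
still have onward dynamics. One matrix per arm is estimated from the
baseline→week-12 change and reused for every cycle; the engine accepts
distinct run-in and extrapolation matrices if a user wants per-phase
dynamics.

## Responder split and waning

At week 12 the treated arm splits into a responder sub-cohort (weight r,
difelikefalin matrix until transplant or death, accruing drug cost) and a
non-responder sub-cohort (weight 1 − r) that was treated through the
run-in (difelikefalin matrix, drug cost) and then discontinues to BSC
dynamics. The default response criterion is improvement by at least one
severity category; a ≥ 5-point score criterion (the scale's minimal
clinically important difference) is configurable — the underlying trial
reports do not pin down the definition, so it is an explicit knob.

Waning applies to every sub-cohort on BSC dynamics: at the end of annual
cycle y, the severity distribution over survivors is
(1 − w)·(no-waning projection) + w·(baseline distribution) with
w = min(y/10, 1). The no-waning projection is supplied by a companion
cohort evolved in parallel under identical survival-augmented matrices,
which makes the year-10 endpoint exact. The path is linear because only
the endpoint (return to baseline by year 10) is specified by the
underlying assumption. The mixture acts on the severity block only;
transplant and death mass are untouched. A consequence worth noting: with
identical matrices in both arms, arm traces coincide only when waning is
disabled, because responders are exempt from waning by construction.

## Survival

Annual death and transplant probabilities come from a year-on-dialysis
schedule (years 1–10; later years reuse year 10). Severity-specific
all-cause mortality hazard ratios — 1.11 (moderate), 1.02 (severe), 1.24
(very severe), from a published Cox analysis of bothered-by-pruritus
categories — are applied on the rate scale, p′ = 1 − (1 − p)^HR, which is
the correct transform for hazard-scale quantities and cannot leave [0, 1].
The sequence is non-monotone in severity; it is applied as published, not
smoothed. Annual probabilities convert to cycle length by
1 − (1 − p)^(weeks/52), so 13 four-week cycles compound exactly to the
annual value. Death and transplant compete by proportional scaling of the
severity row with the remaining mass. Post-transplant mortality is the
female-fraction mixture of life-table q at the cohort's current integer
age. Transplant probability is severity-independent.

## Economics

Each severity state carries an annual management cost plus an annual BSC
medication cost (moderate tied to mild, very severe to severe, per the
source-data conventions); dialysis cost is excluded from the base case
because mortality gains would otherwise be penalised by the cost of the
extra dialysis time. Drug cost is vials/session (⌈weight·0.5 µg / 65 µg⌉,
minimum 1, single-use vials) × £31.90 × 2.96 sessions/week × 52. The
printed yearly figure of £4915.02 implies an unrounded ≈ 2.963
sessions/week (2.96 gives £4910.05); `sessions_per_week` is exposed at
full precision. The 65 µg vial content is a configuration default — no
published vial strength was available to us. Adverse events are costed as
one GP appointment (£33.19) at a small equal rate in both arms and carry
zero QALY loss. A one-off transplant cost and an annual post-transplant
cost are synthetic defaults (£17,000 and £5,000/year), as the published
analysis does not print them. Both costs and QALYs discount at 3.5%/year.

## Synthetic cohort generator

The generator emulates the statistical structure the estimator assumes:
integer baseline scores from a discretised normal (mean 18, SD 3)
truncated to [12, 25]; week-12 score = baseline + round(N(µ_{arm,stratum},
σ)) clamped to [5, 25]; sex Bernoulli (female fraction 0.4); dry body
weight normal (75 ± 15 kg, truncated at 30 kg). The default change means
(difelikefalin −4.08/−5.08/−6.08, placebo −3.18/−3.68/−4.18 for
moderate/severe/very severe; σ = 5) were solved analytically, before any
simulation, so the expected proportions achieving a ≥ 5-point improvement
are 52.1% and 42.3% — the response proportions reported for the pooled
trials. A single integer seed drives one RNG stream per cohort.

What the generator does **not** emulate: correlation between baseline
severity and weight or sex, visit-level trajectories, dropout, and the
true joint distribution of the pooled trial data. Passing tests therefore
demonstrate the correctness and internal consistency of the machinery —
not that the synthetic base case reproduces the published trial-data
incrementals, which depend on patient-level data that are not public. The
shipped survival schedule (annual death probability rising 0.12 → 0.255
over years 1–10, transplant 0.045 → 0.015) and Gompertz-shaped life table
are synthetic fixtures chosen to give realistic UK haemodialysis survival
(about 50% at five years); both files are labelled synthetic.

## Sensitivity analyses

One-way: each scalar input is set to base ± 20% (absolute ranges
configurable), the pipeline re-runs, and parameters rank by the absolute
ICER swing, filtered at a £1000/QALY floor. Out-of-domain perturbations
clamp with a logged warning.

Probabilistic: utilities are beta (moment-matched, CV 0.1), costs gamma
(CV 0.1), hazard ratios log-normal (CV 0.1, mean-preserving µ = ln HR −
σ²/2), transition rows Dirichlet (α = row × 1000, roughly the pooled-trial
information size), schedule probabilities beta, and the responder fraction
beta with its binomial standard error. Every distribution has mean equal
to the base value, so the PSA mean converges to the deterministic result
up to Monte-Carlo error and higher-order nonlinearity. Draws follow a
fixed documented order from a single seeded stream, so iteration tables
are reproducible. CEAC probabilities are the fraction of iterations with
positive NMB at each threshold.

## Numerical choices and degenerate inputs

- Band integrals use the normal CDF; σ = 0 collapses to an indicator of
  the band containing the mean.
- Matrix rows are validated to sum to 1 within 1e−12; traces to 1e−10.
- Per-cycle death + transplant mass ≥ 1 raises rather than silently
  truncating.
- Life-table and schedule lookups clamp (ages to the tabulated range,
  years to 1–10).
- An ICER with ΔQALY = 0 is flagged `undefined`; sign-discordant
  incrementals are flagged `dominant`/`dominated`; NMB is always
  reported.
- Problem sizes in the defaults — 500 patients/arm, a 42-year horizon,
  1000 PSA iterations — run the full pipeline in seconds; the test suite
  uses 80–2000 patients and up to 5000 PSA iterations.

## Known limitations

State homogeneity is the usual Markov simplification: outcomes depend
only on the current severity band. The severity matrices estimated from a
12-week change are reused for annual cycles, a strong stationarity
assumption inherited from the modelling approach. Graft failure, dialysis
vintage at entry, treatment re-challenge, and age-adjustment of utilities
over the horizon are not modelled. With synthetic matrices the tornado
ranking need not match analyses built on the real trial data.
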