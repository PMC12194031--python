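# ckdap-cea

A Markov cohort cost-utility model of **difelikefalin plus best supportive
care (BSC) versus BSC alone** for moderate-to-severe chronic kidney
disease-associated pruritus (CKD-aP) in adults receiving in-centre
haemodialysis, from a UK healthcare-payer perspective.

CKD-aP is systemic itch affecting roughly half of haemodialysis patients;
it degrades sleep and quality of life and is independently associated with
higher mortality. Difelikefalin, a peripherally restricted kappa-opioid
agonist given intravenously after each dialysis session, is the only
licensed treatment. This package implements the full economic evaluation
as a tested, configurable pipeline driven by a **synthetic patient-level
cohort generator** (the underlying pooled trial data are not public), so
every stage runs end to end from a seed.

## Model

Seven health states: five pruritus-severity states defined by total 5-D
Itch score bands (none ≤ 8, mild 9–11, moderate 12–17, severe 18–21, very
severe ≥ 22), plus kidney transplant and death. Patients enter in the
moderate-or-worse states, pass through a 12-week run-in of three 4-week
cycles, then 52-week cycles to a 42-year horizon.

- **Transitions.** Per-arm severity matrices are estimated from
  patient-level records: within each baseline-severity stratum the mean
  week-12 score change Δ̄ₛ is computed, and each patient's destination
  probabilities are the mass of N(baseline + Δ̄ₛ, σ) falling in each band
  (half-integer boundaries 8.5/11.5/17.5/21.5).
- **Responder split.** At week 12 the treated arm splits: responders
  (≥ 1 severity-category improvement by default) continue difelikefalin
  until transplant or death; non-responders discontinue and follow BSC
  dynamics.
- **Waning.** The BSC-dynamics severity mix over survivors returns
  linearly to the baseline distribution by year 10; difelikefalin
  responders have no waning.
- **Survival.** Year-on-dialysis death/transplant probabilities (year-10
  values thereafter), with severity-specific mortality hazard ratios
  (moderate 1.11, severe 1.02, very severe 1.24) applied on the rate scale
  p′ = 1 − (1 − p)^HR; post-transplant mortality follows a sex-mixed life
  table.
- **Economics.** State utilities (e.g. none 0.744, moderate 0.589,
  transplant 0.712) and annual state + BSC medication costs; drug cost
  £31.90/vial, 0.5 µg/kg with vial rounding, 2.96 sessions/week; both
  costs and QALYs discounted at 3.5%/year. Outputs: per-arm totals,
  incremental cost/QALY, ICER = ΔC/ΔQ, and net monetary benefit
  NMB(λ) = λ·ΔQ − ΔC.
- **Sensitivity.** One-way ±20% perturbations with tornado ranking, and a
  probabilistic analysis (beta utilities, gamma costs, log-normal hazard
  ratios, Dirichlet matrix rows) with cost-effectiveness plane and
  acceptability curve.

## Worked example

```sh
ckdap-cea run --seed 1 --out demo
```

prints (synthetic default configuration, 500 patients/arm):

```
        quantity  difelikefalin_bsc          bsc  incremental icer_gbp_per_qaly
  total_cost_gbp       35140.406563 24254.049148 10886.357416          63073.06
total_life_years           5.185933     5.121834     0.064098
     total_qalys           3.667857     3.495258     0.172599
```

Read this as: over the lifetime horizon a treated patient accrues £35,140
in discounted costs and 3.67 discounted QALYs versus £24,254 and 3.50 on
BSC alone, i.e. the treatment buys 0.17 extra QALYs for £10,886 — an ICER
of about £63,000 per QALY under this synthetic calibration. (The
magnitudes of the incrementals depend on the synthetic transition
matrices; they are not estimates of the published trial-data results.)
`ckdap-cea psa --seed 1 --iterations 1000` adds the probabilistic
analysis, e.g. a cost-effectiveness acceptability curve over the £30–50k
willingness-to-pay thresholds. `ckdap-cea all` runs every stage and writes
traces, tables, a tornado plot and the CE plane to the output directory,
together with a `manifest.json` that reproduces the run.

All inputs live in one YAML file (see
`src/ckdap_cea/data/default_config.yaml`); pass `--config` to override any
subset of sections.

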