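# isatis

Scoring, reliability estimation and between-arm inference for the
**I-Satis** inpatient satisfaction questionnaire — the French national
instrument (32 items, 28 scored across six dimensions) — together with a
seeded synthetic two-arm cohort generator, so a complete
mode-of-administration comparison (web self-completion vs telephone
interview) can be exercised end to end without any patient-level data.

It is written for biostatisticians analyzing satisfaction surveys from
randomized two-arm designs, and for methodologists who want a testbed for
survey nonresponse and mode effects.

## What it computes

**Scores.** Item answer codes run 0–10: codes 1–5 are ordinal satisfaction
answers valued 0/25/50/75/100; codes 0/6/7/8 (item not relevant), 9
("don't know") and 10 (refusal) are treated as missing. A dimension score
is the mean of its valued items, defined only when at least 3/3/3/3/2/2
items (in the six dimensions' reporting order) are answered; the global
score is the mean of **all** valued answers over the 28 scored items,
defined only when every dimension score is defined. A returned
questionnaire with fewer than 16 completed items counts as a nonresponse,
and analysis is restricted to stays of at least two nights.

**Reliability.** Cronbach alpha per dimension and for the 28-item global
scale, `α = k/(k−1) · (1 − tr C / Σ C)` with the item covariance matrix
`C` estimated from pairwise-complete observations over score-defined
patients; percentile-bootstrap 95% CIs resampling patients within arm.

**Inference.** Fisher exact test (direct hypergeometric enumeration) on
participation; Wilcoxon–Mann–Whitney on completion delays; Monte-Carlo
permutation tests (patients shuffled between arms, add-one p estimator
`(1+#{|Δ*|≥|Δ|})/(B+1)`) for differences in means **and** in alpha; Cohen
d with pooled SD and bootstrap CIs.

**Simulation.** Item answers arise from an equi-correlated Gaussian latent
per dimension — `X_ij = μ[arm][d] + σ(√ρ·U_id + √(1−ρ)·e_ij)` — cut at
four thresholds into the codes 1–5, with arm-dependent response
probability, nonrelevancy/refusal injection, and arm-dependent completion
delays. The default calibration inverts the analytic latent→score link so
expected per-dimension means match the published per-arm score table, and
uses the published response rates (154/392 and 344/389).

## Worked example

```bash
isatis run-all --seed 11 --n-boot 500 --n-perm 5000 --out demo/
```

prints

```
report written to demo/report.json
internet: 147/392 responders (37.5%)
telephone: 345/389 responders (88.7%)
```

i.e. at the trial's arm sizes the simulated web arm returns far fewer
questionnaires than the telephone arm. `demo/comparison.tsv` then holds
the score comparison (excerpt):

```
scale          mean_internet  n    mean_telephone  n    difference  permutation_p  effect_d
information    59.36          147  65.26           332  -5.90       0.0014         -0.303
communication  70.11          139  76.23           318  -6.12       0.0008         -0.360
global         67.83          91   69.96           152  -2.13       0.042          -0.270
```

Interviewer-facing dimensions score several points lower under web
self-completion (small-to-moderate negative effect sizes with significant
permutation p), while room convenience and catering barely differ —
the pattern the calibration targets encode. `demo/alpha.tsv` holds the
per-scale Cronbach alpha table with bootstrap CIs and per-scale n (the
number of patients whose score is defined).

The same steps are available separately: `isatis simulate` (cohort CSV +
`truth.json` sidecar), `isatis score` (per-patient scores + flow counts),
`isatis analyze` (full analysis of an existing cohort file). Python API:

```python
import isatis

cfg = isatis.default_trial_calibration(seed=11)
cohort = isatis.generate_cohort(cfg)
scores, flow = isatis.score_cohort(cohort.records, isatis.default_isatis_spec())
```

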