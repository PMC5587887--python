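# Methods

## Score construction

Answer codes 1–5 are valued 0, 25, 50, 75, 100; codes 0, 6, 7, 8
(nonrelevancy), 9 (don't know) and 10 (refusal) are missing in every
calculation. A dimension score is the mean of the valued items of that
dimension and is defined only when the number of valued items reaches the
dimension's minimum (3, 3, 3, 3, 2, 2 in reporting order: global care,
information to patient, communication with providers, behavior of
providers, room convenience, catering). The global score is the mean of
all valued answers across the 28 scored items — deliberately *not* the
mean of the six dimension scores, so dimensions with more items weigh
more — and is defined only when every dimension score is defined.
Undefined scores propagate as explicit `None`, never as sentinel numbers.

Two eligibility rules precede scoring. Stays shorter than two nights are
excluded when the length-of-stay filter is on (`los_days` counts nights;
`los_days >= 2`). A returned questionnaire with fewer than 16 completed
items is handled as a nonresponse. "Completed" is ambiguous between
"bears any answer code" and "bears a valued answer": the default counts
any recorded code 0–10 over all 32 items, on the reasoning that a
refusal or nonrelevancy answer is still an act of completion; the
alternative (valued answers over the 28 scored items) is available via
`completed_definition="valued"` and the `--completed-definition` CLI
flag. Items never administered to a patient are simply absent and need
no special casing: the generic missing rules cover structural
missingness.

## Cronbach alpha

Alpha is computed from the item covariance matrix `C` by the generalized
formula `k/(k−1) · (1 − tr C / Σ C)`, algebraically identical on complete
data to the classic item-variance form (the test suite asserts this to
1e−10 on a thousand random matrices, plus an independent cross-check
against `pingouin`). Because partially completed questionnaires still
contribute to any scale whose score is defined, `C` is estimated from
pairwise-complete observations over the rows whose scale score is
defined; this keeps each scale's n equal to its score-defined patient
count. A `listwise=True` option restricts to fully complete rows for
sensitivity. Degenerate inputs (zero total variance, an item pair with
fewer than two joint observations) raise rather than return a number.

Confidence intervals are percentile bootstrap (default 2000 resamples)
over patients, resampled within arm; the percentile method is the
minimal-assumption choice when the interval construction is otherwise
unspecified. A resample on which alpha is undefined is redrawn, with a
capped retry count. The conventional 0.7 "satisfactory" threshold is a
reporting annotation only and gates nothing.

## Between-arm inference

*Participation* uses a Fisher exact test implemented directly by
log-factorial hypergeometric accumulation. The two-sided rule is the
probability-mass method: sum over tables with the observed margins whose
point probability is at most the observed one, with a 1e−7 relative
tolerance for floating-point ties. An exhaustive enumeration oracle over
all tables with margins ≤ 12, and `scipy.stats.fisher_exact` on random
larger tables, pin the implementation down in the tests.

*Delays* use Wilcoxon–Mann–Whitney with midranks (exact enumeration for
small tie-free samples, normal approximation with tie correction
otherwise, via scipy); the fully tied degenerate case returns p = 1.

*Scores and alphas* are compared by Monte-Carlo permutation: patients are
pooled and reassigned to arms preserving group sizes, and the two-sided
p-value uses the add-one estimator `(1 + #{|Δ*| ≥ |Δ|}) / (B + 1)`, which
cannot return zero. For alpha differences entire patient rows (item
vectors) are shuffled, preserving within-patient correlation — the
patient is the exchangeable unit. Default `B` = 10 000 is a desk-scale
compromise (Monte-Carlo SE of a p near 0.05 is ≈ 0.002); it is
configurable upward where tighter p-values are needed. A vectorized path
handles the difference-in-means statistic; arbitrary statistics take a
generic per-shuffle path with capped redraws for undefined shuffles.

*Effect sizes* are Cohen d with pooled (n−1)-denominator SD and
patient-level within-group bootstrap CIs.

No multiple-testing correction is applied across the seven scales; the
comparison mirrors a per-scale reporting convention and annotates
significance at p ≤ .05 only.

## Synthetic cohorts

The generator emulates a 1:1 two-arm randomized survey-mode comparison:

- **Response.** Bernoulli per patient with arm-specific probability
  (defaults 154/392 ≈ 0.393 web, 344/389 ≈ 0.884 telephone).
  Nonresponders carry no answers and no delay.
- **Items.** For responders, each dimension has a patient-level latent
  `U_id ~ N(0,1)`; item latents are
  `X_ij = μ[arm][d] + σ(√ρ U_id + √(1−ρ) e_ij)`, so items within a
  dimension have correlation ρ (`within_dim_corr`, default 0.55 —
  chosen so dimension alphas land in the high-.7s/low-.8s range typical
  of satisfaction scales) and items of different dimensions are
  independent. Four fixed thresholds (−1.5, −0.5, 0.5, 1.5) cut `X` into
  codes 1–5. The four excluded items get codes from an uncorrelated
  latent at the mean of the dimension means.
- **Calibration.** The marginal of `X_ij` is Normal(μ, σ²), so the
  expected valued score is an analytic strictly increasing function of μ;
  `default_trial_calibration` inverts it (Brent root-finding) per arm and
  dimension against the published score-table means (catering lowest
  ≈ 46, behavior of providers highest ≈ 88–92). Covariate frequencies
  come from the published baseline table; age is a clipped normal
  matching its median/IQR.
- **Missingness injection.** Independently per item, the code is replaced
  by a nonrelevancy code (uniform over {0, 6, 7, 8}) with arm-specific
  probability (defaults 0.139 web / 0.208 telephone, set so the expected
  per-responder count of non-valued answers ≈ 4.3 and 6.3 of 28, matching
  the published bucket distribution's means), by 9 or 10 with small
  don't-know/refusal probabilities (0.010/0.005), or dropped entirely
  with a small "not administered" probability (0.005) emulating
  structurally missing items.
- **Delays.** Web: rounded lognormal, median 6 days, σ = 1 (long tail);
  telephone: 7 + Poisson(0.65), concentrated at the scheduled day-7 call.
- **Determinism.** One `numpy.random.Generator` (PCG64) seeded from the
  config; a seed reproduces the cohort file byte for byte. Pipeline
  stages derive their seeds from one root via `SeedSequence` spawning and
  log them.

For effect-size experiments, `effect_size_calibration(d, n_per_arm)`
builds a no-missingness config in which every web-arm latent mean is
shifted by a common δ solved against the *analytic* mean and variance of
the global score (within-dimension covariances come from bivariate-normal
orthant probabilities), so the expected standardized difference equals
`d` without any Monte-Carlo tuning.

### What the generator does not emulate

Dimensions are independent given the arm, so the 28-item global-scale
alpha (≈ 0.67–0.73 in simulation) is lower than the published .84–.89,
which reflects a real general-satisfaction factor correlating dimensions;
a person-level general factor is the natural extension. Nonrelevancy
counts are binomial per patient and hence underdispersed relative to the
published bucket distribution (real nonrelevancy is structural: whole
item blocks do not apply to a patient). Score SDs are somewhat smaller
than the published CIs imply. Interviewer identity effects are collapsed
into the arm-level mean shift. Passing tests therefore demonstrate the
pipeline's correctness and calibration of the *means and rates*, not
item-level realism.

## Problem sizes in the checks

The replicated checks use sizes chosen to give tight Monte-Carlo bands
on a single CPU: 1000 random matrices for alpha-oracle equivalence; 500
null cohorts of 60 + 60 patients at 2000 permutations for the type-I
error (binomial SE ≈ 0.01 around 0.05); 200 cohorts of 116 + 189 for
recovery of d = −0.25 (SE of the mean ≈ 0.008); 100 calibrated cohorts
at 392 + 389 for the marginal calibration check.
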