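# Methods

## Problem setting

`txlearn` estimates the causal effect of drug exposure on a rare binary
outcome — incident COVID-19 within 180 days of a pandemic-wave start —
from routinely collected dispensing and admission records. A patient is
described by static covariates (age, sex, SIMD deprivation decile,
diabetes status) and by a sparse, time-stamped stream of BNF dispensing
codes and ICD-10 admission codes inside a six-month lookback window
preceding each wave. Exposure to a drug class (ACE inhibitors,
beta-blockers, calcium-channel blockers, thiazides, statins) is defined
as at least one dispensing record whose BNF code carries the class
prefix inside the lookback window. The outcome is the composite 180-day
endpoint: earliest of first positive test, first COVID-19
hospitalisation, or COVID-19 death.

All effects are risk differences. The individual treatment effect (ITE)
of drug *d* for a patient with covariates *x* is
τ_d(x) = P(Y=1 | x, T_d=1) − P(Y=1 | x, T_d=0) ∈ [−1, 1]; the average
treatment effect (ATE) is the population mean of τ_d(x).

## Cohort construction

Eligibility: age ≥ 40 at the index date, complete sex/age/SIMD.
All windows are half-open `[start, end)` at day resolution; the wave-1
lookback runs 2019-10-01 → 2020-04-01 with follow-up from 2020-04-01,
wave 2 shifted by six calendar months. Patients whose earliest outcome
predates a wave's follow-up start are excluded from that wave with a
logged reason (the prevalent-case rule; exclusion-with-log is this
package's choice for a step that incidence designs rarely spell out).

Class imbalance is handled at the cohort level: wave-1 negatives are
thinned by stratified Bernoulli undersampling at keep-fraction
`ratio = wave-1 cases / wave-2 cases`, within strata of 10-year age band ×
sex × SIMD decile. Every case is retained; the removed negatives form an
independent second-wave cohort, re-labelled on the wave-2 windows. The
10-year age bands are a design choice (the stratification variables are
given, their granularity is not).

## Sequence encoding

Codes are truncated before tokenisation — BNF to the 7-character
chemical-substance stem, ICD-10 to the 3-character category (both
configurable). The vocabulary (PAD=0, UNK=1, CLS=2, then tokens by
descending training-fold count, ties lexicographic) is built on training
data only; unseen codes map to UNK. Each patient becomes a fixed-length
sequence of (token id, day offset) with a padding mask, sorted by
(date, BNF-before-ICD-10, code); when more than `max_len` events remain
the most recent are kept, because recency is the clinically meaningful
end of a lookback window. Static features are standardised age (training
statistics), sex one-hot, SIMD decile as an integer, and the diabetes
flag.

**Leakage guard.** When encoding inputs for drug *d*'s causal models,
every event whose BNF code starts with one of *d*'s prefixes is removed
first. Otherwise the treatment indicator is trivially readable from the
sequence and the control-arm outcome surface would collapse onto the
factual arm. Note a residual caveat for real data: with 7-character
truncation, a non-statin lipid-regulating product would share the
`0212000` stem with statins; the guard operates on raw codes, so such
tokens would survive. The simulator contains no such colliding products,
and the test suite checks token-level cleanliness exhaustively.

## Risk models

The primary classifier is a transformer encoder: token embedding +
learned positional embedding + learned embedding of the day offset
bucketed into 10-day bins (18 buckets per 180-day window), a pre-norm
multi-head self-attention stack with key padding mask, masked mean
pooling over real tokens, concatenation with the static vector, and a
two-layer head with logistic output. Training minimises binary
cross-entropy with Adam and early stopping on a 10% validation split.
Patients with no events pool to a zero sequence vector so their
prediction depends only on statics, and appended padding never changes a
prediction (tested to 1e-6).

Because no deep-learning framework is part of this package's dependency
set, the transformer and the LSTM baseline run on `txlearn.nn`, a small
reverse-mode automatic-differentiation engine over numpy implementing
exactly the required operations. Every operation, and both networks end
to end, are verified against central finite differences.

Baselines: logistic regression and gradient-boosted trees
(xgboost) on log(1 + bag-of-token counts) + statics, and a single-layer
LSTM on the same encoded sequences. Default transformer size
(embed 64, 4 heads, 2 layers, feed-forward 128, dropout 0.1, ≤30 epochs,
patience 3) is desk-scale; the recovery experiments use a smaller
1-layer/32-dim configuration (`txlearn.validation.DESK_TRANSFORMER`)
because calibrated outcome surfaces matter more there than capacity.

All training is seeded and CPU-deterministic; two runs with the same
seed produce byte-identical outputs.

## X-learner

Per drug, with T the exposure indicator:

1. fit μ0 on controls and μ1 on treated (any risk model);
2. impute individual effects: D1_i = Y_i − μ0(x_i) for treated i,
   D0_j = μ1(x_j) − Y_j for controls j;
3. regress D1 on x over treated (τ1) and D0 on x over controls (τ0),
   fit a propensity model g(x), and combine
   τ̂(x) = g(x)·τ0(x) + (1−g(x))·τ1(x), clipped to [−1, 1].

Design choices where the design was genuinely open:

- τ0/τ1 default to gradient-boosted regression trees on statics +
  log(1+token counts); the propensity defaults to logistic regression on
  the same features, clipped to [0.01, 0.99]. Transformer-based effect
  heads would be possible but the imputed-effect regression is a
  low-signal smoothing problem where trees are the robust default.
- The control group for drug *d* is "not exposed to *d*" regardless of
  other drug use, matching the drug-by-drug exposure definition;
  analyses per drug are independent fits.
- No cross-fitting by default.
- The ATE is the uniform mean of τ̂ over the evaluation population (the
  propensity weighting already lives inside τ̂); the dispersion reported
  with it is the SD of the τ̂ distribution, with median and IQR
  alongside.
- Arms smaller than `min_arm_size` (default 25) or with single-class
  outcomes abort with a diagnostic rather than silently extrapolating.

## Evaluation

- **Cross-validation:** stratified k=5 folds; vocabulary and scalers are
  rebuilt per fold on training patients only; accuracy and F1 at the
  fixed threshold 0.5 (configurable); AUPRC by trapezoidal integration
  of the step precision-recall curve over all distinct thresholds,
  anchored at (recall 0, precision of the strictest threshold). Under
  this convention a constant score yields AUPRC equal to prevalence, the
  no-skill baseline.
- **Paired comparisons:** Wilcoxon signed-rank on paired ITE differences
  (zeros dropped, mid-ranks for ties, exact null distribution for small
  tie-free samples, otherwise normal approximation with tie and
  continuity corrections); effect size r = |Z|/√(non-zero pairs), banded
  left-closed: Small [0.1, 0.3), Moderate [0.3, 0.5), Large [0.5, ∞),
  Negligible below 0.1. Cohen's d uses the pooled SD with the asymptotic
  variance CI. No multiple-testing adjustment is applied; results are
  reported per comparison.
- **Subgroups:** per-level median/IQR and Silverman KDE bandwidth of the
  ITE distribution across age bands, sex, SIMD; the between-group
  dispersion statistic is the maximum pairwise difference of medians.
- **Recovery (simulation only):** bias, RMSE/PEHE
  (√mean((τ̂ − τ*)²)), and Spearman rank correlation against the
  simulator's ground truth.

## Synthetic cohort simulator

The simulator is first-class, tested code; it emulates the study's data
model, not its empirical joint code distribution.

- Covariates: age = 40 + 55·Beta(1.2, 2) (median ≈ 60), sex F with
  probability 0.562, SIMD deciles with deprived deciles
  over-represented (decile 1 at 22.8%), diabetes 8.1%.
- Events: per-patient background code counts are Poisson with mean
  `base_event_rate` (default 2.5 per lookback window), codes drawn from
  a configurable frequency table of common BNF stems and rare ICD-10
  categories, dates uniform over the window (no within-window time
  structure is assumed, so none is imposed).
  Background rates are covariate-independent, which keeps the total
  count exactly Poisson; confounding flows through the *realised*
  comorbidity count instead.
- Exposure: per drug, a logistic propensity in standardised age, sex,
  SIMD, diabetes and log(1+comorbidity count), scaled by
  `confounding_strength`, plus idiosyncratic prescriber noise
  (SD 0.2 logits). Exposure is materialised as 1–5 dispensing events of
  the drug's product codes, so the cohort builder exercises its real
  prefix-matching path. In two-wave mode wave-1 users continue with a
  persistence boost of 2.5 logits.
- Outcome: additive on the probability scale,
  P(Y=1) = clip(base_risk(x) + Σ_d T_d·τ*_d(x), 0, 1), because the
  effects of interest are risk differences (a logit-additive variant is
  available via `risk_scale="logit"`). Configurations whose
  probabilities would leave [0, 1] before clipping beyond a tolerance
  are rejected as mis-specified. Intercepts are calibrated by bisection
  on a fixed internal reference sample (not the realised cohort), so
  enlarging the cohort never perturbs earlier patients — per-patient
  streams are seeded by (master seed, patient index).
- Ground truth records per patient/wave/drug: g*(x), τ*(x) and both
  counterfactual arm probabilities (after clipping, so
  τ* = p_treated − p_control holds identically).

Default effects are small (−0.020 … +0.012) so that no combination of
concurrent exposures can push a 9.5%-prevalence outcome below zero
pre-clipping. Larger effect magnitudes (±0.10 and beyond, the scale
reported for real drug classes) are exercised in dedicated scenarios
with base prevalence 0.30
(`constant_effect_scenario`, `heterogeneous_age_scenario`).

What the simulator does **not** model: vaccination, viral variants,
transmission between patients, realistic joint code distributions,
within-window dispensing rhythms, or code-specific outcome effects
beyond the comorbidity count. Passing recovery tests therefore shows
that the estimator recovers effects under the stated generative
assumptions — confounding through observed covariates and sequence
summaries — not that it would be unbiased under unmeasured confounding
in real data.

## Validation experiments and problem sizes

The end-to-end experiments (`txlearn.validation`) use cohorts of 20,000
patients with the 1-layer/32-dim transformer base learner and
sequence length 32:

- **Null recovery:** τ* ≡ 0 for all five drug classes with confounded
  exposure; all estimated ATEs must stay within 0.03 of zero.
- **Constant-signal recovery:** τ* = −0.10 for one drug at base
  prevalence 0.30; the estimated ATE must land within ±0.03.
- **Heterogeneity recovery:** τ*(age) falling linearly from +0.05 at age
  40 to −0.20 at age 95; Spearman(τ̂, τ*) must exceed 0.5.

Smaller cohorts (800–1,500) back the determinism, leakage and pipeline
checks.

## Numerical notes and limitations

- Probability clipping: propensities to [ε, 1−ε] with ε = 0.01; τ̂ to
  [−1, 1]; simulator outcome probabilities to [0, 1] with a
  mis-specification check before clipping.
- Tie-breaks are explicit everywhere ordering matters: same-day events
  order BNF before ICD-10 then by code; vocabulary ties break
  lexicographically; undersampling draws are per-stratum with
  sorted-stratum seeds.
- The Wilcoxon Z (hence r) always comes from the normal approximation
  even when the p-value is exact, so the effect size is defined
  uniformly across sample sizes.
- The paired Cohen's d uses the two-sample pooled-SD form with the
  asymptotic CI; a paired-difference standardisation would give
  different values on strongly correlated ITE vectors.
- The X-learner inherits the usual observational-data caveats: it
  adjusts only for covariates and code-sequence information it sees, and
  residual confounding by unmeasured variables is out of reach by
  construction.
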