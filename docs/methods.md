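# Methods

## The classification model

CURB65-A is a deterministic composite of two orderings: the CURB65 class
(scores 0–1 / 2 / 3–5) and the ProADM category (≤ 0.75, (0.75, 1.5],
> 1.5 nmol/L). The 3 × 3 grid partitions into risk class I (one cell:
low/low), class II (three cells: low CURB65 with mid ProADM, or CURB65 2
with ProADM ≤ 1.5), and class III (the remaining five cells). The mapping
is monotone in both axes: worsening either input never lowers the risk
class. Each class carries one site-of-care recommendation (outpatient /
short hospitalization / inpatient).

Two conventions are fixed here and configurable via `ScoreThresholds`:

- CURB65 component cut-offs follow the original score definition
  (confusion; urea > 7 mmol/L; respiratory rate ≥ 30/min; SBP < 90 mmHg or
  DBP ≤ 60 mmHg; age ≥ 65 y).
- ProADM boundaries are closed on the upper side ([0, 0.75], (0.75, 1.5],
  (1.5, ∞)). Published descriptions alternate between "<0.75" and "≤0.75";
  we adopt the inclusive reading of the composite rule and note that the
  choice only moves patients whose assay value lands exactly on a boundary.

Missing urea is a hard error at the scoring layer: whether to drop or
impute incomplete rows is a cohort-level policy (the default pipeline
rejects them), and the original study's multiple-imputation model is out
of scope here.

## Statistical primitives

- **Proportion intervals** are Wald: p̂ ± z·√(p̂(1−p̂)/n), reported in
  percent and *not* truncated at 0, so rare-event strata can show negative
  lower bounds — the convention that identifies the method in the
  reference tables.
- **AUC** is the ties-corrected Mann–Whitney probability, computed via
  midranks; ordinal predictors are expanded to their level values, so the
  ordinal and continuous paths agree exactly on discretized data. Standard
  errors use DeLong's structural components; correlated AUCs (two markers
  on the same subjects) are compared with the paired DeLong z-test.
  Rank-identical markers yield a zero variance of the difference and p = 1.
- **Logistic regression** is maximum likelihood via IRLS (statsmodels GLM,
  binomial family) with tolerance 1e-10 and ≤ 100 iterations. Constant
  outcomes and rank-deficient designs are rejected up front; separation is
  flagged when statsmodels reports perfect prediction or any coefficient
  exceeds 1e4 in magnitude.
- **Hosmer–Lemeshow** groups subjects into deciles of predicted
  probability (stable sort, near-equal bins), and uses
  χ² = Σ (O−E)²/(E(1−E/n_g)) on g−2 degrees of freedom. The g−2 reference
  assumes the probabilities come from a fitted model; the test-suite null
  replicates therefore fit a 2-parameter logistic model before testing,
  which is the regime in which the nominal 5% type-I error holds. Bins
  with zero expected events are merged into a neighbour with a warning.
- **Trend tests** are Cochran–Armitage with equally spaced scores, which
  is algebraically the 1-df score test of a logistic regression on the
  level scores (the suite asserts z² agreement to 1e-6). All-zero (or
  all-one) event vectors return p = 1 with an explanatory note.
- **Smoothed risk curves** replace a penalized GAM with a fixed-df
  natural-cubic-spline logistic fit (df = 4 by default; the original
  smoothing parameters are unreported, so an exact reproduction is not
  attempted). The spline basis spans the constant, so it is fit without a
  separate intercept; pointwise 95% bands come from the delta method on
  the linear predictor, evaluated on a 100-point grid over the 1st–99th
  percentile of the marker.
- **Count recovery** from printed percentages rounds n × p to the nearest
  integer, half away from zero; this reproduces the published totals (67
  deaths, 170 adverse events) from every stratification.

## The synthetic cohort generator

The generator emulates the derivation cohort's structure, not its
patients. Defaults (all in `CohortConfig`):

- n = 1359; CURB65 class probabilities 0.485 / 0.319 / 0.196.
- Conditional ProADM-category matrix given CURB65 class. The published
  margins pin seven of the nine cells (row sums 659/434/266, column sums
  353/588/418, 306 patients in the low/low cell, 11 in the
  high-CURB65/low-ProADM cell); the one remaining free cell — low CURB65
  with mid ProADM — is set to 250/659, which makes the three conditional
  distributions stochastically ordered, i.e. ProADM shifts upward with
  CURB65 severity.
- ProADM values are truncated log-normals per category: (μ, σ) on the log
  scale of (log 0.55, 0.40), (log 1.05, 0.35), (log 2.0, 0.55), truncated
  to [0.08, 0.75], (0.75, 1.5], (1.5, ∞) with 0.08 nmol/L as the assay
  detection floor. These place the overall median near 1.1 nmol/L with a
  right skew.
- 30-day event probabilities per CURB65-A class: adverse
  0.0392 / 0.0861 / 0.2158, mortality 0.0065 / 0.0262 / 0.0983. Outcomes
  are driven by the risk class, not by the covariates directly — the
  minimal structure that keeps every pipeline stage (trend tests,
  calibration, model comparison) non-degenerate.
- A within-class log-ProADM effect (default slope 1.0 log-odds per log
  nmol/L) modulates the per-patient adverse probability as
  expit(a_k + slope·log x); the intercept a_k is solved per class (Brent's
  method) so the realized class-average probability equals the configured
  value exactly, whatever the biomarker draw.
- Mortality is a sub-event of the composite with constant conditional
  probability (ratio of the configured rates), so the composite invariant
  holds by construction and deaths inherit the biomarker gradient. The
  non-fatal remainder is split into ICU admission and disease-specific
  complication, with complications confined to CAP patients.
- Covariates (age, confusion, urea, respiratory rate, blood pressures) are
  drawn from marginal distributions matched to the published baseline
  table (age ~ N(70, 16) truncated to ≥ 18; confusion 6.8%; RR
  log-normal around 20; SBP ~ N(134, 22); DBP ~ N(75, 12); urea
  log-normal around 6 mmol/L) and *rejection-sampled* so every patient's
  computed CURB65 class equals the sampled target class. Rejection (in
  vectorized waves) keeps the covariates jointly plausible at the cost of
  ~3 draws per patient, which is negligible at the scales used.
- Outpatient status is Bernoulli per risk class (rates 88/306, 38/534,
  16/519, matching the published site-of-care margins); diagnosis is
  multinomial (68.1% CAP, 16.8% COPD, 11.1% bronchitis, 4.0% other).

All randomness flows through one `numpy` generator seeded from the config;
identical configs give byte-identical CSV output.

**What the generator does not emulate:** correlations between covariates
beyond those induced by the CURB65 class; outcome dependence on covariates
within a risk class (beyond ProADM); biomarker kinetics over days 3–7;
length of stay; missing data. Tests passing on synthetic cohorts therefore
validate the pipeline's arithmetic and its statistical operating
characteristics under the configured structure — they do not re-establish
the clinical findings on real patients, and cohort-level quantities that
depend on unmodelled structure (e.g. the joint-model AUC magnitude)
deliberately differ from the published ones.

## Problem sizes and numerical choices

The suite runs its stochastic checks at sizes chosen to make the assertions
sharp at desk scale: exhaustive-pair AUC oracles at 200 × 200, slope
recovery at n = 20 000 (±0.1 on a true 1.2), Hosmer–Lemeshow type-I error
over 200 fitted-model replicates of n = 1000 (accepting 2–10%), generator
parameter recovery over 50 replicates of n = 50 000 (≥ 90% Wald coverage
of the configured class rates, counted per replicate × class), and the
joint-vs-CURB65 AUC ordering over 50 cohorts of n = 1359. Deterministic
reference checks (AUCs 0.73/0.65, the Wald intervals, count consistency,
triage fractions, the mixture identity) are exact reconstructions from the
published stratified table.

Ties in decile construction are broken by stable sort order; report
rounding follows the reference tables (rates and AUCs to 2 decimals,
percentages to 1). Subgroup analyses are a filter (`all` / `cap` /
`non_cap`, the latter meaning COPD exacerbation + bronchitis, excluding
"other" diagnoses), not duplicated code paths. Combined-model AUCs are
apparent (in-sample), matching the derivation design; no cross-validation
is performed.

## Known limitations

- The smoothed risk curve is a fixed-df spline, not a penalized GAM;
  curve shapes at sparse marker tails are variance-dominated.
- Wald intervals misbehave at very small event counts (negative bounds are
  reported by design); no exact or score intervals are offered.
- The triage cross-tab quantifies *potential* reallocation under the
  score's recommendations; it is not a clinical decision tool.
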