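# Methods

This note documents the statistical content of `pcatriage`: the models,
their assumptions, the tunable parameters, what the synthetic
generators do and do not emulate, and the numerical and design choices
made where more than one reading was defensible.

## Risk model

The outcome is binary: clinically significant prostate cancer (csPCa,
ISUP grade ≥ 2) versus no cancer or indolent grade-1 cancer. Pooling
indolent cancer with the negatives is deliberate — the tool's question
is whether a biopsy would find *treatable, significant* disease, and a
grade-1 finding is a harm (overdiagnosis), not a benefit.

PSA, %freePSA (free/total ratio) and the rough DRE volume estimate are
right-skewed and act multiplicatively, so they enter as log2 values
centered at the training-cohort mean of the log2 value. Base 2 makes a
coefficient the log-odds change per *doubling*, the natural clinical
unit for PSA. The centering constants are stored on the fitted model,
so prediction for a new patient needs no access to the cohort; the
intercept is the log-odds for a man at cohort-average PSA and %freePSA
and zero on the remaining predictors. Age enters in raw years;
DRE and family history are 0/1.

Fitting is maximum likelihood (Newton), with an explicit marginal
separation check so that a perfectly separating predictor is reported
by name rather than surfacing as an optimizer failure. The
`free_psa_pct` field is a ratio in (0, 1] everywhere in files and code;
the CLI accepts a percent and converts at the boundary, because percent
is how the quantity is spoken.

## Model-selection metrics

- **Concordance index** via midranks (Mann–Whitney form): exactly the
  all-pairs count with half-credit for tied predictions, at
  O(n log n). Tests verify exact agreement with an O(n²) brute-force
  oracle and with an independent ROC-AUC implementation.
- **Bootstrap optimism**: refit on each with-replacement resample;
  optimism is mean(c on the resample − c of that refit on the original
  data); corrected c = apparent − optimism. Default 1000 replicates.
  Resamples with a single outcome class, separation, or
  non-convergence are skipped and counted; more than 10 % skipped is
  an error rather than a silently biased estimate.
- **IPA** = (1 − Brier(model)/Brier(null)) × 100 with the null model
  predicting prevalence: 0 % means no better than prevalence, 100 %
  means perfect, negative means actively miscalibrated.
- **Net benefit** at threshold t: TP/n − (t/(1−t))·FP/n, advising
  biopsy when predicted risk ≥ t. The decision curve covers t ∈
  [3 %, 10 %] in 0.5 % steps — a step fine enough for a smooth curve at
  negligible cost — against the default strategy "biopsy iff
  PSA ≥ 3.0 ng/mL", treat-all and treat-none. Biopsies avoided per
  1000 men relative to the default strategy are reported per point;
  the headline reduction is read at the 5 % threshold.

## Life expectancy

All survival curves are two-parameter Weibulls,
S(t) = exp(−(t/λ)^k), LE = λ·Γ(1+1/k). The Weibull is the standard
parametric choice for all-cause mortality over a 10–25-year horizon:
monotone hazard, closed-form mean, and closed under proportional
hazards (hazard × r ⇒ same k, λ × r^(−1/k)), which the treatment and
healthy-screenee adjustments both exploit.

**Fitting published curve points** uses least squares on
log(−log S) vs log t (slope = k). This inverts exact Weibull
tabulations to machine precision and is the conventional way to
approximate a curve known only through read-off points. Points with
S ∈ {0, 1} are rejected rather than clipped.

**Fitting individual censored data** uses a Weibull accelerated-failure
model: log λ linear in age (centered at 65) and Charlson indicators,
common shape, censored maximum likelihood (via lifelines). Follow-up
arrives in months and is converted to years internally.

**Gleason mixture.** Registry curves are stratified into Gleason 5–7
and 8–10 bands; a screening population's ISUP ≥ 2 disease has a
different band composition, so the adjusted curve is the
target-weighted mixture of band curves, tabulated on a yearly grid and
refit to a single Weibull. The refit is an approximation (a Weibull
mixture is not Weibull); over the 1–20-year grid the discrepancy is
small relative to the read-off error in published points.

**PSA-era adjustment.** Overall survival is decomposed under
independent competing hazards into other-cause × cancer-specific
components, S = S_other · S_pca; the cancer-specific factor is powered
by the relative effect 0.79 (the adjustment is applied to the
cause-specific *hazard*, not to cumulative incidence) and the product
reassembled. The other-cause curve must dominate the overall curve
pointwise; otherwise the decomposition is rejected as inconsistent
data. The independence-of-competing-hazards assumption is documented,
not tested — it is unidentifiable from marginal curves.

**Healthy-screenee correction.** Expected deaths per man are
accumulated from a life table along his follow-up, age advancing
annually with the final fractional year pro-rated, and enter a Poisson
regression of observed deaths as a log offset, with centered age and
Charlson indicators as covariates. The reported ratio is
reference-population vs cohort mortality at reference covariates
(exp(−intercept)), so a screening cohort healthier than the life table
yields a ratio above 1, and multiplying the fitted hazard by that
ratio (ratio 1.6 ⇒ λ × 1.6^(−1/k)) generalizes the cohort's life
expectancy to the general population.

**Imputation.** Missing Charlson strata (about 1 % in the emulated
cohort) are filled by predictive-mean matching: the numeric code is
regressed on age and vital status among complete records, and each
missing value takes the observed stratum of a donor drawn uniformly
from the 5 nearest predicted means. This is *single* imputation with a
fixed seed rather than full multiple imputation with pooling: the
imputed variable is one covariate in a 19,000-man survival fit, where
between-imputation variance is negligible next to sampling error; the
simplification is deliberate and documented here.

**Restricted mean.** `WeibullSurvival.restricted_mean(horizon=25)` is
provided alongside the unrestricted mean because extrapolating a
fitted Weibull far beyond the observed follow-up is unreliable for
very old or very comorbid men; the default pipeline uses the
unrestricted mean.

## Treatment benefit

gain = LE_untreated · (hr^(−1/k) − 1), the difference of Weibull means
under proportional hazards. The reference shape is fixed at **k = 1.4**
for the shipped untreated-csPCa strata: inverting the gain law at each
published (LE, gain) anchor pair — (12.3, 1.6), (10.9, 1.5),
(9.7, 1.3) years — gives k = 1.43, 1.35, 1.39 respectively, so 1.4 is
the single value jointly consistent with all three (a property the
test suite checks). At k = 1.4 exactly, the closed form reproduces the
1.6- and 1.3-year anchors and the 20-month worked example to the
printed precision; the middle stratum evaluates to 1.45 y, which
matches its printed 1.5 y at that stratum's own implied shape.

The overall trial hazard ratio is applied uniformly across age and
comorbidity (the trials are too small for subgroup effects), and the
sensitivity analysis simply swaps in the SPCG-4 and ProtecT ratios.
Gains are displayed in whole months, rounded half away from zero.

## Referral decision

Bands: risk 5–10 %, life expectancy 10–15 y, gain 1–2 y. The LE
criterion uses the life expectancy *without* csPCa — the man's
competing-risk horizon; the untreated-csPCa LE is displayed but not
thresholded, since thresholding both would double-count the same
mortality. The rule set, in order:

1. risk below 5 % → no referral;
2. gain above 2 y (risk ≥ 5 %) → refer, flagged as an override when
   LE is below 10 y;
3. gain and LE both below their bands → no referral, whatever the
   risk — nothing can be gained;
4. risk, LE and gain all at/above their lower limits with at least one
   at or past its band midpoint → refer;
5. otherwise → shared decision.

Rule 4 is the *consensus-band* reading: a literal
"any-criterion-above ⇒ refer" rule cannot hold simultaneously with
rule 3 (a high-risk man with no horizon and no benefit must not be
referred), and a literal "all-within ⇒ patient preference" rule would
not refer the canonical favorable case (risk 9 %, LE comfortable, gain
20 months). The midpoint condition resolves both, and the whole rule
set is monotone — raising risk or gain never moves the advice away
from referral — which the suite property-tests on a 10⁴-point grid.

## Synthetic data

The generators reproduce *published marginals*, not joint mechanisms:

- **Biopsy cohort** (default n = 3616, seed 1): outcomes drawn at
  75/16/9 % (no cancer / indolent / csPCa); per-outcome log-normal PSA
  with medians 4.0/5.1/7.8 ng/mL and σ from the printed IQR ratios
  (σ = ln(q₇₅/q₂₅)/1.349); %freePSA medians 0.22/0.17/0.12 likewise;
  truncated-normal age with medians 66/67/68; abnormal-DRE rates
  31/41/66 %. Covariate–outcome dependence is induced purely by
  outcome-conditional sampling; there is no structural dose-response
  model, so fitted coefficients are emergent, and the published ERSPC
  coefficients (never printed) are *emulated*, not matched. The
  shipped reference model's 5 % risk for the 65-year-old worked
  example versus the published 9 % reflects exactly this gap.
- **Survival cohort** (default n = 19,000): Weibull event times with
  shape 1.55, scale 31 y at age 65/Charlson 0, log-scale age slope
  −0.045/y, Charlson contractions −0.22/−0.45, administrative
  censoring at 204 months. These defaults were set once by inverting
  the Weibull CDF at the two published anchors — 81 % ten-year overall
  survival and 38 % deaths at a median 15-year follow-up — and give
  80.0 % and 38.2 % at the default seed.
- **Life table**: Gompertz h(age) = 4.3·10⁻⁵·e^(0.09·age)
  (≈ 1.5 %/year at 65, a realistic level for older European men),
  standing in for national life tables whose values are not
  redistributable. A companion generator simulates cohorts at
  life-table/r hazard to exercise the relative-mortality estimator.
- **Registry curve points**: exact Weibull tabulations (shape 1.4,
  t = 1…20 y) whose means equal per-stratum targets anchored at the
  published 12.3/10.9/9.7 years for Charlson 0 at ages 65/70/75, with
  multiplicative contractions 0.85/0.65 for Charlson 1/2+ and 0.60 for
  the Gleason 8–10 band. The Charlson and high-grade multipliers are
  plausibility choices, not published values.

What passing tests on these cohorts shows: the estimators recover
known generating parameters, the metrics match independent oracles,
and the pipeline reproduces the published closed-form quantities. What
it does not show: performance on real screening data, where covariate
correlations (PSA–volume, age–comorbidity) and non-log-normal tails
exist that the generators do not emulate.

## Numerical choices and degenerate inputs

- Predicted probabilities are clipped to (10⁻¹², 1 − 10⁻¹²); curve
  tabulations are clipped identically before the log(−log) transform.
- Weibull refits of adjusted curves use the yearly grid t = 1…20, the
  span over which published curves are actually read.
- Perfect separation, single-class cohorts, zero deaths, zero expected
  deaths, and all-missing Charlson raise typed errors naming the
  culprit rather than degrading to NaN.
- Bootstrap and imputation take explicit integer seeds and are
  bit-reproducible; the concordance of a refit is computed on the
  linear predictor (rank-equivalent to the probability, cheaper).
- CLI exit codes: 0 ok, 2 input/schema, 3 numeric failure.

## Known limitations

- The published risk-model coefficients and Weibull parameters are not
  printed in the source material; the shipped reference models are
  synthetic-cohort fits, so per-patient risks differ from the
  published worked examples even though the life-expectancy and
  treatment-benefit arms reproduce them.
- The untreated-csPCa LE table anchors Charlson 0; the comorbid
  strata inherit assumed multipliers.
- No mpMRI pathway, no quality-of-life or metastasis outcomes, no
  subgroup-specific treatment effects — all outside the tool's scope.
- The era adjustment assumes independent competing hazards, and the
  Gleason-mixture refit approximates a non-Weibull mixture by a
  Weibull.
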