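# pcatriage

Shared-decision-making support for the first question a general
practitioner faces when a man presents with an elevated PSA: **should he
be referred for a prostate biopsy at all?** Referral is only worthwhile
if three things line up — a real chance that a biopsy today would find
clinically significant prostate cancer (csPCa, ISUP grade ≥ 2 / Gleason
≥ 3+4), enough remaining life expectancy for that cancer to matter, and
a meaningful survival gain from treating it. `pcatriage` computes all
three for one patient and turns them into a concrete recommendation,
and ships the model-selection machinery (optimism-corrected
concordance, Index of Prediction Accuracy, decision-curve analysis)
used to choose the risk model.

It is aimed at biostatisticians and clinical-decision-modelling
researchers. Because no individual-level records from the underlying
screening cohorts, registries and trials are distributable, the package
includes seeded synthetic-data generators that reproduce their
published marginals, so every fitting and validation stage runs
end-to-end out of the box.

## The models

**Risk of csPCa on biopsy.** A logistic regression on GP-accessible
predictors; PSA, the free-to-total-PSA ratio, and the rough
DRE-estimated prostate volume (25/40/60 cc) enter as centered log2
values:

```
logit P(csPCa) = β₀ + β₁·(log₂PSA − c₁) + β₂·age + β₃·(log₂%fPSA − c₂) + …
```

The "basic model" uses PSA + age + %freePSA; DRE and volume can be
added. Indolent (grade-1) cancer counts as a negative outcome — the
tool predicts *significant* cancer only.

**Life expectancy.** Every survival curve is a two-parameter Weibull,
`S(t) = exp(−(t/λ)^k)`, with life expectancy `LE = λ·Γ(1 + 1/k)`.
The *without-csPCa* curve comes from a censored Weibull
accelerated-failure regression (log λ linear in age and Charlson
comorbidity stratum, common shape) on screening-cohort follow-up,
multiplied by a healthy-screenee relative-mortality ratio estimated by
Poisson regression with a life-table expected-death offset. The
*untreated-csPCa* curves come from per-stratum registry survival points
fitted by complementary log-log least squares, re-weighted across
Gleason bands to the ISUP ≥ 2 composition of a screening population,
with a 0.79 relative effect on the cancer-specific hazard for the PSA
era.

**Treatment benefit.** A trial hazard ratio acts on a Weibull by
proportional hazards — same shape, scale × hr^(−1/k) — so the absolute
gain has the closed form

```
gain = LE_untreated · (hr^(−1/k) − 1)
```

with hr = 0.84 (PIVOT) by default and 0.74 (SPCG-4) / 0.93 (ProtecT)
for sensitivity analysis.

**Referral advice.** Risk, life expectancy and gain are held against
consensus bands (5–10 %, 10–15 y, 1–2 y). Risk below 5 % → no
referral. Gain above 2 y → refer even when life expectancy is short
(the override rule). Gain and LE both below their bands → no referral
regardless of risk. All three clearing their lower limits with at
least one at its band midpoint → refer; otherwise the grey zone is a
shared decision.

## Worked example

```
$ triage predict --age 65 --psa 4.0 --free-psa-pct 12 --charlson 0
Age 65, PSA 4 ng/mL, free PSA 12%, Charlson 0
Risk of csPCa on a current biopsy: 11%
Life expectancy without csPCa: 20.5 years
Life expectancy with untreated csPCa: 12.3 years
Life expectancy with treated csPCa: 13.9 years
Expected gain from treatment: 20 months
Advice: Refer to a urologist
```

The risk is the logistic model's probability that a biopsy today finds
ISUP ≥ 2 cancer (from the shipped reference model, fitted on the
synthetic cohort — a low free-PSA ratio is the strongest signal). The
12.3-year untreated life expectancy is the Weibull mean for the
65-year-old, Charlson-0 stratum; applying the PIVOT hazard ratio of
0.84 stretches that curve to 13.9 years — a gain of 20 months. The
same blood values in a 75-year-old with Charlson 2+ produce "No
referral needed": his risk is *higher* (14 %), but with an 8.4-year
competing-risk horizon and only 10 months of expected gain, a biopsy
cannot help him.

The same pipeline is available from Python:

```python
from pcatriage import PatientProfile, triage_patient
report = triage_patient(PatientProfile(age=65, psa=4.0, free_psa_pct=0.12))
print(report["text"])
```

`examples/` contains one short script per capability: per-patient
triage, risk-model fitting and validation, the life-expectancy
machinery, and the treatment-benefit calculus.

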