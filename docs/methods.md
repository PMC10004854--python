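# Methods

## The AE model and its fitting procedure

AE models indexed measured GFR (iothalamate clearance) on its natural
scale: E[mGFR] = exp(xᵀβ) with design columns (intercept, √SCr, age,
ln urea, albumin, male, single kidney), and Var[mGFR] = φ·E[mGFR]. Only
these two moments are specified — a quasi-likelihood model, not a full
distribution. Fitting is by IRLS: with a log link and V(μ) = μ the
working weights are w_i = μ_i and the working response is
z_i = η_i + (y_i − μ_i)/μ_i; each iteration solves a weighted least
squares problem. These estimating equations coincide with the Poisson
score equations, so an independent Poisson-likelihood maximizer
(statsmodels GLM) serves as the cross-check oracle in the tests; the
implementation itself is self-contained.

Numerical choices:

- initialization μ⁽⁰⁾ = max(y, 10⁻⁶) — robust for strictly positive
  responses;
- convergence when the maximum absolute coefficient change < 10⁻⁸
  (default), capped at 100 iterations; non-convergence is reported, not
  raised;
- WLS solved by `lstsq` on the √w-scaled system; rank deficiency raises;
- dispersion φ̂ = Pearson χ²/(n−p), the quasi-likelihood convention;
  standard errors √(φ̂·diag((XᵀWX)⁻¹));
- the quasi-deviance trace uses the Poisson-form deviance
  2Σ[y ln(y/μ) − (y−μ)], which is valid for continuous y > 0 under
  V(μ) = μ and is non-increasing across iterations (checked in tests).

### Creatinine transform

The equation as typeset applies the coefficient −1.7656 to SCr directly,
but the model's stated predictor list uses √SCr. The linear form
collapses to absurd values at high creatinine (SCr = 5 gives eGFR below
0.1 mL/min/1.73 m²), while the square-root form stays physiologic across
the full CKD range, so √SCr is the default; `ae_scr_transform="linear"`
reproduces the typeset form, and the choice is echoed into estimate
metadata.

### Albumin units

Albumin is treated as g/dL throughout (median 4.2): the coefficient
0.060 only produces physiologic output on that scale, even though
clinical sources sometimes label the same numbers g/L. The CSV reader
rescales values > 20 by ÷10 with a warning, so g/L-encoded files load
correctly.

### Other equation-level choices

- MDRD6: IDMS-traceable constant 161.5 with BUN = urea/2.14 (molecular-
  weight ratio); both configurable.
- CKD-MCQ: the published combination rule is not restated by the
  validation study; the arithmetic mean of CKD-EPI 2009 and MCQ is the
  default, with a geometric-mean option.
- MCQ clamps creatinine below 0.8 mg/dL to 0.8 (its published rule), so
  the output is constant on (0, 0.8].
- BSA: Du Bois–Du Bois by default (the near-universal 1.73 m² indexing
  convention); Mosteller available.
- Race coefficients default to off (the development cohort is entirely
  Latin American); exposed for completeness on MDRD and CKD-EPI 2009.
- Obesity grades use half-open bins [30,35), [35,40), [40,∞) so the
  conventional "30–34.9" labels are honored without gaps.
- James LBM goes non-positive in the extreme short/super-obese corner
  (e.g. BMI ≳ 72 at 140 cm for women); this raises a domain error rather
  than returning a negative mass.

## Metrics

- Bias quartiles use linear interpolation between order statistics (the
  common statistical-software default); the convention is fixed so
  Q1/Q3 are reproducible.
- P30 is boundary-inclusive (|e − m| ≤ 0.30·m).
- Pearson CI: Fisher z with normal quantiles.
- CKD stages partition (0, ∞) with inclusive lower edges at 90/60/30/15.
- Raw-scale equations (LBM_CG, SC) are scored against mGFR de-indexed by
  BSA. For %CC their estimates are re-indexed (×1.73/BSA) before
  staging, so staging always happens on the scale the stage bounds are
  defined on; `stage_raw_on_raw=True` stages raw against raw instead.

## Cross-validation

Plain random k-fold (default k = 10) via a seeded shuffle; fold sizes
differ by at most one (n = 189 gives nine folds of 19 and one of 18).
No stratification is applied. Every subject is predicted exactly once by
a model fitted without it, and all metrics are computed on the pooled
out-of-fold predictions. The seed is a required parameter and results
are byte-reproducible under it.

## Synthetic cohort generator

The generator emulates the marginal structure of the development
population: grade mix 60/25.1/14.9%, 52.1% female, single kidney 9.3%,
diabetes 18.1%, hypertension 47.1%, age median 50 (IQR 40.2–59.8,
truncated 18–85), creatinine 0.85 (0.71–1.1) mg/dL, urea 31.1
(25.2–41.7) mg/dL, albumin 4.2 (3.94–4.44) g/dL, BMI capped at 72.3
kg/m².

Distribution families are a modelling choice — only medians and IQRs
are published — picked so two parameters match both statistics:
log-normal for the right-skewed quantities (age, creatinine, urea),
normal for albumin and height (♂ 172±7, ♀ 160±6 cm), uniform within the
grade-I/II BMI bands and a truncated exponential tail (scale 5 kg/m²,
inverse-CDF truncation at 72.3, no point mass at the cap) above 40.
Weight is derived from BMI and height. Creatinine and urea share a
log-normal factor (log-correlation 0.5) since both track renal
function; no other dependence is modelled — the true joint distribution
of the study covariates is unknown, so passing marginal checks says
nothing about joint structure in real data.

Two modes:

- **forward** (default): mGFR ~ Gamma(shape = μ/φ, scale = φ) with μ the
  AE mean function at the subject's covariates and φ = 5 by default, so
  E = μ and Var = φμ — exactly the second-moment structure the
  quasi-likelihood model assumes. The gamma family is a convenience (a
  continuous positive response with the right two moments), not a
  distributional claim. Draws are truncated below at 1 mL/min/1.73 m²
  to keep the response strictly positive; at typical μ this truncation
  is never active. Refitting on forward cohorts recovers the generating
  coefficients, closing the simulation–inference loop.
- **marginal_matched**: mGFR is drawn from the study's CKD-stage mix
  (51.6/27.4/14.4/4.2/2.3%, renormalized from the printed rounded
  percentages), uniform within each stage band between 5.6 and 173.1,
  and creatinine is back-solved from the AE mean with log-scale noise
  (sd 0.15, chosen once to give realistic eGFR–mGFR scatter), clamped
  to 0.2–15 mg/dL. Use this mode when the mGFR marginal, not the
  regression structure, is the calibration target.

Each variable family draws from its own RNG stream spawned from the
master seed, so changing the dispersion never reshuffles covariate
draws, and cohorts are bit-reproducible under a seed.

Forward-mode cohorts encode AE's own mean structure, so comparative
performance tables on synthetic data favor AE by construction; they
exercise the machinery, not the clinical claim.

## Validation study sizes

The coefficient-recovery study (tests and `scripts/acceptance.py`) uses
25 replicates of n = 20,000 — large enough that the Monte-Carlo standard
error of each mean coefficient is well below 1% of its magnitude, and
the whole study runs in seconds. The cross-validation contract is
checked at n = 189, the size of the model's internal validation sample;
cohort-calibration checks use n = 10,000 with 3-binomial-SE tolerances.

## Known limitations

- The original patient cohorts are not deposited, so the published
  validation-table numbers (P30 85.2%, r 0.86, %CC 74.4% for AE, etc.)
  cannot be reproduced here; what is reproduced is the equations'
  arithmetic, the metric definitions, the fitting machinery, and
  coefficient recovery under the model's own assumptions.
- Coefficient standard errors and the development-fit dispersion were
  never published, so the SE/φ estimates have no external reference.
- Cystatin C equations, pediatric equations and drug-dosing guidance are
  out of scope.
- The generator matches marginals only; real covariate dependence
  (e.g. age–creatinine, comorbidity clustering) is not emulated, and the
  recruitment-period creatinine shift between the study's two validation
  samples is ignored.
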