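# aegfr

GFR estimation equations for obese adults, built around the **Argentinian
Equation (AE)** — a creatinine-based estimator developed specifically for
patients with BMI ≥ 30 kg/m², where the standard equations (CKD-EPI, MDRD,
Cockcroft–Gault variants) are known to degrade.

Estimating glomerular filtration rate from serum markers is routine in
nephrology, but obesity distorts the creatinine–GFR relationship: muscle
mass, body surface area and tubular secretion all shift. This package
implements AE and its seven comparators, the validation metrics used to
compare them, the model-fitting machinery AE was built with, and a
synthetic obese-cohort generator so the whole pipeline is testable without
patient data. It is aimed at biostatisticians and nephrology researchers
validating eGFR equations or developing their own.

## The model

AE predicts indexed measured GFR (iothalamate clearance, mL/min/1.73 m²)
on its natural scale through a log link:

```
eGFR = exp( 6.3106 − 1.7656·√SCr − 0.0055·age − 0.0656·ln(urea)
            + 0.060·albumin + 0.224·[male] − 0.2052·[single kidney] )
```

with SCr and urea in mg/dL, albumin in g/dL, age in years. The model is a
**quasi-likelihood GLM**: only the mean (log-linear) and the variance
function V(μ) = μ are specified — no response distribution is assumed —
and it is fitted by iteratively reweighted least squares (IRLS). Internal
validation uses 10-fold cross-validation.

Comparators: CKD-EPI 2009 and 2021, MDRD4 and MDRD6 (IDMS-traceable),
the Mayo Clinic Quadratic equation (MCQ), the CKD-EPI 2009/MCQ
combination (CKD-MCQ), lean-body-mass Cockcroft–Gault (LBM_CG) and
Salazar–Corcoran (SC). The last two predict raw creatinine clearance
(mL/min), so they are evaluated against mGFR de-indexed by the subject's
Du Bois body surface area.

Performance metrics: **bias** (eGFR − mGFR; median with Q1/Q3, positive =
overestimation), **P30** (% of estimates within ±30% of mGFR, boundary
inclusive), **Pearson r** with a Fisher-z 95% CI, and **%CC** (% of
subjects placed in the correct CKD stage: ≥90, 60–89.9, 30–59.9, 15–29.9,
<15 mL/min/1.73 m²).

## Worked example

```python
from aegfr import PatientRecord, estimate_all

patient = PatientRecord(
    id="example-median", sex="female", age=50.0, weight=91.0, height=165.0,
    diabetes=False, hypertension=False, single_kidney=False,
    scr=0.85, urea=31.1, albumin=4.2,
)
for eid, value in estimate_all(patient).values.items():
    print(eid, round(value, 1))
```

prints (this subject sits at the development population's median
covariates; `examples/estimate_patient.py` is the runnable version):

```
LBM_CG 65.4
SC 99.1
MDRD4 70.8
MDRD6 72.8
CKDMCQ 90.3
CKDEPI2009 79.9
CKDEPI2021 83.4
AE 84.3
```

AE gives 84.3 mL/min/1.73 m² — preserved kidney function. The raw
clearances (LBM_CG, SC, in mL/min) are not directly comparable to the
indexed values; the spread across the indexed equations (70.8–90.3) is
exactly why equation choice matters in obesity.

Other entry points:

- `examples/evaluate_cohort.py` — full validation table (bias, P30, r,
  %CC), overall and by obesity grade.
- `examples/crossvalidate_ae.py` — 10-fold CV refit at n=189.
- `examples/simulate_cohort.py` — synthetic cohort marginals vs. targets.
- CLI: `aegfr estimate|validate|crossval|simulate` (see `aegfr --help`)
  for shell use on cohort CSVs.

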