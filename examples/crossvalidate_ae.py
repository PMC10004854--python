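"""Refit the AE quasi-likelihood model with 10-fold cross-validation.

Uses a cohort of n=189 (the size of the model's internal validation
sample).  Each fold's model is fitted by iteratively reweighted least
squares on the complement (log link, variance proportional to the mean)
and predicts the held-out subjects, so every subject is scored by a
model that never saw it.
"""

from aegfr import CohortSpec, cross_validate, generate_cohort
from aegfr.io import format_coefficient_table, format_performance_table

cohort = generate_cohort(CohortSpec(n=189, seed=2023))
cv = cross_validate(cohort, k=10, seed=7)

print("fold sizes:", sorted(cv.folds.fold_sizes().values()))
print(format_performance_table([cv.summary], title="Pooled out-of-fold metrics"))
print("fold-1 coefficients (published values in brackets):")
print("  [6.3106, -1.7656, -0.0055, -0.0656, 0.060, 0.224, -0.2052]")
print(format_coefficient_table(cv.fold_fits[0]))
print("Out-of-fold P30/%CC are honest generalization estimates; at n=189")
print("the per-fold coefficients scatter visibly around the generating values.")
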