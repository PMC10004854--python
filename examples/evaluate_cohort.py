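"""Score every equation against measured GFR on a synthetic cohort.

Generates a 2,000-subject obese cohort whose measured GFR follows the
AE mean function with mean-proportional noise (dispersion 5), then
prints the validation table: median bias (eGFR − mGFR; positive =
overestimation), P30 (% of estimates within ±30% of mGFR), Pearson r
with 95% CI, and %CC (% classified into the correct CKD stage).
"""

from aegfr import CohortSpec, generate_cohort, performance_table
from aegfr.io import format_performance_table

cohort = generate_cohort(CohortSpec(n=2000, seed=42))
rows = performance_table(cohort)
print(format_performance_table(rows, title="Synthetic cohort, all subjects"))

for grade in ("I", "II", "III"):
    rows = performance_table(cohort, grade=grade)
    print(format_performance_table(rows, title=f"Grade {grade} obesity"))

print("AE tops P30 and has near-zero median bias here by construction —")
print("the synthetic mGFR is generated from the AE mean function, so this")
print("shows the evaluation machinery, not clinical superiority.")
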