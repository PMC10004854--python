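"""Performance evaluation of GFR estimates against measured GFR.

Metrics follow standard nephrology validation practice: bias
(eGFR − mGFR, summarized by median and quartiles; positive = the equation
overestimates), P30 (percentage of estimates within ±30% of mGFR,
boundary inclusive), Pearson correlation with a Fisher-z 95% CI, and the
percentage of subjects classified into the correct CKD stage (%CC).

Raw-scale equations (LBM_CG, SC — creatinine clearances in mL/min) are
compared against mGFR de-indexed by the subject's body surface area;
staging for %CC happens on the indexed scale by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .equations import (
    DEFAULT_CONFIG,
    EQUATIONS,
    TABLE_EQUATIONS,
    EquationConfig,
    body_surface_area,
    deindex_gfr,
    estimate_frame,
    index_gfr,
)
from .records import DomainError, obesity_grade_vector

__all__ = [
    "PerformanceSummary",
    "CKD_STAGE_LOWER_BOUNDS",
    "bias_summary",
    "p30",
    "pearson_r_ci",
    "ckd_stage",
    "percent_cc",
    "evaluate_equation",
    "performance_table",
]

#: Lower bounds (inclusive) of CKD stages 1..5, mL/min/1.73 m².
CKD_STAGE_LOWER_BOUNDS = (90.0, 60.0, 30.0, 15.0, 0.0)


@dataclass(frozen=True)
class PerformanceSummary:
    """One equation's metrics on one cohort stratum (a table row)."""

    equation_id: str
    n: int
    bias_median: float
    bias_q1: float
    bias_q3: float
    p30: float
    pearson_r: float
    r_ci_low: float
    r_ci_high: float
    pct_cc: float
    reference_scale: str  # "indexed" or "raw"


def _check_pair(estimates, reference):
    e = np.asarray(estimates, dtype=float)
    m = np.asarray(reference, dtype=float)
    if e.shape != m.shape or e.ndim != 1:
        raise ValueError(f"length mismatch: {e.shape} vs {m.shape}")
    if e.size == 0:
        raise ValueError("empty input")
    if np.any(m <= 0):
        raise DomainError("reference GFR must be positive")
    return e, m


def bias_summary(estimates, reference):
    """Median, Q1 and Q3 of per-subject bias eGFR − mGFR.

    Quartiles use linear interpolation between order statistics.  A
    positive median indicates systematic overestimation.
    """
    e, m = _check_pair(estimates, reference)
    d = e - m
    q1, med, q3 = np.percentile(d, [25, 50, 75])
    return float(med), float(q1), float(q3)


def p30(estimates, reference):
    """Percentage of estimates within ±30% of the measured GFR (inclusive)."""
    e, m = _check_pair(estimates, reference)
    hit = np.abs(e - m) <= 0.30 * m
    return float(100.0 * np.count_nonzero(hit) / e.size)


def pearson_r_ci(x, y, level: float = 0.95):
    """Pearson r with a Fisher-z confidence interval.

    Returns (r, ci_low, ci_high).  Requires n ≥ 4 and non-degenerate
    variance in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations for a Fisher-z CI")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(stats.pearsonr(x, y).statistic)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(x.size - 3)
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    return r, float(lo), float(hi)


def ckd_stage(gfr):
    """CKD stage (1–5) for a GFR in mL/min/1.73 m².

    Half-open bins with inclusive lower edges: [90,∞)=1, [60,90)=2,
    [30,60)=3, [15,30)=4, (0,15)=5.  Vectorized.
    """
    g = np.asarray(gfr, dtype=float)
    if np.any(g <= 0) or np.any(~np.isfinite(g)):
        raise DomainError("GFR must be positive and finite for staging")
    stage = 5 - np.digitize(g, [15.0, 30.0, 60.0, 90.0], right=False)
    return int(stage) if np.ndim(gfr) == 0 else stage


def percent_cc(estimates, reference):
    """Percent of subjects whose estimate lands in the reference CKD stage."""
    e, m = _check_pair(estimates, reference)
    agree = ckd_stage(e) == ckd_stage(m)
    return float(100.0 * np.count_nonzero(agree) / e.size)


def evaluate_equation(frame, estimates, equation_id: str,
                      config: EquationConfig = DEFAULT_CONFIG,
                      stage_raw_on_raw: bool = False) -> PerformanceSummary:
    """All metrics for one equation against the cohort's measured GFR.

    ``estimates`` is a DataFrame of per-subject estimates (columns are
    equation ids, as produced by :func:`aegfr.equations.estimate_frame`).
    Indexed-scale equations are compared to mGFR (mL/min/1.73 m²);
    raw-scale clearances (LBM_CG, SC) to mGFR de-indexed by the subject's
    BSA.  %CC for raw-scale equations re-indexes the estimate so staging
    always happens on the indexed scale, unless ``stage_raw_on_raw``.
    """
    info = EQUATIONS[equation_id]
    mgfr = frame["mgfr_ml_min_173"].to_numpy(dtype=float)
    if np.any(~np.isfinite(mgfr)):
        raise DomainError("measured GFR missing for some records")
    est = estimates[equation_id].to_numpy(dtype=float)

    if info.scale == "raw":
        w = frame["weight_kg"].to_numpy(dtype=float)
        h = frame["height_cm"].to_numpy(dtype=float)
        if np.any(~np.isfinite(w)) or np.any(~np.isfinite(h)):
            raise DomainError("weight/height required to de-index mGFR")
        bsa = np.asarray(body_surface_area(w, h, config=config))
        ref = np.asarray(deindex_gfr(mgfr, bsa))
        if stage_raw_on_raw:
            cc = percent_cc(est, ref)
        else:
            cc = percent_cc(np.asarray(index_gfr(est, bsa)), mgfr)
    else:
        ref = mgfr
        cc = percent_cc(est, ref)

    med, q1, q3 = bias_summary(est, ref)
    r, lo, hi = pearson_r_ci(est, ref)
    return PerformanceSummary(
        equation_id=equation_id,
        n=int(est.size),
        bias_median=med, bias_q1=q1, bias_q3=q3,
        p30=p30(est, ref),
        pearson_r=r, r_ci_low=lo, r_ci_high=hi,
        pct_cc=cc,
        reference_scale=info.scale,
    )


def performance_table(frame, grade: Optional[str] = None,
                      equations: Optional[list[str]] = None,
                      config: EquationConfig = DEFAULT_CONFIG,
                      estimates=None) -> list[PerformanceSummary]:
    """One PerformanceSummary per equation, optionally within one obesity grade.

    Row order follows the validation-table convention (LBM_CG, SC, MDRD4,
    MDRD6, CKD-MCQ, CKD-EPI 2009, CKD-EPI 2021, AE).  ``estimates`` may be
    supplied to evaluate externally produced predictions.
    """
    ids = TABLE_EQUATIONS if equations is None else list(equations)
    if grade is not None:
        grades = obesity_grade_vector(
            frame["weight_kg"].to_numpy(float)
            / (frame["height_cm"].to_numpy(float) / 100.0) ** 2)
        frame = frame.loc[grades == grade]
        if estimates is not None:
            estimates = estimates.loc[frame.index]
    if estimates is None:
        estimates = estimate_frame(frame, ids, config)
    return [evaluate_equation(frame, estimates, eid, config) for eid in ids]
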