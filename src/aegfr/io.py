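"""Cohort CSV reading with validation/exclusion rules, and report writers.

The reader mirrors the study's data-computable inclusion rules: adults
only (age ≥ 18), BMI ≥ 30 kg/m², and positive creatinine, urea and
albumin.  Each excluded row is logged once with the first rule it
violated.  Albumin values above 20 are assumed to be on the g/L scale
and rescaled to g/dL (÷10) with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import PerformanceSummary
from .records import COHORT_COLUMNS

__all__ = ["Exclusion", "CohortFormatError", "read_cohort", "write_cohort",
           "format_performance_table", "format_coefficient_table"]

logger = logging.getLogger("aegfr")

_BOOL_MAP = {"0": False, "1": True, "true": True, "false": False,
             "yes": True, "no": False}
_NUMERIC_COLS = ["age_years", "weight_kg", "height_cm", "scr_mg_dl",
                 "urea_mg_dl", "albumin_g_dl", "mgfr_ml_min_173"]
_BOOL_COLS = ["diabetes", "hypertension", "single_kidney"]


class CohortFormatError(ValueError):
    """The CSV file does not conform to the cohort schema."""


@dataclass(frozen=True)
class Exclusion:
    """One excluded record: its id, the first rule violated, the value."""

    record_id: str
    rule: str
    value: object


def _parse_bool(series: pd.Series, col: str) -> pd.Series:
    def one(v):
        s = str(v).strip().lower()
        if s in _BOOL_MAP:
            return _BOOL_MAP[s]
        raise CohortFormatError(f"column {col!r}: unparseable boolean {v!r}")
    return series.map(one)


def read_cohort(path) -> tuple[pd.DataFrame, list[Exclusion]]:
    """Read a cohort CSV, apply exclusion rules, return (frame, exclusions).

    Exclusion rules, in order (a record is logged under the first one it
    fails): age < 18; BMI < 30; missing or non-positive creatinine, urea
    or albumin.  Retained albumin values > 20 are divided by 10 (g/L →
    g/dL) with a logged warning.  mGFR is optional.
    """
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip().lower() for c in raw.columns]
    required = [c for c in COHORT_COLUMNS if c != "mgfr_ml_min_173"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise CohortFormatError(f"malformed header: missing column(s) {missing}")
    extra = [c for c in raw.columns if c not in COHORT_COLUMNS]
    if extra:
        raise CohortFormatError(f"malformed header: unknown column(s) {extra}")
    has_mgfr = "mgfr_ml_min_173" in raw.columns

    frame = pd.DataFrame({"id": raw["id"].astype(str)})
    sex = raw["sex"].str.strip().str.lower()
    bad_sex = ~sex.isin(["male", "female"])
    if bad_sex.any():
        line = int(np.flatnonzero(bad_sex.to_numpy())[0]) + 2  # header is line 1
        raise CohortFormatError(f"line {line}: sex must be male/female")
    frame["sex"] = sex
    for col in _NUMERIC_COLS:
        if col == "mgfr_ml_min_173" and not has_mgfr:
            frame[col] = np.nan
            continue
        vals = pd.to_numeric(raw[col], errors="coerce")
        unparseable = vals.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if unparseable.any():
            line = int(np.flatnonzero(unparseable.to_numpy())[0]) + 2
            raise CohortFormatError(
                f"line {line}: unparseable value {raw[col][unparseable].iloc[0]!r} "
                f"in column {col!r}")
        frame[col] = vals.astype(float)
    for col in _BOOL_COLS:
        frame[col] = _parse_bool(raw[col], col)
    frame = frame[COHORT_COLUMNS]

    exclusions: list[Exclusion] = []
    keep = np.ones(len(frame), dtype=bool)

    def exclude(mask: np.ndarray, rule: str, values) -> None:
        hit = mask & keep
        for i in np.flatnonzero(hit):
            exclusions.append(Exclusion(str(frame["id"].iat[i]), rule,
                                        values.iat[i] if values is not None else None))
        keep[hit] = False

    age = frame["age_years"]
    exclude((age.isna() | (age < 18)).to_numpy(), "age_lt_18", age)
    bmi = frame["weight_kg"] / (frame["height_cm"] / 100.0) ** 2
    exclude((bmi.isna() | (bmi < 30)).to_numpy(), "bmi_lt_30", bmi.round(2))
    for col, rule in [("scr_mg_dl", "missing_or_nonpositive_scr"),
                      ("urea_mg_dl", "missing_or_nonpositive_urea"),
                      ("albumin_g_dl", "missing_or_nonpositive_albumin")]:
        v = frame[col]
        exclude((v.isna() | (v <= 0)).to_numpy(), rule, v)

    retained = frame.loc[keep].reset_index(drop=True)
    rescale = retained["albumin_g_dl"] > 20
    if rescale.any():
        for rid in retained.loc[rescale, "id"]:
            logger.warning("record %s: albumin > 20, assuming g/L; dividing by 10", rid)
        retained.loc[rescale, "albumin_g_dl"] /= 10.0
    return retained, exclusions


def write_cohort(frame: pd.DataFrame, path) -> None:
    """Write a cohort frame in the canonical CSV schema."""
    out = frame[COHORT_COLUMNS].copy()
    for col in _BOOL_COLS:
        out[col] = out[col].astype(bool).astype(int)
    out.to_csv(path, index=False)


def format_performance_table(summaries: list[PerformanceSummary],
                             title: str | None = None) -> str:
    """Validation-style TSV report: Bias (Q1/Q3), P30 (%), r (95% CI), %CC.

    Bias and percentages to 1 decimal, r to 2 — the precision convention
    of published eGFR validation tables.
    """
    from .equations import EQUATIONS

    lines = []
    if title:
        lines.append(f"# {title}")
    lines.append("Equation\tn\tBias (Q1/Q3)\tP30 (%)\tr (95% CI)\t%CC")
    for s in summaries:
        label = EQUATIONS[s.equation_id].label if s.equation_id in EQUATIONS else s.equation_id
        lines.append(
            f"{label}\t{s.n}"
            f"\t{s.bias_median:.1f} ({s.bias_q1:.1f}/{s.bias_q3:.1f})"
            f"\t{s.p30:.1f}"
            f"\t{s.pearson_r:.2f} ({s.r_ci_low:.2f}-{s.r_ci_high:.2f})"
            f"\t{s.pct_cc:.1f}")
    return "\n".join(lines) + "\n"


def format_coefficient_table(fit) -> str:
    """Plain-text TSV coefficient table (term, estimate, SE)."""
    lines = ["term\testimate\tstd_error"]
    for name, b, se in zip(fit.column_names, fit.coefficients, fit.standard_errors):
        lines.append(f"{name}\t{b:.6f}\t{se:.6f}")
    return "\n".join(lines) + "\n"
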