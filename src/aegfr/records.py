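"""Patient-level data model and obesity grading.

A cohort is represented two ways: as a list of :class:`PatientRecord`
(validated, one subject each) or as a :class:`pandas.DataFrame` using the
canonical CSV column names in :data:`COHORT_COLUMNS`.  Labs are on the US
clinical scales: serum creatinine and urea in mg/dL, albumin in g/dL,
measured GFR indexed to 1.73 m² of body surface area.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "DomainError",
    "PatientRecord",
    "COHORT_COLUMNS",
    "obesity_grade",
    "records_to_frame",
    "frame_to_records",
]


class DomainError(ValueError):
    """An input lies outside the domain of an equation or data contract."""


#: Canonical cohort CSV schema (column order). ``mgfr_ml_min_173`` is optional.
COHORT_COLUMNS = [
    "id",
    "sex",
    "age_years",
    "weight_kg",
    "height_cm",
    "diabetes",
    "hypertension",
    "single_kidney",
    "scr_mg_dl",
    "urea_mg_dl",
    "albumin_g_dl",
    "mgfr_ml_min_173",
]

_OBESITY_EDGES = (30.0, 35.0, 40.0)


def obesity_grade(bmi: float) -> str:
    """WHO obesity grade for a BMI in kg/m².

    Half-open bins: I = [30, 35), II = [35, 40), III = [40, ∞).  Raises
    :class:`DomainError` below 30 (non-obese subjects are outside the
    cohort definition).
    """
    if np.isnan(bmi) or bmi < _OBESITY_EDGES[0]:
        raise DomainError(f"BMI {bmi} is below 30 kg/m²; not an obese subject")
    if bmi < _OBESITY_EDGES[1]:
        return "I"
    if bmi < _OBESITY_EDGES[2]:
        return "II"
    return "III"


def obesity_grade_vector(bmi: np.ndarray | pd.Series) -> np.ndarray:
    """Vectorized :func:`obesity_grade`; raises if any BMI < 30."""
    bmi = np.asarray(bmi, dtype=float)
    if np.any(bmi < 30.0):
        raise DomainError("cohort contains BMI < 30 kg/m²")
    out = np.full(bmi.shape, "I", dtype=object)
    out[bmi >= 35.0] = "II"
    out[bmi >= 40.0] = "III"
    return out


@dataclass(frozen=True)
class PatientRecord:
    """One subject's demographics, anthropometrics, labs and optional mGFR.

    Parameters
    ----------
    sex : {"male", "female"}
    age : years
    weight, height : kg, cm
    scr, urea : serum creatinine and urea, mg/dL (IDMS-traceable creatinine)
    albumin : serum albumin, g/dL
    mgfr_indexed : measured GFR in mL/min/1.73 m² (iothalamate clearance),
        or ``None`` when no reference measurement exists.
    """

    id: str
    sex: str
    age: float
    weight: float
    height: float
    diabetes: bool
    hypertension: bool
    single_kidney: bool
    scr: float
    urea: float
    albumin: float
    mgfr_indexed: Optional[float] = None

    @property
    def bmi(self) -> float:
        return self.weight / (self.height / 100.0) ** 2

    @property
    def is_male(self) -> bool:
        return self.sex == "male"

    @property
    def grade(self) -> str:
        return obesity_grade(self.bmi)

    def validate(self, require_obese: bool = True) -> "PatientRecord":
        """Check the record invariants, returning self; raise DomainError."""
        if self.sex not in ("male", "female"):
            raise DomainError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not self.age >= 18:
            raise DomainError(f"age must be >= 18 years, got {self.age}")
        for name in ("scr", "urea", "albumin", "weight", "height"):
            v = getattr(self, name)
            if not (v is not None and np.isfinite(v) and v > 0):
                raise DomainError(f"{name} must be positive and finite, got {v}")
        if require_obese and self.bmi < 30.0:
            raise DomainError(f"BMI {self.bmi:.1f} < 30 kg/m²; outside cohort")
        if self.mgfr_indexed is not None and not self.mgfr_indexed > 0:
            raise DomainError(f"mgfr_indexed must be positive, got {self.mgfr_indexed}")
        return self


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Assemble PatientRecords into the canonical cohort DataFrame."""
    rows = [
        {
            "id": r.id,
            "sex": r.sex,
            "age_years": r.age,
            "weight_kg": r.weight,
            "height_cm": r.height,
            "diabetes": bool(r.diabetes),
            "hypertension": bool(r.hypertension),
            "single_kidney": bool(r.single_kidney),
            "scr_mg_dl": r.scr,
            "urea_mg_dl": r.urea,
            "albumin_g_dl": r.albumin,
            "mgfr_ml_min_173": np.nan if r.mgfr_indexed is None else r.mgfr_indexed,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[PatientRecord]:
    """Materialize PatientRecords from a canonical cohort DataFrame."""
    out = []
    for _, row in frame.iterrows():
        mgfr = row.get("mgfr_ml_min_173", np.nan)
        out.append(
            PatientRecord(
                id=str(row["id"]),
                sex=str(row["sex"]),
                age=float(row["age_years"]),
                weight=float(row["weight_kg"]),
                height=float(row["height_cm"]),
                diabetes=bool(row["diabetes"]),
                hypertension=bool(row["hypertension"]),
                single_kidney=bool(row["single_kidney"]),
                scr=float(row["scr_mg_dl"]),
                urea=float(row["urea_mg_dl"]),
                albumin=float(row["albumin_g_dl"]),
                mgfr_indexed=None if pd.isna(mgfr) else float(mgfr),
            )
        )
    return out
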