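"""Closed-form GFR and creatinine-clearance equations for obese adults.

Implements the Argentinian Equation (AE) — a log-link quasi-likelihood
model of measured GFR on √creatinine, age, ln urea, albumin, sex and
single-kidney status — together with the comparator equations it was
validated against (CKD-EPI 2009/2021, MDRD4/6, the Mayo Clinic Quadratic
equation and its combination with CKD-EPI 2009, lean-body-mass
Cockcroft–Gault and Salazar–Corcoran), plus body-size helpers (Du Bois /
Mosteller BSA, James lean body mass) and 1.73 m² indexing conversions.

All equation functions are NumPy-vectorized: scalars in → float out,
arrays in → array out.  eGFR units are mL/min/1.73 m² except LBM_CG and
SC, which predict raw (non-indexed) creatinine clearance in mL/min.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .records import DomainError, PatientRecord

__all__ = [
    "AE_COEFFICIENTS",
    "EquationConfig",
    "EquationInfo",
    "EQUATIONS",
    "TABLE_EQUATIONS",
    "EstimateSet",
    "egfr_ae",
    "egfr_ckdepi2009",
    "egfr_ckdepi2021",
    "egfr_mdrd4",
    "egfr_mdrd6",
    "egfr_mcq",
    "egfr_ckd_mcq",
    "lean_body_mass_james",
    "crcl_lbm_cg",
    "crcl_salazar_corcoran",
    "bsa_dubois",
    "bsa_mosteller",
    "deindex_gfr",
    "index_gfr",
    "estimate_all",
    "estimate_frame",
]

#: Published AE coefficients, keyed by design column.  The creatinine term
#: applies to √SCr under the default transform (see EquationConfig).
AE_COEFFICIENTS = {
    "intercept": 6.3106,
    "scr_term": -1.7656,
    "age": -0.0055,
    "log_urea": -0.0656,
    "albumin": 0.060,
    "male": 0.224,
    "single_kidney": -0.2052,
}


@dataclass(frozen=True)
class EquationConfig:
    """Options where the published sources leave a choice.

    ae_scr_transform : {"sqrt", "linear"}
        How AE's creatinine coefficient is applied.  "sqrt" (default)
        follows the model's stated predictor (√SCr); "linear" reproduces
        the equation exactly as typeset, which yields non-physiologic
        values at high creatinine.
    ckd_mcq_rule : {"mean", "geometric"}
        How CKD-EPI 2009 and MCQ are combined into CKD-MCQ.
    bsa_formula : {"dubois", "mosteller"}
        Body-surface-area formula used for 1.73 m² indexing.
    mdrd6_constant : float
        Leading constant of the IDMS-traceable 6-variable MDRD.
    urea_to_bun : float
        Divisor converting urea (mg/dL) to blood urea nitrogen.
    """

    ae_scr_transform: str = "sqrt"
    ckd_mcq_rule: str = "mean"
    bsa_formula: str = "dubois"
    mdrd6_constant: float = 161.5
    urea_to_bun: float = 2.14

    def __post_init__(self):
        if self.ae_scr_transform not in ("sqrt", "linear"):
            raise ValueError(f"ae_scr_transform: {self.ae_scr_transform!r}")
        if self.ckd_mcq_rule not in ("mean", "geometric"):
            raise ValueError(f"ckd_mcq_rule: {self.ckd_mcq_rule!r}")
        if self.bsa_formula not in ("dubois", "mosteller"):
            raise ValueError(f"bsa_formula: {self.bsa_formula!r}")


DEFAULT_CONFIG = EquationConfig()


def _require_positive(**fields) -> None:
    for name, value in fields.items():
        arr = np.asarray(value, dtype=float)
        if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
            raise DomainError(f"{name} must be positive and finite")


def _maybe_scalar(x: np.ndarray):
    return float(x) if np.ndim(x) == 0 else x


def egfr_ae(scr, age, urea, albumin, is_male, single_kidney=False,
            *, config: EquationConfig = DEFAULT_CONFIG,
            coefficients: Optional[dict] = None):
    """Argentinian Equation eGFR, mL/min/1.73 m².

    exp(6.3106 − 1.7656·√SCr − 0.0055·age − 0.0656·ln(urea)
        + 0.060·albumin + 0.224·[male] − 0.2052·[single kidney])

    SCr and urea in mg/dL, albumin in g/dL.  ``coefficients`` overrides
    the published values (used by the model-fitting loop).
    """
    _require_positive(scr=scr, age=age, urea=urea, albumin=albumin)
    c = AE_COEFFICIENTS if coefficients is None else coefficients
    scr = np.asarray(scr, dtype=float)
    scr_term = np.sqrt(scr) if config.ae_scr_transform == "sqrt" else scr
    eta = (
        c["intercept"]
        + c["scr_term"] * scr_term
        + c["age"] * np.asarray(age, dtype=float)
        + c["log_urea"] * np.log(np.asarray(urea, dtype=float))
        + c["albumin"] * np.asarray(albumin, dtype=float)
        + c["male"] * np.asarray(is_male, dtype=float)
        + c["single_kidney"] * np.asarray(single_kidney, dtype=float)
    )
    return _maybe_scalar(np.exp(eta))


def egfr_ckdepi2009(scr, age, is_female, is_black=False):
    """CKD-EPI 2009 creatinine eGFR, mL/min/1.73 m²."""
    _require_positive(scr=scr, age=age)
    scr = np.asarray(scr, dtype=float)
    female = np.asarray(is_female, dtype=bool)
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.329, -0.411)
    r = scr / kappa
    out = (
        141.0
        * np.minimum(r, 1.0) ** alpha
        * np.maximum(r, 1.0) ** -1.209
        * 0.993 ** np.asarray(age, dtype=float)
        * np.where(female, 1.018, 1.0)
        * np.where(np.asarray(is_black, dtype=bool), 1.159, 1.0)
    )
    return _maybe_scalar(out)


def egfr_ckdepi2021(scr, age, is_female):
    """CKD-EPI 2021 race-free creatinine eGFR, mL/min/1.73 m²."""
    _require_positive(scr=scr, age=age)
    scr = np.asarray(scr, dtype=float)
    female = np.asarray(is_female, dtype=bool)
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.241, -0.302)
    r = scr / kappa
    out = (
        142.0
        * np.minimum(r, 1.0) ** alpha
        * np.maximum(r, 1.0) ** -1.200
        * 0.9938 ** np.asarray(age, dtype=float)
        * np.where(female, 1.012, 1.0)
    )
    return _maybe_scalar(out)


def egfr_mdrd4(scr, age, is_female, is_black=False):
    """IDMS-traceable 4-variable MDRD eGFR, mL/min/1.73 m²."""
    _require_positive(scr=scr, age=age)
    out = (
        175.0
        * np.asarray(scr, dtype=float) ** -1.154
        * np.asarray(age, dtype=float) ** -0.203
        * np.where(np.asarray(is_female, dtype=bool), 0.742, 1.0)
        * np.where(np.asarray(is_black, dtype=bool), 1.212, 1.0)
    )
    return _maybe_scalar(out)


def egfr_mdrd6(scr, age, urea, albumin, is_female, is_black=False,
               *, config: EquationConfig = DEFAULT_CONFIG):
    """IDMS-traceable 6-variable MDRD eGFR, mL/min/1.73 m².

    Urea (mg/dL) is converted to BUN by the molecular-weight ratio
    (default ÷2.14); albumin in g/dL.
    """
    _require_positive(scr=scr, age=age, urea=urea, albumin=albumin)
    bun = np.asarray(urea, dtype=float) / config.urea_to_bun
    out = (
        config.mdrd6_constant
        * np.asarray(scr, dtype=float) ** -0.999
        * np.asarray(age, dtype=float) ** -0.176
        * bun ** -0.170
        * np.asarray(albumin, dtype=float) ** 0.318
        * np.where(np.asarray(is_female, dtype=bool), 0.762, 1.0)
        * np.where(np.asarray(is_black, dtype=bool), 1.180, 1.0)
    )
    return _maybe_scalar(out)


def egfr_mcq(scr, age, is_female):
    """Mayo Clinic Quadratic eGFR, mL/min/1.73 m².

    Creatinine below 0.8 mg/dL is clamped to 0.8 per the equation's
    published rule.
    """
    _require_positive(scr=scr, age=age)
    s = np.maximum(np.asarray(scr, dtype=float), 0.8)
    out = np.exp(
        1.911
        + 5.249 / s
        - 2.114 / s**2
        - 0.00686 * np.asarray(age, dtype=float)
        - np.where(np.asarray(is_female, dtype=bool), 0.205, 0.0)
    )
    return _maybe_scalar(out)


def egfr_ckd_mcq(scr, age, is_female, *, config: EquationConfig = DEFAULT_CONFIG):
    """CKD-MCQ: combination of CKD-EPI 2009 (non-black) and MCQ.

    Arithmetic mean by default; geometric mean available via config.
    """
    a = np.asarray(egfr_ckdepi2009(scr, age, is_female))
    b = np.asarray(egfr_mcq(scr, age, is_female))
    out = np.sqrt(a * b) if config.ckd_mcq_rule == "geometric" else (a + b) / 2.0
    return _maybe_scalar(out)


def lean_body_mass_james(weight, height, is_male):
    """James lean body mass, kg.  Weight in kg, height in cm.

    male:   1.1·W − 128·(W/H)²
    female: 1.07·W − 148·(W/H)²
    """
    _require_positive(weight=weight, height=height)
    w = np.asarray(weight, dtype=float)
    h = np.asarray(height, dtype=float)
    male = np.asarray(is_male, dtype=bool)
    ratio2 = (w / h) ** 2
    lbm = np.where(male, 1.1 * w - 128.0 * ratio2, 1.07 * w - 148.0 * ratio2)
    if np.any(lbm <= 0):
        raise DomainError("lean body mass <= 0: degenerate anthropometrics")
    return _maybe_scalar(lbm)


def crcl_lbm_cg(scr, age, lbm, is_female):
    """Cockcroft–Gault creatinine clearance on lean body mass, mL/min (raw)."""
    _require_positive(scr=scr, age=age, lbm=lbm)
    out = (
        (140.0 - np.asarray(age, dtype=float))
        * np.asarray(lbm, dtype=float)
        / (72.0 * np.asarray(scr, dtype=float))
        * np.where(np.asarray(is_female, dtype=bool), 0.85, 1.0)
    )
    return _maybe_scalar(out)


def crcl_salazar_corcoran(scr, age, weight, height_m, is_female):
    """Salazar–Corcoran creatinine clearance for obese subjects, mL/min (raw).

    Height in metres (note: not cm).
    """
    _require_positive(scr=scr, age=age, weight=weight, height_m=height_m)
    age = np.asarray(age, dtype=float)
    w = np.asarray(weight, dtype=float)
    h = np.asarray(height_m, dtype=float)
    scr = np.asarray(scr, dtype=float)
    male_val = (137.0 - age) * (0.285 * w + 12.1 * h**2) / (51.0 * scr)
    female_val = (146.0 - age) * (0.287 * w + 9.74 * h**2) / (60.0 * scr)
    out = np.where(np.asarray(is_female, dtype=bool), female_val, male_val)
    return _maybe_scalar(out)


def bsa_dubois(weight, height):
    """Du Bois–Du Bois body surface area, m².  Weight kg, height cm."""
    w = np.asarray(weight, dtype=float)
    h = np.asarray(height, dtype=float)
    return _maybe_scalar(0.007184 * w**0.425 * h**0.725)


def bsa_mosteller(weight, height):
    """Mosteller body surface area, m².  Weight kg, height cm."""
    w = np.asarray(weight, dtype=float)
    h = np.asarray(height, dtype=float)
    return _maybe_scalar(np.sqrt(w * h / 3600.0))


def body_surface_area(weight, height, *, config: EquationConfig = DEFAULT_CONFIG):
    f = bsa_mosteller if config.bsa_formula == "mosteller" else bsa_dubois
    return f(weight, height)


def deindex_gfr(gfr_indexed, bsa):
    """Convert mL/min/1.73 m² to the subject's raw mL/min."""
    out = np.asarray(gfr_indexed, dtype=float) * np.asarray(bsa, dtype=float) / 1.73
    return _maybe_scalar(out)


def index_gfr(gfr_raw, bsa):
    """Convert raw mL/min to mL/min/1.73 m²; inverse of :func:`deindex_gfr`."""
    out = np.asarray(gfr_raw, dtype=float) * 1.73 / np.asarray(bsa, dtype=float)
    return _maybe_scalar(out)


# ---------------------------------------------------------------------------
# Equation registry


@dataclass(frozen=True)
class EquationInfo:
    """Registry entry: a stable id, output scale, and a frame evaluator."""

    id: str
    label: str
    scale: str  # "indexed" (mL/min/1.73 m²) or "raw" (mL/min)
    func: Callable  # (frame, config) -> ndarray


def _female(frame) -> np.ndarray:
    return (frame["sex"].to_numpy() == "female")


def _eval_ae(f, cfg):
    return egfr_ae(f["scr_mg_dl"].to_numpy(float), f["age_years"].to_numpy(float),
                   f["urea_mg_dl"].to_numpy(float), f["albumin_g_dl"].to_numpy(float),
                   ~_female(f), f["single_kidney"].to_numpy(bool), config=cfg)


def _eval_lbm_cg(f, cfg):
    lbm = lean_body_mass_james(f["weight_kg"].to_numpy(float),
                               f["height_cm"].to_numpy(float), ~_female(f))
    return crcl_lbm_cg(f["scr_mg_dl"].to_numpy(float),
                       f["age_years"].to_numpy(float), lbm, _female(f))


EQUATIONS: dict[str, EquationInfo] = {
    e.id: e
    for e in [
        EquationInfo("LBM_CG", "LBM_CG", "raw", _eval_lbm_cg),
        EquationInfo("SC", "SC", "raw",
                     lambda f, c: crcl_salazar_corcoran(
                         f["scr_mg_dl"].to_numpy(float), f["age_years"].to_numpy(float),
                         f["weight_kg"].to_numpy(float),
                         f["height_cm"].to_numpy(float) / 100.0, _female(f))),
        EquationInfo("MDRD4", "MDRD4", "indexed",
                     lambda f, c: egfr_mdrd4(f["scr_mg_dl"].to_numpy(float),
                                             f["age_years"].to_numpy(float), _female(f))),
        EquationInfo("MDRD6", "MDRD6", "indexed",
                     lambda f, c: egfr_mdrd6(f["scr_mg_dl"].to_numpy(float),
                                             f["age_years"].to_numpy(float),
                                             f["urea_mg_dl"].to_numpy(float),
                                             f["albumin_g_dl"].to_numpy(float),
                                             _female(f), config=c)),
        EquationInfo("MCQ", "MCQ", "indexed",
                     lambda f, c: egfr_mcq(f["scr_mg_dl"].to_numpy(float),
                                           f["age_years"].to_numpy(float), _female(f))),
        EquationInfo("CKDMCQ", "CKD-MCQ", "indexed",
                     lambda f, c: egfr_ckd_mcq(f["scr_mg_dl"].to_numpy(float),
                                               f["age_years"].to_numpy(float),
                                               _female(f), config=c)),
        EquationInfo("CKDEPI2009", "CKD-EPI 2009", "indexed",
                     lambda f, c: egfr_ckdepi2009(f["scr_mg_dl"].to_numpy(float),
                                                  f["age_years"].to_numpy(float),
                                                  _female(f))),
        EquationInfo("CKDEPI2021", "CKD-EPI 2021", "indexed",
                     lambda f, c: egfr_ckdepi2021(f["scr_mg_dl"].to_numpy(float),
                                                  f["age_years"].to_numpy(float),
                                                  _female(f))),
        EquationInfo("AE", "AE", "indexed", _eval_ae),
    ]
}

#: The eight equations reported in the validation tables, in table order.
#: (MCQ enters only through CKD-MCQ but remains individually addressable.)
TABLE_EQUATIONS = ["LBM_CG", "SC", "MDRD4", "MDRD6", "CKDMCQ",
                   "CKDEPI2009", "CKDEPI2021", "AE"]


@dataclass
class EstimateSet:
    """Per-subject estimates keyed by equation id, with scale tags.

    ``values`` maps equation id → estimate; ``scales`` maps id →
    "indexed"/"raw"; ``errors`` collects per-equation failures (missing
    anthropometrics etc.) without blocking the remaining equations.
    """

    subject_id: str
    values: dict = field(default_factory=dict)
    scales: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


def estimate_frame(frame, equations: Optional[list[str]] = None,
                   config: EquationConfig = DEFAULT_CONFIG):
    """Evaluate equations over a cohort frame → DataFrame of estimates.

    Columns are equation ids, index matches the input frame.  Unknown ids
    raise KeyError listing the registry.
    """
    import pandas as pd

    ids = TABLE_EQUATIONS if equations is None else list(equations)
    unknown = [i for i in ids if i not in EQUATIONS]
    if unknown:
        raise KeyError(
            f"unknown equation id(s) {unknown}; registry: {sorted(EQUATIONS)}")
    out = pd.DataFrame(index=frame.index)
    for eid in ids:
        out[eid] = np.asarray(EQUATIONS[eid].func(frame, config), dtype=float)
    return out


def estimate_all(record: PatientRecord, equations: Optional[list[str]] = None,
                 config: EquationConfig = DEFAULT_CONFIG) -> EstimateSet:
    """Evaluate all (default: the eight table) equations for one subject.

    Per-equation domain errors are captured in ``EstimateSet.errors``
    tagged with the equation id; the other equations still evaluate.
    """
    from .records import records_to_frame

    # Labs and age must be valid; anthropometrics may be missing, in which
    # case only the equations needing them (LBM_CG, SC) report errors.
    _require_positive(scr=record.scr, urea=record.urea,
                      albumin=record.albumin, age=record.age)
    frame = records_to_frame([record])
    ids = TABLE_EQUATIONS if equations is None else list(equations)
    es = EstimateSet(subject_id=record.id,
                     metadata={"ae_scr_transform": config.ae_scr_transform,
                               "ckd_mcq_rule": config.ckd_mcq_rule,
                               "bsa_formula": config.bsa_formula})
    for eid in ids:
        info = EQUATIONS[eid]
        try:
            es.values[eid] = float(np.asarray(info.func(frame, config))[0])
            es.scales[eid] = info.scale
        except (DomainError, ValueError) as exc:
            es.errors[eid] = f"{eid}: {exc}"
    return es
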