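"""Equation-level checks against independently hand-computed values.

Every expected number below was evaluated term by term from the published
formula with standard double-precision arithmetic, independently of the
package code.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aegfr.equations import (
    EQUATIONS,
    TABLE_EQUATIONS,
    EquationConfig,
    bsa_dubois,
    bsa_mosteller,
    crcl_lbm_cg,
    crcl_salazar_corcoran,
    deindex_gfr,
    egfr_ae,
    egfr_ckd_mcq,
    egfr_ckdepi2009,
    egfr_ckdepi2021,
    egfr_mcq,
    egfr_mdrd4,
    egfr_mdrd6,
    estimate_all,
    estimate_frame,
    index_gfr,
    lean_body_mass_james,
)
from aegfr.records import DomainError, PatientRecord, obesity_grade

REL = 1e-6


# --- hand-computed value oracles, one parametrized test per equation ------

@pytest.mark.parametrize("kwargs,expected", [
    # Table-style median subject: 6.3106 − 1.7656·√0.85 − 0.0055·50
    #   − 0.0656·ln 31.1 + 0.060·4.2 → exp(4.434113…) = 84.29448…
    (dict(scr=0.85, age=50, urea=31.1, albumin=4.2, is_male=False), 84.2944812850687),
    (dict(scr=0.85, age=50, urea=31.1, albumin=4.2, is_male=True,
          single_kidney=True), 85.89420784589775),
    (dict(scr=2.5, age=65, urea=90.0, albumin=3.5, is_male=True),
     math.exp(6.3106 - 1.7656 * math.sqrt(2.5) - 0.0055 * 65
              - 0.0656 * math.log(90.0) + 0.060 * 3.5 + 0.224)),
])
def test_ae_matches_hand_computation(kwargs, expected):
    assert egfr_ae(**kwargs) == pytest.approx(expected, rel=REL)


@pytest.mark.parametrize("args,expected", [
    ((0.9, 50, False), 99.23880760942112),   # at the male knot: 141·0.993^50
    ((0.7, 50, True), 101.0251061463907),    # at the female knot
    ((1.2, 60, True), 49.0812036065478),
])
def test_ckdepi2009_matches_hand_computation(args, expected):
    assert egfr_ckdepi2009(*args) == pytest.approx(expected, rel=REL)


@pytest.mark.parametrize("args,expected", [
    ((0.9, 50, False), 104.0490129932253),   # at the knot: 142·0.9938^50
    ((1.4, 65, True), 41.75104679388652),
    ((0.7, 50, True), 142 * 0.9938**50 * 1.012),
])
def test_ckdepi2021_matches_hand_computation(args, expected):
    assert egfr_ckdepi2021(*args) == pytest.approx(expected, rel=REL)


@pytest.mark.parametrize("args,expected", [
    ((1.0, 1.0, False), 175.0),              # all power terms unity
    ((0.85, 50, True), 70.79483971395409),
    ((1.3, 64, False), 55.57671656907578),
])
def test_mdrd4_matches_hand_computation(args, expected):
    assert egfr_mdrd4(*args) == pytest.approx(expected, rel=REL)


@pytest.mark.parametrize("kwargs,expected", [
    (dict(scr=1.0, age=1.0, urea=2.14, albumin=1.0, is_female=False), 161.5),
    (dict(scr=0.85, age=50, urea=31.1, albumin=4.2, is_female=True),
     72.81378718612048),
    (dict(scr=1.1, age=62, urea=48.0, albumin=3.8, is_female=False),
     63.98686190631968),
])
def test_mdrd6_matches_hand_computation(kwargs, expected):
    assert egfr_mdrd6(**kwargs) == pytest.approx(expected, rel=REL)


@pytest.mark.parametrize("args,expected", [
    ((0.8, 40, False), 133.58326616477106),
    ((1.5, 55, True), 48.836489923801416),
    ((2.0, 70, False),
     math.exp(1.911 + 5.249 / 2.0 - 2.114 / 4.0 - 0.00686 * 70)),
])
def test_mcq_matches_hand_computation(args, expected):
    assert egfr_mcq(*args) == pytest.approx(expected, rel=REL)


@pytest.mark.parametrize("args,expected", [
    ((100, 170, True), 65.70934256055364),
    ((100, 170, False), 55.78892733564013),
])
def test_lean_body_mass_matches_hand_computation(args, expected):
    assert lean_body_mass_james(*args) == pytest.approx(expected, rel=REL)


@pytest.mark.parametrize("args,expected", [
    ((1.0, 40, 72.0, False), 100.0),         # (140−40)·72/(72·1)
    ((1.0, 40, 72.0, True), 85.0),
    ((0.85, 50, 65.70934256055364, False), 96.63138611846124),
])
def test_cockcroft_gault_lbm_matches_hand_computation(args, expected):
    assert crcl_lbm_cg(*args) == pytest.approx(expected, rel=REL)


@pytest.mark.parametrize("args,expected", [
    ((1.0, 50, 100.0, 1.7, False), 108.27064705882353),
    ((1.0, 50, 100.0, 1.7, True), 90.95776),
    ((0.5, 50, 100.0, 1.7, False), 2 * 108.27064705882353),  # 1/scr scaling
])
def test_salazar_corcoran_matches_hand_computation(args, expected):
    assert crcl_salazar_corcoran(*args) == pytest.approx(expected, rel=REL)


def test_bsa_and_indexing():
    bsa = bsa_dubois(100, 170)
    assert bsa == pytest.approx(2.105919624385031, rel=REL)
    assert deindex_gfr(90.0, bsa) == pytest.approx(109.55651225124437, rel=REL)
    assert deindex_gfr(90.0, 1.73) == 90.0
    assert bsa_mosteller(100, 170) == pytest.approx(math.sqrt(100 * 170 / 3600))


# --- structural identities -------------------------------------------------

def test_ae_indicators_are_exact_multiplicative_constants():
    base = dict(scr=1.2, age=61.0, urea=44.0, albumin=4.0)
    male = egfr_ae(**base, is_male=True)
    female = egfr_ae(**base, is_male=False)
    sk = egfr_ae(**base, is_male=True, single_kidney=True)
    assert male / female == pytest.approx(math.exp(0.224), abs=1e-12)
    assert sk / male == pytest.approx(math.exp(-0.2052), abs=1e-12)


def test_ae_linear_transform_switch():
    cfg = EquationConfig(ae_scr_transform="linear")
    val = egfr_ae(2.0, 50, 40, 4.0, True, config=cfg)
    sqrt_val = egfr_ae(2.0, 50, 40, 4.0, True)
    # linear uses scr itself: differs by exp(−1.7656·(2 − √2))
    assert val / sqrt_val == pytest.approx(
        math.exp(-1.7656 * (2.0 - math.sqrt(2.0))), rel=1e-12)


@pytest.mark.parametrize("func,kappa", [
    (lambda s: egfr_ckdepi2009(s, 50, False), 0.9),
    (lambda s: egfr_ckdepi2009(s, 50, True), 0.7),
    (lambda s: egfr_ckdepi2021(s, 50, False), 0.9),
    (lambda s: egfr_ckdepi2021(s, 50, True), 0.7),
])
def test_ckdepi_continuous_at_knot(func, kappa):
    eps = 1e-10
    assert abs(func(kappa - eps) - func(kappa + eps)) < 1e-6
    assert abs(func(kappa) - func(kappa + eps)) < 1e-6


def test_mcq_clamps_low_creatinine():
    assert egfr_mcq(0.5, 40, False) == egfr_mcq(0.8, 40, False)
    for s in [0.1, 0.3, 0.6, 0.8]:
        assert egfr_mcq(s, 40, False) == egfr_mcq(0.8, 40, False)


def test_ckd_mcq_is_mean_of_components():
    a = egfr_ckdepi2009(0.9, 50, False)
    b = egfr_mcq(0.9, 50, False)
    combined = egfr_ckd_mcq(0.9, 50, False)
    assert combined == pytest.approx((a + b) / 2, rel=1e-12)
    assert min(a, b) <= combined <= max(a, b)
    geo = egfr_ckd_mcq(0.9, 50, False, config=EquationConfig(ckd_mcq_rule="geometric"))
    assert geo == pytest.approx(math.sqrt(a * b), rel=1e-12)


def test_mdrd4_power_law_in_scr():
    assert egfr_mdrd4(2.0, 50, False) / egfr_mdrd4(1.0, 50, False) == pytest.approx(
        2.0 ** -1.154, rel=1e-12)


def test_ae_monotone_in_scr_urea_albumin():
    scr = np.linspace(0.2, 15, 300)
    vals = egfr_ae(scr, 50, 31.1, 4.2, False)
    assert np.all(np.diff(vals) < 0)
    urea = np.linspace(5, 300, 300)
    assert np.all(np.diff(egfr_ae(0.85, 50, urea, 4.2, False)) < 0)
    alb = np.linspace(1.5, 5.5, 100)
    assert np.all(np.diff(egfr_ae(0.85, 50, 31.1, alb, False)) > 0)


def test_ckdepi2021_monotone_nonincreasing_in_scr():
    scr = np.linspace(0.1, 15, 500)
    for female in (True, False):
        vals = egfr_ckdepi2021(scr, 50, female)
        assert np.all(np.diff(vals) <= 0)


def test_all_equations_finite_positive_over_cohort_envelope(forward_cohort):
    est = estimate_frame(forward_cohort, list(EQUATIONS))
    assert np.all(np.isfinite(est.to_numpy()))
    assert np.all(est.to_numpy() > 0)


def test_lbm_below_weight_over_cohort_envelope():
    """James LBM stays below total weight wherever it is defined; the
    extreme short/super-obese corner where the quadratic goes non-positive
    raises the degenerate-anthropometrics error instead."""
    bmi = np.linspace(30, 75, 40)
    height = np.linspace(140, 200, 40)
    bb, hh = np.meshgrid(bmi, height)
    w = (bb * (hh / 100) ** 2).ravel()
    h = hh.ravel()
    for male, a, b in ((True, 1.1, 128.0), (False, 1.07, 148.0)):
        direct = a * w - b * (w / h) ** 2
        ok = direct > 0
        lbm = lean_body_mass_james(w[ok], h[ok], male)
        assert np.all(lbm < w[ok])
        if (~ok).any():
            with pytest.raises(DomainError):
                lean_body_mass_james(w, h, male)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(x=st.floats(1.0, 200.0), bsa=st.floats(1.2, 3.5))
def test_index_deindex_round_trip(x, bsa):
    assert index_gfr(deindex_gfr(x, bsa), bsa) == pytest.approx(x, abs=1e-12)


# --- domain errors and registry -------------------------------------------

@pytest.mark.parametrize("bad_kwargs,field", [
    (dict(scr=-0.1, age=50, urea=31.1, albumin=4.2, is_male=False), "scr"),
    (dict(scr=0.85, age=50, urea=0.0, albumin=4.2, is_male=False), "urea"),
    (dict(scr=0.85, age=50, urea=31.1, albumin=-1.0, is_male=False), "albumin"),
    (dict(scr=0.85, age=0.0, urea=31.1, albumin=4.2, is_male=False), "age"),
])
def test_ae_domain_errors_name_the_field(bad_kwargs, field):
    with pytest.raises(DomainError, match=field):
        egfr_ae(**bad_kwargs)


def test_lbm_degenerate_anthropometrics_raise():
    with pytest.raises(DomainError):
        lean_body_mass_james(200.0, 120.0, False)


def test_obesity_grade_bins():
    assert obesity_grade(30.0) == "I"
    assert obesity_grade(34.99) == "I"
    assert obesity_grade(35.0) == "II"
    assert obesity_grade(39.99) == "II"
    assert obesity_grade(40.0) == "III"
    assert obesity_grade(72.3) == "III"
    with pytest.raises(DomainError):
        obesity_grade(29.9)


def test_estimate_all_registry_and_tags(median_patient):
    es = estimate_all(median_patient)
    assert len(es.values) == 8
    scales = list(es.scales.values())
    assert scales.count("indexed") == 6 and scales.count("raw") == 2
    assert es.scales["LBM_CG"] == "raw" and es.scales["SC"] == "raw"
    # delegation: agrees with the direct calls
    assert es.values["AE"] == pytest.approx(
        egfr_ae(0.85, 50, 31.1, 4.2, False), rel=1e-12)
    assert es.values["CKDEPI2009"] == pytest.approx(
        egfr_ckdepi2009(0.85, 50, True), rel=1e-12)


def test_estimate_all_missing_height_fails_only_body_size_equations(median_patient):
    import dataclasses

    rec = dataclasses.replace(median_patient, height=float("nan"))
    es = estimate_all(rec)
    assert set(es.errors) == {"LBM_CG", "SC"}
    assert set(es.values) == set(TABLE_EQUATIONS) - {"LBM_CG", "SC"}


def test_estimate_frame_unknown_id_lists_registry(forward_cohort):
    with pytest.raises(KeyError, match="AE"):
        estimate_frame(forward_cohort, ["NOPE"])
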