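"""Exact-mass arithmetic: parsing, masses, ion m/z, ppm and isobar deltas."""

import math

import pytest
from hypothesis import given, settings, strategies as st
from pyteomics import mass as pyteomics_mass

from fufatag import (
    ELECTRON_MASS,
    Formula,
    IonSpec,
    formula_format,
    formula_parse,
    ion_mz,
    isobar_delta,
    monoisotopic_mass,
    ppm_error,
    required_resolution,
    round_half_up,
)


# -- parsing / formatting ---------------------------------------------------

@pytest.mark.parametrize(
    "text,expected",
    [
        ("C22H38O3", {"C": 22, "H": 38, "O": 3}),
        ("O", {"O": 1}),
        ("CH4", {"C": 1, "H": 4}),
        ("C57H98O6", {"C": 57, "H": 98, "O": 6}),
        ("H8O", {"H": 8, "O": 1}),
    ],
)
def test_formula_parse(text, expected):
    assert dict(formula_parse(text)) == expected


@pytest.mark.parametrize("bad", ["Xx12", "C-3", "22C", "C0", "Hh2"])
def test_formula_parse_rejects_malformed(bad):
    with pytest.raises(ValueError):
        formula_parse(bad)


@st.composite
def formulas(draw):
    counts = {
        e: draw(st.integers(min_value=0, max_value=120)) for e in ("C", "H", "N", "O")
    }
    return Formula(counts)


@settings(derandomize=True, max_examples=200)
@given(formulas())
def test_parse_format_round_trip(f):
    assert formula_parse(formula_format(f)) == f


def test_hill_order():
    assert formula_format(Formula(O=7, H=99, C=58)) == "C58H99O7"
    assert formula_format(Formula(N=1, H=4)) == "H4N"


def test_subtraction_below_zero_is_an_error():
    with pytest.raises(ValueError):
        Formula(C=1) - Formula(C=2)


# -- monoisotopic masses ----------------------------------------------------

@pytest.mark.parametrize(
    "text,mass4",
    [
        ("CH4", 16.0313),
        ("O", 15.9949),
        ("C22H38O3", 350.2821),
        ("C23H42O2", 350.3185),
        ("H8O", 24.0575),
        ("C2", 24.0000),
    ],
)
def test_printed_exact_masses(text, mass4):
    assert round_half_up(monoisotopic_mass(formula_parse(text)), 4) == mass4


def test_empty_formula_mass_is_zero():
    assert monoisotopic_mass(Formula()) == 0.0


@settings(derandomize=True, max_examples=200)
@given(formulas(), formulas())
def test_mass_additivity(a, b):
    assert math.isclose(
        monoisotopic_mass(a + b),
        monoisotopic_mass(a) + monoisotopic_mass(b),
        abs_tol=1e-9,
    )


@settings(derandomize=True, max_examples=50)
@given(formulas())
def test_mass_agrees_with_pyteomics(f):
    """Independent oracle: pyteomics' element table, to sub-ppb agreement."""
    if not len(f):
        return
    assert math.isclose(
        monoisotopic_mass(f),
        pyteomics_mass.calculate_mass(formula=formula_format(f)),
        rel_tol=1e-9,
    )


# -- ion m/z ----------------------------------------------------------------

@pytest.mark.parametrize(
    "formula,mz4",
    [
        ("C57H98O6", 879.7442),  # LLL
        ("C58H98O7", 907.7391),  # LL9M5
        ("C58H102O7", 911.7704),  # OO9M5
        ("C60H98O9", 963.7289),  # tri9M5
        ("C59H104O7", 925.7860),  # OO9D5
        ("C61H96O6", 925.7285),  # OEpEp
        ("C61H102O8", 963.7653),  # L9D5.9D5
    ],
)
def test_protonated_precursors(formula, mz4):
    mz = ion_mz(IonSpec(formula_parse(formula), adduct="H"))
    assert round_half_up(mz, 4) == mz4


def test_fragment_cation_electron_convention():
    inventory = formula_parse("C11H17O")
    off = ion_mz(IonSpec(inventory, adduct=None, electron_correction=False))
    on = ion_mz(IonSpec(inventory, adduct=None, electron_correction=True))
    assert math.isclose(off - on, ELECTRON_MASS, abs_tol=1e-12)
    assert round_half_up(off, 4) == 165.1279
    assert round_half_up(on, 4) == 165.1274


def test_ammonium_adduct():
    # LL9M5 [M+NH4]+ sits 17.0265 Da above [M+H]+
    neutral = formula_parse("C58H98O7")
    mh = ion_mz(IonSpec(neutral, adduct="H"))
    mnh4 = ion_mz(IonSpec(neutral, adduct="NH4"))
    assert math.isclose(mnh4 - mh, 17.02655, abs_tol=1e-4)


def test_negative_charge_rejected():
    with pytest.raises(ValueError):
        IonSpec(formula_parse("CH4"), charge=0)


# -- ppm & resolution -------------------------------------------------------

def test_ppm_error_printed_example():
    assert round_half_up(ppm_error(879.7458, 879.7442), 3) == 1.819


def test_ppm_error_identity_and_sign():
    assert ppm_error(500.0, 500.0) == 0.0
    assert ppm_error(911.7690, 911.7704) == pytest.approx(-1.535, abs=5e-4)


def test_ppm_error_requires_positive_reference():
    with pytest.raises(ValueError):
        ppm_error(100.0, 0.0)


@pytest.mark.parametrize(
    "mz,dm,expected",
    [(925.7285, 0.0575, 16100), (963.7289, 0.0364, 26500), (100.0, 1.0, 100)],
)
def test_required_resolution(mz, dm, expected):
    assert round(required_resolution(mz, dm) / 100) * 100 == expected


def test_required_resolution_rejects_zero_delta():
    with pytest.raises(ValueError):
        required_resolution(100.0, 0.0)


# -- isobar deltas ----------------------------------------------------------

def test_isobar_delta_o_vs_ch4():
    s1, s2, dm = isobar_delta(formula_parse("C22H38O3"), formula_parse("C23H42O2"))
    assert formula_format(s1) == "O"
    assert formula_format(s2) == "CH4"
    assert round_half_up(dm, 4) == -0.0364


def test_isobar_delta_c2_vs_h8o():
    s1, s2, dm = isobar_delta(formula_parse("C59H105O7"), formula_parse("C61H97O6"))
    assert formula_format(s1) == "H8O"
    assert formula_format(s2) == "C2"
    assert round_half_up(dm, 4) == 0.0575


def test_isobar_delta_identity():
    f = formula_parse("C22H38O3")
    s1, s2, dm = isobar_delta(f, f)
    assert len(s1) == 0 and len(s2) == 0 and dm == 0.0


def test_ppm_of_equal_ions_is_zero():
    ion = IonSpec(formula_parse("C58H98O7"))
    assert ppm_error(ion_mz(ion), ion_mz(ion)) == 0.0
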