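"""TAG assembly, canonical naming, precursor m/z and candidate enumeration."""

import itertools
import math

import pytest
from hypothesis import given, settings, strategies as st

from fufatag import (
    build_tag,
    enumerate_candidates,
    find_isobaric_conflicts,
    formula_format,
    monoisotopic_mass,
    parse_tag_name,
    round_half_up,
    tag_precursor_mz,
)
from fufatag.formula import GLYCEROL, WATER
from fufatag.lipids import parse_fa_token


def _fa(blocks, token):
    return blocks.get(token)


def test_build_tag_formula_and_name(blocks):
    tag = build_tag(_fa(blocks, "L"), _fa(blocks, "L"), _fa(blocks, "9M5"))
    assert tag.name == "LL9M5"
    assert formula_format(tag.neutral_formula) == "C58H98O7"
    assert tag.carbon_number == 55
    assert tag.n_fufa == 1


def test_build_tag_order_insensitive(blocks):
    a = build_tag(_fa(blocks, "L"), _fa(blocks, "L"), _fa(blocks, "9M5"))
    b = build_tag(_fa(blocks, "9M5"), _fa(blocks, "L"), _fa(blocks, "L"))
    assert a == b


def test_conventional_fas_sorted_ascending_mass(blocks):
    tag = build_tag(_fa(blocks, "O"), _fa(blocks, "P"), _fa(blocks, "9D5"))
    assert tag.name == "PO9D5"
    tag = build_tag(_fa(blocks, "Ln"), _fa(blocks, "15:0"), _fa(blocks, "9D5"))
    assert tag.name == "15:0-Ln9D5"


def test_carbon_number_excludes_glycerol(blocks):
    tag = build_tag(_fa(blocks, "L"), _fa(blocks, "L"), _fa(blocks, "9D5"))
    assert tag.carbon_number == 56  # 18 + 18 + 20


@pytest.mark.parametrize(
    "name,mz4",
    [
        ("LL9M5", 907.7391),
        ("OO9M5", 911.7704),
        ("OO9D5", 925.7860),
        ("tri9M5", 963.7289),
        ("L9M59M5", 935.7340),
    ],
)
def test_precursor_mz(blocks, name, mz4):
    tag = parse_tag_name(name, blocks)
    assert round_half_up(tag_precursor_mz(tag, "H"), 4) == mz4


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.sampled_from(
    ["P", "Pn", "S", "O", "L", "Ln", "Ep", "Dp", "Dh", "9M5", "9D5", "11D5", "7D5"]
), min_size=3, max_size=3))
def test_tag_atom_conservation(tokens):
    """TAG atoms = three FAs + glycerol - 3 waters, element-wise."""
    fas = [parse_fa_token(t) for t in tokens]
    tag = build_tag(*fas)
    expected = GLYCEROL
    for fa in fas:
        expected = expected + fa.neutral_formula
    expected = expected - 3 * WATER
    assert tag.neutral_formula == expected
    assert math.isclose(
        monoisotopic_mass(tag.neutral_formula),
        sum(fa.neutral_mass for fa in fas) + monoisotopic_mass(GLYCEROL)
        - 3 * monoisotopic_mass(WATER),
        abs_tol=1e-9,
    )


@pytest.mark.parametrize(
    "name",
    ["LL9M5", "LO9M5", "OO9M5", "LL9D5", "LO9D5", "PLn11D5", "OO9D5",
     "LO11D5", "tri9M5", "L9D59D5", "EpEp9M5", "EpEp11D3", "EpDh11D5",
     "PL9D3", "LO9D3", "15:0-Ln9D5", "17:0-L9D5", "PnL9D5", "OS9D5"],
)
def test_tag_name_round_trip(blocks, name):
    """Canonical TAG names parse and re-format to themselves."""
    assert parse_tag_name(name, blocks).name == name


def test_noncanonical_order_normalizes():
    """Names written higher-mass-first normalize to ascending order."""
    assert parse_tag_name("OL9D5").name == "LO9D5"
    assert parse_tag_name("9M5LL").name == "LL9M5"


def test_unparseable_name_raises(blocks):
    with pytest.raises(ValueError):
        parse_tag_name("XYZ", blocks)
    with pytest.raises(ValueError):
        parse_tag_name("LL", blocks)  # only two fatty acids


def test_protonated_formula_matches_published_list(blocks):
    published = {
        "PL9D3": "C55H97O7",
        "LL9M5": "C58H99O7",
        "LO9D5": "C59H103O7",
        "PLn11D5": "C59H103O7",
        "tri9M5": "C60H99O9",
        "L9D59D5": "C61H103O8",
        "EpDh11D5": "C67H103O7",
    }
    from fufatag.formula import PROTON

    for name, formula in published.items():
        tag = parse_tag_name(name, blocks)
        assert formula_format(tag.neutral_formula + PROTON) == formula


# -- enumeration ------------------------------------------------------------

def test_enumeration_count_closed_form(core_blocks):
    db = enumerate_candidates(core_blocks, 1)
    f, k = len(core_blocks.furan), len(core_blocks.conventional)
    assert len(db) == f * k * (k + 1) // 2 == 168
    # oracle: exhaustive multiset generation
    brute = {
        tuple(sorted((fu.token,) + tuple(c.token for c in convs)))
        for fu in core_blocks.furan
        for convs in itertools.combinations_with_replacement(core_blocks.conventional, 2)
    }
    assert {c.tag.token_multiset for c in db} == brute


def test_enumeration_single_pair(blocks):
    from fufatag.lipids import BuildingBlockSet

    tiny = BuildingBlockSet((blocks.get("L"),), (blocks.get("9M5"),))
    db = enumerate_candidates(tiny, 1)
    assert len(db) == 1
    db2 = enumerate_candidates(tiny, 2)
    assert [c.name for c in db2] == ["L9M59M5"]
    assert round_half_up(db2.candidates[0].mz_mh, 4) == 935.7340


def test_enumeration_requires_blocks(blocks):
    from fufatag.lipids import BuildingBlockSet

    empty = BuildingBlockSet((), ())
    with pytest.raises(ValueError):
        enumerate_candidates(empty, 1)


def test_database_deduplicated_and_sorted(screening_db):
    mzs = [c.mz_mh for c in screening_db]
    assert mzs == sorted(mzs)
    keys = [c.tag.token_multiset for c in screening_db]
    assert len(keys) == len(set(keys))


def test_by_precursor_window(screening_db):
    hits = screening_db.by_precursor(921.7543, tol_ppm=4.0)
    assert any(c.name == "LL9D5" for c in hits)
    assert all(abs(c.mz_mh - 921.7543) / 921.7543 * 1e6 <= 4.0 for c in hits)


# -- isobaric conflicts -----------------------------------------------------

def test_isobar_conflicts_resolved_at_high_resolution(blocks):
    from fufatag.lipids import BuildingBlockSet

    fufa_db = enumerate_candidates(
        BuildingBlockSet((blocks.get("O"),), (blocks.get("9D5"),)), 1
    )
    conv_db = enumerate_candidates(
        BuildingBlockSet((blocks.get("O"), blocks.get("Ep")), ()), 0
    )
    # OO9D5 vs OEpEp: dm 0.0575 > 925.7/70000, resolvable at R = 70,000
    assert find_isobaric_conflicts(fufa_db, conv_db, 70_000) == []
    # at very low resolving power the pair collides, labeled by formula class
    conflicts = find_isobaric_conflicts(fufa_db, conv_db, 10_000)
    pair = [c for c in conflicts if c.name_b == "OEpEp"]
    assert pair and pair[0].label == "H8O vs C2"
    assert round_half_up(pair[0].delta_m, 4) == 0.0575


def test_o_vs_ch4_conflict_class(blocks):
    from fufatag.lipids import BuildingBlockSet

    a = enumerate_candidates(BuildingBlockSet((), (blocks.get("9M5"),)), 3)
    b = enumerate_candidates(
        BuildingBlockSet((blocks.get("L"),), (blocks.get("9D5"),)), 2
    )
    conflicts = find_isobaric_conflicts(a, b, 10_000)
    assert conflicts and conflicts[0].label == "O vs CH4"
    assert round_half_up(conflicts[0].delta_m, 4) == -0.0364


def test_identical_composition_is_not_a_conflict(screening_db):
    assert all(
        c.name_a != c.name_b
        for c in find_isobaric_conflicts(screening_db, screening_db, 1_000)
    )
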