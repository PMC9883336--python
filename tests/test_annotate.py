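"""The identification flow: filter steps, tiers, dedup, reporting math."""

import numpy as np
import pandas as pd
import pytest

from fufatag import (
    Ms2Spectrum,
    SimulationParams,
    annotate_run,
    annotate_spectra,
    estimate_contents,
    parse_tag_name,
    relative_abundances,
    screen_spectrum,
    simulate_spectrum,
)

NOISE_FREE = SimulationParams(sigma_ppm=0.0, decoy_peaks=0, seed=0)


def _ll9m5_spectrum(drop_diacyl=False):
    mz = [907.7391, 627.4989, 599.5039, 291.2324, 165.1280, 109.0653]
    intensity = [10.0, 40.0, 40.0, 100.0, 12.0, 10.0]
    if drop_diacyl:
        mz, intensity = mz[:1] + mz[3:], intensity[:1] + intensity[3:]
    return Ms2Spectrum("ll9m5", 907.7391, np.array(mz), np.array(intensity))


def test_full_annotation_of_ll9m5(screening_db):
    results = screen_spectrum(_ll9m5_spectrum(), screening_db, tol_ppm=4.0)
    assert [r.name for r in results] == ["LL9M5"]
    res = results[0]
    assert res.tier == "FULL"
    assert res.carbon_number == 55
    assert res.intensity == 100.0  # the [FCO]+ peak height
    assert {m.ion_type for m in res.matches} >= {
        "fco", "furan_core", "mclafferty", "diacyl", "precursor_H"
    }


def test_fufa_only_when_diacyl_ions_missing(screening_db):
    results = screen_spectrum(_ll9m5_spectrum(drop_diacyl=True), screening_db)
    assert len(results) == 1
    assert results[0].tier == "FUFA_ONLY"
    assert results[0].name == "XY9M5"
    assert all(m.ion_type != "diacyl" for m in results[0].matches)


def test_fufa_free_spectrum_yields_nothing(screening_db, blocks):
    spec = simulate_spectrum(parse_tag_name("LLL", blocks), NOISE_FREE)
    assert screen_spectrum(spec, screening_db) == []


def test_full_annotations_are_sound(screening_db, blocks):
    """Matched ions of a FULL annotation recompute from the annotated name."""
    from fufatag import fragment_set

    results = screen_spectrum(_ll9m5_spectrum(), screening_db)
    res = results[0]
    fs = fragment_set(parse_tag_name(res.name, blocks))
    predicted = {round(i.mz, 4) for i in fs.diacyl + fs.fco + fs.furan_core + fs.mclafferty}
    predicted.add(round(fs.precursor_mh, 4))
    for match in res.matches:
        assert round(match.mz_calc, 4) in predicted


def test_precursor_isomers_resolved_by_fco(screening_db, blocks):
    """LO9D5 and PLn11D5 share [M+H]+; the [FCO]+/core pick the right one."""
    for name in ("LO9D5", "PLn11D5"):
        spec = simulate_spectrum(parse_tag_name(name, blocks), NOISE_FREE)
        results = screen_spectrum(spec, screening_db)
        assert [r.name for r in results] == [name]


def test_base_peak_strict_mode(screening_db):
    spec = _ll9m5_spectrum()
    assert screen_spectrum(spec, screening_db, require_base_peak=True)
    # make a diacyl ion the base peak: strict mode now rejects
    demoted = Ms2Spectrum(
        "x", 907.7391, spec.mz.copy(),
        np.where(spec.mz == 599.5039, 500.0, spec.intensity),
    )
    assert screen_spectrum(demoted, screening_db, require_base_peak=True) == []
    assert screen_spectrum(demoted, screening_db, require_base_peak=False)


def test_shrinking_tolerance_never_adds_annotations(screening_db, mushroom_fixture):
    previous = None
    for tol in [4.0, 2.0, 1.0, 0.5, 0.1]:
        names = {
            r.name for spec in mushroom_fixture
            for r in screen_spectrum(spec, screening_db, tol_ppm=tol)
        }
        if previous is not None:
            assert names <= previous
        previous = names


def test_annotate_run_dedup(screening_db, mushroom_fixture):
    table = annotate_run(mushroom_fixture, screening_db)
    doubled = annotate_run(mushroom_fixture * 2, screening_db)
    assert len(table) == len(doubled) == 18
    assert sorted(table.name) == sorted(doubled.name)


def test_annotate_run_empty(screening_db):
    assert len(annotate_run([], screening_db)) == 0


def test_dedup_keeps_highest_fco_intensity(screening_db):
    bright = _ll9m5_spectrum()
    dim = Ms2Spectrum(
        "dim", 907.7391, bright.mz.copy(), bright.intensity * 0.5
    )
    results = annotate_spectra([dim, bright], screening_db)
    assert len(results) == 1
    assert results[0].spectrum_id == "ll9m5"


# -- relative abundances ----------------------------------------------------

def _toy_table(intensities):
    return pd.DataFrame(
        {
            "name": list(intensities),
            "intensity": list(intensities.values()),
            "n_fufa": [1] * len(intensities),
        }
    )


def test_identical_replicates_have_zero_rsd():
    table = _toy_table({"LL9D5": 1000.0, "LO9D5": 500.0})
    out = relative_abundances([table, table.copy(), table.copy()])
    assert np.allclose(out["rsd_pct"], 0.0)
    ref_row = out[out.name == "LL9D5"].iloc[0]
    assert ref_row["rel_pct_run1"] == 100.0
    other = out[out.name == "LO9D5"].iloc[0]
    assert other["rel_pct_run1"] == 50.0


def test_missing_reference_is_flagged_not_dropped():
    run1 = _toy_table({"LL9D5": 1000.0, "LO9D5": 500.0})
    run2 = _toy_table({"LO9D5": 450.0})
    out = relative_abundances([run1, run2])
    assert out[out.name == "LO9D5"]["flagged"].item()
    assert len(out) == 2


def test_replicate_noise_gives_plausible_rsd():
    """Multiplicative noise of CV 0.2 puts FuFA-TAG RSDs in the tens of %."""
    rng = np.random.default_rng(7)
    base = {"LL9D5": 66800.0, "LO9D5": 29100.0, "PO9D5": 9550.0, "OO9M5": 121.0}
    tables = [
        _toy_table({k: v * rng.lognormal(0.0, 0.2) for k, v in base.items()})
        for _ in range(3)
    ]
    out = relative_abundances(tables)
    rsd = out.loc[out.name != out["reference"], "rsd_pct"]
    assert 3.0 < rsd.median() < 60.0


def test_relative_abundances_needs_two_tables():
    with pytest.raises(ValueError):
        relative_abundances([_toy_table({"A": 1.0})])


# -- content estimation -----------------------------------------------------

def test_contents_proportional_split():
    table = _toy_table({"A9D5": 3.0, "B9D5": 1.0})
    out = estimate_contents(table, total_fufa_content=4.0)
    assert dict(zip(out.name, out.content)) == {"A9D5": 3.0, "B9D5": 1.0}


def test_contents_conserve_total(screening_db, mushroom_fixture):
    table = annotate_run(mushroom_fixture, screening_db)
    out = estimate_contents(table, total_fufa_content=33.0)
    assert out.content.sum() == pytest.approx(33.0, rel=1e-9)


def test_minimum_content_converts_to_lipid_basis():
    table = _toy_table({"A9D5": 0.1, "B9D5": 32.9})
    out = estimate_contents(
        table, total_fufa_content=33.0, basis="dry_weight", lipid_fraction=0.05
    )
    assert out.attrs["minimum_content"] == pytest.approx(0.1)
    assert out.attrs["minimum_content_per_lipid"] == pytest.approx(2.0)


def test_single_tag_receives_everything():
    out = estimate_contents(_toy_table({"A9D5": 7.0}), total_fufa_content=12.5)
    assert out.content.item() == pytest.approx(12.5)


def test_zero_total_intensity_rejected():
    with pytest.raises(ValueError):
        estimate_contents(_toy_table({"A9D5": 0.0}), total_fufa_content=1.0)
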