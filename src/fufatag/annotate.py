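"""The MS2 identification flow for FuFA-containing TAGs, plus run reporting.

Screening steps per spectrum (all matching at a configurable ppm tolerance,
default 4 ppm):

1. precursor  — candidates whose [M+H]+ (optionally [M+NH4]+) lies within
                tolerance of the declared precursor m/z; an in-spectrum
                precursor peak, when present, is recorded as corroborating
                evidence.
2. [FCO]+     — the FuFA acylium must be present; this narrows the FuFA to
                a positional-isomer pair.
3. furan core — selects the concrete FuFA within the pair; the McLafferty
                ion must additionally be consistent with the methylation
                degree.  Multi-FuFA candidates need the trio once per
                distinct FuFA species.
4. diacyl     — [M-RCOO]+ matches assign the conventional fatty acids.

Candidates that share a precursor formula (true isomers such as OL9D5 vs
PLn11D5) are arbitrated by diacyl support: the candidate(s) explaining the
most distinct [M-RCOO]+ peaks win (ties are flagged AMBIGUOUS).  When no
candidate in a group has any diacyl support the group collapses to a single
FUFA_ONLY annotation whose name carries the "XY" prefix — the FuFA is
identified, the conventional fatty acids are not.

The reported intensity of an annotation is the intensity of the matched
[FCO]+ peak (the base peak of clean FuFA-TAG spectra).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .formula import PROTON, formula_format, ppm_error
from .fragments import FragmentIon, FragmentSet
from .spectra import Ms2Spectrum, Peak, base_peak, match_peak
from .tags import Candidate, CandidateDatabase, TagComposition

__all__ = [
    "IonMatch",
    "AnnotationResult",
    "screen_spectrum",
    "annotate_run",
    "annotation_table",
    "relative_abundances",
    "estimate_contents",
]

logger = logging.getLogger(__name__)

TIER_FULL = "FULL"
TIER_FUFA_ONLY = "FUFA_ONLY"


@dataclass(frozen=True)
class IonMatch:
    ion_type: str
    label: str
    mz_calc: float
    mz_obs: float
    ppm: float
    intensity: float


@dataclass
class AnnotationResult:
    """One identified FuFA-containing TAG in one spectrum."""

    name: str
    tier: str  # FULL | FUFA_ONLY
    tag: TagComposition | None  # None only conceptually; kept for evidence
    formula_mh: str
    mz_calc: float
    carbon_number: int
    n_fufa: int
    fufa_tokens: tuple[str, ...]
    spectrum_id: str
    precursor_mz_obs: float
    precursor_ppm: float
    rt_min: float | None
    intensity: float  # matched [FCO]+ peak intensity
    matches: tuple[IonMatch, ...]
    flags: tuple[str, ...] = ()  # e.g. AMBIGUOUS; always positional-unresolved

    @property
    def n_diacyl_matches(self) -> int:
        return sum(1 for m in self.matches if m.ion_type == "diacyl")


@dataclass
class _CandidateMatch:
    candidate: Candidate
    matches: list[IonMatch]
    diacyl_count: int
    fco_intensity: float

    @property
    def support(self) -> tuple[int, int]:
        """Ranking key: diacyl assignments first, then distinct explained peaks.

        The second component separates compositions whose predicted ions
        collapse onto fewer spectrum peaks (e.g. two FuFA moieties sharing
        one furan-core m/z) from those explaining every diagnostic peak.
        """
        distinct = len(
            {
                round(m.mz_obs, 6)
                for m in self.matches
                if m.ion_type in ("fco", "furan_core", "mclafferty", "diacyl")
            }
        )
        return (self.diacyl_count, distinct)


def _match_ion(
    spectrum: Ms2Spectrum, ion: FragmentIon, tol_ppm: float
) -> IonMatch | None:
    peak = match_peak(spectrum, ion.mz, tol_ppm)
    if peak is None:
        return None
    return IonMatch(
        ion_type=ion.ion_type,
        label=ion.label,
        mz_calc=ion.mz,
        mz_obs=peak.mz,
        ppm=ppm_error(peak.mz, ion.mz),
        intensity=peak.intensity,
    )


def _evaluate_candidate(
    spectrum: Ms2Spectrum,
    candidate: Candidate,
    tol_ppm: float,
    require_base_peak: bool,
) -> _CandidateMatch | None:
    """Run filter steps 2-4 for one precursor-matched candidate."""
    fs: FragmentSet = candidate.fragments
    matches: list[IonMatch] = []
    fco_intensity = 0.0

    # steps 2-3: the diagnostic trio, once per distinct FuFA species
    trio = {"fco": fs.fco, "furan_core": fs.furan_core, "mclafferty": fs.mclafferty}
    for step, ions in trio.items():
        for ion in ions:
            hit = _match_ion(spectrum, ion, tol_ppm)
            if hit is None:
                logger.debug(
                    "spectrum=%s candidate=%s rejected=%s (%s m/z %.4f absent)",
                    spectrum.spectrum_id,
                    candidate.name,
                    step,
                    ion.label,
                    ion.mz,
                )
                return None
            matches.append(hit)
            if step == "fco":
                fco_intensity = max(fco_intensity, hit.intensity)

    if require_base_peak:
        bp = base_peak(spectrum)
        fco_obs = {m.mz_obs for m in matches if m.ion_type == "fco"}
        if bp.mz not in fco_obs:
            logger.debug(
                "spectrum=%s candidate=%s rejected=base_peak ([FCO]+ is not the base peak)",
                spectrum.spectrum_id,
                candidate.name,
            )
            return None

    # step 4: diacyl ions (conventional-FA assignment)
    diacyl_count = 0
    for ion in fs.diacyl:
        hit = _match_ion(spectrum, ion, tol_ppm)
        if hit is not None:
            matches.append(hit)
            diacyl_count += 1

    # corroborating in-spectrum precursor peak
    precursor_peak = match_peak(spectrum, fs.precursor_mh, tol_ppm)
    if precursor_peak is not None:
        matches.append(
            IonMatch(
                ion_type="precursor_H",
                label="[M+H]+",
                mz_calc=fs.precursor_mh,
                mz_obs=precursor_peak.mz,
                ppm=ppm_error(precursor_peak.mz, fs.precursor_mh),
                intensity=precursor_peak.intensity,
            )
        )

    return _CandidateMatch(candidate, matches, diacyl_count, fco_intensity)


def _result_from(
    spectrum: Ms2Spectrum,
    cm: _CandidateMatch,
    tier: str,
    flags: tuple[str, ...],
) -> AnnotationResult:
    tag = cm.candidate.tag
    fufa_tokens = tuple(dict.fromkeys(fa.token for fa in tag.fufas))
    if tier == TIER_FUFA_ONLY:
        prefix = "XY" if tag.n_fufa == 1 else "X" if tag.n_fufa == 2 else ""
        name = prefix + "".join(fa.token for fa in tag.fufas)
        # conventional FAs are unassigned: drop their diacyl/acylium evidence
        matches = tuple(m for m in cm.matches if m.ion_type != "diacyl")
    else:
        name = tag.name
        matches = tuple(cm.matches)
    return AnnotationResult(
        name=name,
        tier=tier,
        tag=tag,
        formula_mh=formula_format(tag.neutral_formula + PROTON),
        mz_calc=cm.candidate.mz_mh,
        carbon_number=tag.carbon_number,
        n_fufa=tag.n_fufa,
        fufa_tokens=fufa_tokens,
        spectrum_id=spectrum.spectrum_id,
        precursor_mz_obs=spectrum.precursor_mz,
        precursor_ppm=ppm_error(spectrum.precursor_mz, cm.candidate.mz_mh),
        rt_min=spectrum.rt_min,
        intensity=cm.fco_intensity,
        matches=matches,
        flags=flags,
    )


def screen_spectrum(
    spectrum: Ms2Spectrum,
    db: CandidateDatabase,
    tol_ppm: float = 4.0,
    require_base_peak: bool = False,
    adducts: Sequence[str] = ("H",),
) -> list[AnnotationResult]:
    """Screen one MS2 spectrum against a candidate database.

    Returns zero or more annotations; a spectrum without the diagnostic
    FuFA ion set simply yields an empty list.
    """
    candidates = db.by_precursor(spectrum.precursor_mz, tol_ppm, adducts)
    survivors: list[_CandidateMatch] = []
    for cand in candidates:
        cm = _evaluate_candidate(spectrum, cand, tol_ppm, require_base_peak)
        if cm is not None:
            survivors.append(cm)
        # rejection reasons are logged inside _evaluate_candidate
    if not survivors:
        return []

    # group true isomers (same protonated formula -> same precursor window)
    groups: dict[str, list[_CandidateMatch]] = {}
    for cm in survivors:
        key = formula_format(cm.candidate.tag.neutral_formula)
        groups.setdefault(key, []).append(cm)

    results: list[AnnotationResult] = []
    for group in groups.values():
        max_diacyl = max(cm.diacyl_count for cm in group)
        if max_diacyl > 0:
            best_support = max(cm.support for cm in group)
            winners = [cm for cm in group if cm.support == best_support]
            flags = ("AMBIGUOUS",) if len(winners) > 1 else ()
            for cm in winners:
                results.append(_result_from(spectrum, cm, TIER_FULL, flags))
        else:
            # conventional FAs unresolved: one FUFA_ONLY result per distinct
            # FuFA multiset (candidates differing only in the conventional
            # pair collapse onto the same XY name)
            by_fufa: dict[tuple[str, ...], _CandidateMatch] = {}
            for cm in group:
                key = tuple(sorted(fa.token for fa in cm.candidate.tag.fufas))
                by_fufa.setdefault(key, cm)
            flags = ("AMBIGUOUS",) if len(by_fufa) > 1 else ()
            for cm in by_fufa.values():
                results.append(_result_from(spectrum, cm, TIER_FUFA_ONLY, flags))
    results.sort(key=lambda r: (-r.intensity, r.name))
    return results


def annotate_spectra(
    spectra: Iterable[Ms2Spectrum],
    db: CandidateDatabase,
    tol_ppm: float = 4.0,
    require_base_peak: bool = False,
    adducts: Sequence[str] = ("H",),
) -> list[AnnotationResult]:
    """Screen a run and deduplicate by TAG name (highest [FCO]+ intensity wins)."""
    best: dict[str, AnnotationResult] = {}
    for spectrum in spectra:
        for result in screen_spectrum(spectrum, db, tol_ppm, require_base_peak, adducts):
            held = best.get(result.name)
            if held is None or result.intensity > held.intensity:
                best[result.name] = result
    return sorted(best.values(), key=lambda r: (r.rt_min is None, r.rt_min, r.name))


def annotation_table(results: Sequence[AnnotationResult]) -> pd.DataFrame:
    """Tabulate annotations with one row per TAG (report-table shape)."""
    rows = []
    for res in results:
        frag_str = ";".join(
            f"{m.ion_type}:{m.mz_obs:.4f}"
            for m in res.matches
            if m.ion_type in ("mclafferty", "furan_core", "fco", "diacyl")
        )
        rows.append(
            {
                "name": res.name,
                "tier": res.tier,
                "rt_min": res.rt_min,
                "formula_mh": res.formula_mh,
                "mz_mh_obs": round(res.precursor_mz_obs, 4),
                "mz_mh_calc": round(res.mz_calc, 4),
                "precursor_ppm": round(res.precursor_ppm, 3),
                "fufa": ";".join(res.fufa_tokens),
                "carbon_number": res.carbon_number,
                "intensity": res.intensity,
                "fragments": frag_str,
                "flags": ";".join(res.flags),
                "spectrum_id": res.spectrum_id,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "name", "tier", "rt_min", "formula_mh", "mz_mh_obs", "mz_mh_calc",
            "precursor_ppm", "fufa", "carbon_number", "intensity", "fragments",
            "flags", "spectrum_id",
        ],
    )
    table.attrs["results"] = list(results)
    return table


def annotate_run(
    spectra: Iterable[Ms2Spectrum],
    db: CandidateDatabase,
    tol_ppm: float = 4.0,
    require_base_peak: bool = False,
    adducts: Sequence[str] = ("H",),
) -> pd.DataFrame:
    """Screen all spectra of a run into a deduplicated annotation table."""
    return annotation_table(
        annotate_spectra(spectra, db, tol_ppm, require_base_peak, adducts)
    )


# ---------------------------------------------------------------------------
# Reporting computations
# ---------------------------------------------------------------------------

def relative_abundances(
    tables: Sequence[pd.DataFrame],
    class_column: str | None = "n_fufa",
) -> pd.DataFrame:
    """Replicate-run intensities as % of the first run's most abundant TAG.

    For each class (FuFA-containing vs conventional, when ``class_column``
    is available) the most abundant TAG of run 1 defines the reference; in
    every run each TAG's intensity is expressed as a percentage of that
    run's intensity of the reference TAG.  The per-TAG relative standard
    deviation across runs quantifies reproducibility.  Runs missing the
    reference TAG are flagged, not dropped.
    """
    if len(tables) < 2:
        raise ValueError("need at least two replicate tables")
    for t in tables:
        if "name" not in t.columns or "intensity" not in t.columns:
            raise ValueError("tables need 'name' and 'intensity' columns")

    def tag_class(row: pd.Series) -> str:
        if class_column and class_column in row and not pd.isna(row[class_column]):
            return "fufa" if row[class_column] > 0 else "conventional"
        return "all"

    first = tables[0]
    classes = first.apply(tag_class, axis=1)
    references: dict[str, str] = {}
    for cls in classes.unique():
        sub = first[classes == cls]
        references[cls] = sub.loc[sub["intensity"].idxmax(), "name"]

    records: list[dict] = []
    for run_index, table in enumerate(tables, start=1):
        lookup = table.set_index("name")["intensity"]
        for _, row in table.iterrows():
            cls = tag_class(row)
            ref_name = references.get(cls, references.get("all"))
            flagged = ref_name not in lookup.index
            rel = np.nan if flagged else row["intensity"] / lookup[ref_name] * 100.0
            records.append(
                {
                    "name": row["name"],
                    "class": cls,
                    "run": run_index,
                    "relative_pct": rel,
                    "reference": ref_name,
                    "flagged": flagged,
                }
            )
    long = pd.DataFrame(records)
    wide = long.pivot_table(index=["name", "class"], columns="run", values="relative_pct")
    wide.columns = [f"rel_pct_run{c}" for c in wide.columns]
    wide["mean_pct"] = wide.mean(axis=1)
    std = wide[[c for c in wide.columns if c.startswith("rel_pct_")]].std(axis=1, ddof=1)
    wide["rsd_pct"] = std / wide["mean_pct"] * 100.0
    wide["flagged"] = long.groupby(["name", "class"])["flagged"].any()
    wide = wide.reset_index()
    wide["reference"] = wide["class"].map(references)
    return wide


def estimate_contents(
    table: pd.DataFrame,
    total_fufa_content: float,
    basis: str = "dry_weight",
    lipid_fraction: float | None = None,
) -> pd.DataFrame:
    """Allocate a known total FuFA-TAG content over annotations by intensity.

    ``content_i = total * I_i / sum(I)`` — assumes similar MS2 response of
    all FuFA-containing TAGs.  When ``basis`` is ``"dry_weight"`` and a
    ``lipid_fraction`` is given, a per-lipid column (content divided by the
    fraction) is added; the smallest allocated content is the indirect
    detection-limit estimate and is stored in ``df.attrs``.
    """
    if total_fufa_content <= 0:
        raise ValueError("total content must be positive")
    if basis not in ("dry_weight", "lipid"):
        raise ValueError("basis must be 'dry_weight' or 'lipid'")
    intensities = table["intensity"].astype(float)
    total_intensity = intensities.sum()
    if total_intensity <= 0:
        raise ValueError("total intensity is zero; cannot allocate contents")
    out = table[["name", "intensity"]].copy()
    out["content"] = total_fufa_content * intensities / total_intensity
    out["basis"] = basis
    if basis == "dry_weight" and lipid_fraction is not None:
        if lipid_fraction <= 0:
            raise ValueError("lipid_fraction must be positive")
        out["content_per_lipid"] = out["content"] / lipid_fraction
    out.attrs["minimum_content"] = float(out["content"].min())
    if "content_per_lipid" in out.columns:
        out.attrs["minimum_content_per_lipid"] = float(out["content_per_lipid"].min())
    return out
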