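"""Diagnostic MS2 fragment-ion prediction for TAGs.

Positive-mode TAG spectra are dominated by diacyl [M-RCOO]+ ions (loss of
one fatty acid as RCOOH from [M+H]+).  FuFA-containing TAGs additionally
show three FuFA-diagnostic ions:

* [FCO]+     — the FuFA acylium (acid minus OH), the spectrum base peak;
               each [FCO]+ mass is shared by a pair of positional isomers
               (e.g. 9M5/11M3).
* furan core — the allylic [CH2-(methylated furan)-alkyl]+ ion,
               C_n H_(2n-5) O with n = 5 + ring methyls + alkyl length;
               it differs between the two members of an [FCO]+ pair and
               therefore pins down the concrete FuFA.
* McLafferty — the rearrangement product; depends only on the methylation
               degree (M -> C7H9O at m/z 109.065, D -> C8H11O at 123.081),
               independent of both chain lengths.

Conventional-FA acylium ions are predicted for completeness but carry no
weight in identification.  The "+74 u / +128 u" satellite series is exposed
only as unit-mass report labels (its elemental composition is not modeled)
and is never used for filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .formula import Formula, IonSpec, PROTON, formula_format, ion_mz, monoisotopic_mass
from .lipids import FattyAcid, FuFA, acyl_cation_formula, is_fufa
from .tags import TagComposition, tag_precursor_mz

__all__ = [
    "FragmentIon",
    "FragmentSet",
    "diacyl_ions",
    "acylium_ion",
    "fco_ion",
    "furan_core_ion",
    "mclafferty_ion",
    "fragment_set",
    "satellite_labels",
]

MCLAFFERTY_FORMULA = {"M": Formula(C=7, H=9, O=1), "D": Formula(C=8, H=11, O=1)}


@dataclass(frozen=True)
class FragmentIon:
    """One predicted ion of a TAG's diagnostic set."""

    ion_type: str  # precursor_H | precursor_NH4 | diacyl | acylium | fco | furan_core | mclafferty
    label: str
    formula: Formula
    mz: float
    fufa: str | None = None  # FuFA token this ion is diagnostic for
    leaving: str | None = None  # diacyl ions: token of the FA lost as RCOOH
    remaining: tuple[str, ...] | None = None  # diacyl ions: the retained pair


def _cation_mz(formula: Formula, electron_correction: bool) -> float:
    return ion_mz(IonSpec(formula, adduct=None, electron_correction=electron_correction))


def diacyl_ions(
    tag: TagComposition, electron_correction: bool = False
) -> list[FragmentIon]:
    """[M-RCOO]+ ions: one per distinct leaving fatty acid.

    m/z = protonated precursor - neutral mass of the leaving acid, so mass is
    conserved exactly.  A TAG with three identical FAs yields one ion, two or
    three distinct FAs yield two or three ions.
    """
    precursor = tag_precursor_mz(tag, "H", electron_correction)
    protonated = tag.neutral_formula + PROTON
    seen: dict[tuple[str, ...], FragmentIon] = {}
    for i, leaving in enumerate(tag.fatty_acids):
        # fatty_acids is already in canonical order (conventional FAs
        # ascending, FuFAs last), so the retained-pair label reads naturally
        remaining = tuple(
            fa.token for j, fa in enumerate(tag.fatty_acids) if j != i
        )
        if remaining in seen:
            continue
        formula = protonated - leaving.neutral_formula
        seen[remaining] = FragmentIon(
            ion_type="diacyl",
            label=f"[{''.join(remaining)}]+",
            formula=formula,
            mz=precursor - monoisotopic_mass(leaving.neutral_formula),
            leaving=leaving.token,
            remaining=remaining,
        )
    return list(seen.values())


def acylium_ion(fa: FattyAcid, electron_correction: bool = False) -> FragmentIon:
    """[RCO]+ for any fatty acid ([FCO]+ when the acid is a FuFA)."""
    formula = acyl_cation_formula(fa)
    return FragmentIon(
        ion_type="fco" if is_fufa(fa) else "acylium",
        label=f"[{fa.token}CO]+" if is_fufa(fa) else f"[{fa.token}-CO]+",
        formula=formula,
        mz=_cation_mz(formula, electron_correction),
        fufa=fa.token if is_fufa(fa) else None,
    )


def fco_ion(fufa: FuFA, electron_correction: bool = False) -> FragmentIon:
    return acylium_ion(fufa, electron_correction)


def furan_core_ion(fufa: FuFA, electron_correction: bool = False) -> FragmentIon:
    """Allylic furan-core ion; resolves the [FCO]+ positional-isomer pair."""
    n = 5 + fufa.methyl_count + fufa.alkyl_len  # CH2 + 4 ring C + methyls + alkyl
    formula = Formula(C=n, H=2 * n - 5, O=1)
    return FragmentIon(
        ion_type="furan_core",
        label=f"core({fufa.token})",
        formula=formula,
        mz=_cation_mz(formula, electron_correction),
        fufa=fufa.token,
    )


def mclafferty_ion(fufa: FuFA, electron_correction: bool = False) -> FragmentIon:
    """McLafferty rearrangement ion; a hard rule per methylation degree."""
    formula = MCLAFFERTY_FORMULA[fufa.methylation]
    return FragmentIon(
        ion_type="mclafferty",
        label=f"McL({fufa.methylation})",
        formula=formula,
        mz=_cation_mz(formula, electron_correction),
        fufa=fufa.token,
    )


def satellite_labels(fufa: FuFA) -> tuple[int, int]:
    """Unit-mass +74/+128 satellite annotations relative to [FCO]+ (labels only)."""
    nominal = int(round(monoisotopic_mass(acyl_cation_formula(fufa))))
    return nominal + 74, nominal + 128


@dataclass(frozen=True)
class FragmentSet:
    """The full predicted diagnostic ion table for one TAG."""

    tag: TagComposition
    precursor_mh: float
    precursor_mnh4: float
    diacyl: tuple[FragmentIon, ...]
    acylium: tuple[FragmentIon, ...]  # conventional FAs only (subordinate role)
    fco: tuple[FragmentIon, ...]  # one per distinct FuFA species
    furan_core: tuple[FragmentIon, ...]
    mclafferty: tuple[FragmentIon, ...]

    @property
    def all_ions(self) -> tuple[FragmentIon, ...]:
        return self.diacyl + self.acylium + self.fco + self.furan_core + self.mclafferty

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "tag": self.tag.name,
                "ion_type": "precursor_H",
                "label": "[M+H]+",
                "formula": formula_format(self.tag.neutral_formula + PROTON),
                "mz": round(self.precursor_mh, 4),
            },
            {
                "tag": self.tag.name,
                "ion_type": "precursor_NH4",
                "label": "[M+NH4]+",
                "formula": formula_format(self.tag.neutral_formula + Formula(N=1, H=4)),
                "mz": round(self.precursor_mnh4, 4),
            },
        ]
        for ion in self.all_ions:
            rows.append(
                {
                    "tag": self.tag.name,
                    "ion_type": ion.ion_type,
                    "label": ion.label,
                    "formula": formula_format(ion.formula),
                    "mz": round(ion.mz, 4),
                }
            )
        return pd.DataFrame(rows)


def fragment_set(tag: TagComposition, electron_correction: bool = False) -> FragmentSet:
    """Assemble precursors, diacyl ions and the per-FuFA diagnostic trio."""
    distinct_fufas: dict[str, FuFA] = {fa.token: fa for fa in tag.fufas}
    distinct_conv: dict[str, FattyAcid] = {
        fa.token: fa for fa in tag.fatty_acids if not is_fufa(fa)
    }
    return FragmentSet(
        tag=tag,
        precursor_mh=tag_precursor_mz(tag, "H", electron_correction),
        precursor_mnh4=tag_precursor_mz(tag, "NH4", electron_correction),
        diacyl=tuple(diacyl_ions(tag, electron_correction)),
        acylium=tuple(
            acylium_ion(fa, electron_correction) for fa in distinct_conv.values()
        ),
        fco=tuple(fco_ion(fu, electron_correction) for fu in distinct_fufas.values()),
        furan_core=tuple(
            furan_core_ion(fu, electron_correction) for fu in distinct_fufas.values()
        ),
        mclafferty=tuple(
            mclafferty_ion(fu, electron_correction) for fu in distinct_fufas.values()
        ),
    )


def export_transition_list(
    fragment_sets: Sequence[FragmentSet], path: str | Path
) -> None:
    """Write fragment sets as a tab-separated inclusion/transition list."""
    pd.concat([fs.to_dataframe() for fs in fragment_sets], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )
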