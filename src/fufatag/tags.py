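"""TAG composition construction, canonical naming and candidate enumeration.

A triacylglycerol (TAG) is glycerol esterified with three fatty acids:

    neutral formula = C3H8O3 + sum(FA formulas) - 3 x H2O

Compositions are multisets — the esterification (sn-) positions are not
resolved by the MS2 method, so ``build_tag`` is order-insensitive and the
stored name is purely a display convention: conventional fatty acids in
ascending molecular weight first, FuFAs last (nominally "sn-3").  Every
annotation downstream carries a positional-isomers-unresolved caveat.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .formula import (
    Formula,
    GLYCEROL,
    IonSpec,
    PROTON,
    WATER,
    formula_format,
    ion_mz,
    isobar_delta,
)
from .lipids import (
    BuildingBlockSet,
    ConventionalFA,
    FattyAcid,
    FuFA,
    is_fufa,
    parse_fa_token,
)

__all__ = [
    "TagComposition",
    "Candidate",
    "CandidateDatabase",
    "IsobarConflict",
    "build_tag",
    "tag_precursor_mz",
    "enumerate_candidates",
    "find_isobaric_conflicts",
    "parse_tag_name",
]

# lazy alkyl-length match so concatenated FuFA tokens ("9D59D5") split correctly
_FUFA_TOKEN_RE = re.compile(r"(\d+[MD]\d+?)(?=\d+[MD]|[A-Z]|$|-)")
_NDD_TOKEN_RE = re.compile(r"(\d+:\d+)")


@dataclass(frozen=True)
class TagComposition:
    """An unordered triple of fatty acids on glycerol, canonically named."""

    fatty_acids: tuple[FattyAcid, FattyAcid, FattyAcid]
    name: str
    neutral_formula: Formula
    carbon_number: int  # sum of acyl carbons, glycerol excluded
    n_fufa: int

    @property
    def fufas(self) -> tuple[FuFA, ...]:
        return tuple(fa for fa in self.fatty_acids if is_fufa(fa))

    @property
    def conventional(self) -> tuple[ConventionalFA, ...]:
        return tuple(fa for fa in self.fatty_acids if not is_fufa(fa))

    @property
    def token_multiset(self) -> tuple[str, ...]:
        return tuple(sorted(fa.token for fa in self.fatty_acids))


def _canonical_order(fas: Sequence[FattyAcid]) -> tuple[FattyAcid, ...]:
    conv = sorted(
        (fa for fa in fas if not is_fufa(fa)), key=lambda fa: (fa.neutral_mass, fa.token)
    )
    furan = sorted(
        (fa for fa in fas if is_fufa(fa)), key=lambda fa: (fa.neutral_mass, fa.token)
    )
    return tuple(conv) + tuple(furan)


def _format_name(fas: Sequence[FattyAcid]) -> str:
    tokens = [fa.token for fa in fas]
    if len(set(tokens)) == 1 and is_fufa(fas[0]):
        return f"tri{tokens[0]}"  # e.g. tri9M5; conventional triples stay "LLL"
    # "15:0"-style tokens need a separator so "15:0-L9D5" stays parseable
    parts: list[str] = []
    for fa in fas:
        parts.append(fa.token)
        if ":" in fa.token:
            parts.append("-")
    if parts and parts[-1] == "-":
        parts.pop()
    return "".join(parts)


def build_tag(fa1: FattyAcid, fa2: FattyAcid, fa3: FattyAcid) -> TagComposition:
    """Assemble a TAG from three building blocks (multiset semantics)."""
    fas = _canonical_order((fa1, fa2, fa3))
    neutral = GLYCEROL
    for fa in fas:
        neutral = neutral + fa.neutral_formula
    neutral = neutral - 3 * WATER
    return TagComposition(
        fatty_acids=fas,
        name=_format_name(fas),
        neutral_formula=neutral,
        carbon_number=sum(fa.carbons for fa in fas),
        n_fufa=sum(1 for fa in fas if is_fufa(fa)),
    )


def tag_precursor_mz(
    tag: TagComposition, adduct: str = "H", electron_correction: bool = False
) -> float:
    """[M+H]+ or [M+NH4]+ m/z of a TAG; [M+H]+ is preferred downstream."""
    return ion_mz(
        IonSpec(tag.neutral_formula, adduct=adduct, electron_correction=electron_correction)
    )


@dataclass(frozen=True)
class Candidate:
    """A database entry: TAG with precomputed precursor m/z and fragments."""

    tag: TagComposition
    mz_mh: float
    mz_mnh4: float
    fragments: "FragmentSet"  # noqa: F821 - assembled by fragments.fragment_set

    @property
    def name(self) -> str:
        return self.tag.name


class CandidateDatabase:
    """Sorted, deduplicated list of TAG candidates for precursor matching."""

    def __init__(self, candidates: Iterable[Candidate], provenance: str = ""):
        self.candidates: list[Candidate] = sorted(candidates, key=lambda c: c.mz_mh)
        self.provenance = provenance
        self._mh = np.array([c.mz_mh for c in self.candidates])
        self._mnh4 = np.array([c.mz_mnh4 for c in self.candidates])

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)

    def by_precursor(
        self, mz: float, tol_ppm: float = 4.0, adducts: Sequence[str] = ("H",)
    ) -> list[Candidate]:
        """All candidates whose precursor m/z lies within tol_ppm of ``mz``."""
        hits: dict[int, Candidate] = {}
        for adduct in adducts:
            arr = self._mh if adduct == "H" else self._mnh4
            if len(arr) == 0:
                continue
            lo = np.searchsorted(arr, mz * (1 - tol_ppm * 1e-6), side="left")
            hi = np.searchsorted(arr, mz * (1 + tol_ppm * 1e-6), side="right")
            if adduct == "H":
                for i in range(lo, hi):
                    hits[i] = self.candidates[i]
            else:
                # NH4 column is sorted by the MH order, scan the full window
                mask = np.abs(self._mnh4 - mz) <= mz * tol_ppm * 1e-6
                for i in np.nonzero(mask)[0]:
                    hits[int(i)] = self.candidates[int(i)]
        return [hits[i] for i in sorted(hits)]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for cand in self.candidates:
            tag = cand.tag
            rows.append(
                {
                    "name": tag.name,
                    "neutral_formula": formula_format(tag.neutral_formula),
                    "mz_mh": round(cand.mz_mh, 4),
                    "mz_mnh4": round(cand.mz_mnh4, 4),
                    "fufa": ";".join(fa.token for fa in tag.fufas),
                    "conventional": ";".join(fa.token for fa in tag.conventional),
                    "carbon_number": tag.carbon_number,
                    "n_fufa": tag.n_fufa,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def enumerate_candidates(
    blocks: BuildingBlockSet,
    fufa_per_tag: int | Sequence[int] = 1,
    conv_subset: Sequence[str] | None = None,
    electron_correction: bool = False,
) -> CandidateDatabase:
    """Enumerate all TAG multisets with the requested FuFA count(s).

    With ``k`` conventional FAs and ``f`` FuFAs in one-FuFA mode the count is
    ``f * k*(k+1)/2``.  ``fufa_per_tag`` may be a single count (0-3) or a
    sequence of counts; duplicates across modes are removed.
    """
    from .fragments import fragment_set  # local import to avoid a cycle

    modes = (fufa_per_tag,) if isinstance(fufa_per_tag, int) else tuple(fufa_per_tag)
    if any(m < 0 or m > 3 for m in modes):
        raise ValueError("fufa_per_tag entries must be within 0..3")
    conv: tuple[ConventionalFA, ...] = blocks.conventional
    if conv_subset is not None:
        conv = tuple(blocks.get(t) for t in conv_subset)  # type: ignore[misc]
    seen: dict[tuple[str, ...], Candidate] = {}
    for n_fufa in modes:
        if n_fufa > 0 and not blocks.furan:
            raise ValueError("building-block set has no FuFAs for the requested mode")
        if n_fufa < 3 and not conv:
            raise ValueError(
                "building-block set has no conventional fatty acids for the requested mode"
            )
        for fus in combinations_with_replacement(blocks.furan, n_fufa):
            for convs in combinations_with_replacement(conv, 3 - n_fufa):
                tag = build_tag(*(fus + convs))
                key = tag.token_multiset
                if key in seen:
                    continue
                seen[key] = Candidate(
                    tag=tag,
                    mz_mh=tag_precursor_mz(tag, "H", electron_correction),
                    mz_mnh4=tag_precursor_mz(tag, "NH4", electron_correction),
                    fragments=fragment_set(tag, electron_correction),
                )
    return CandidateDatabase(
        seen.values(),
        provenance=f"{blocks.description or 'custom blocks'}; fufa_per_tag={modes}",
    )


@dataclass(frozen=True)
class IsobarConflict:
    name_a: str
    name_b: str
    mz_a: float
    mz_b: float
    delta_m: float
    label: str


def _difference_label(f1: Formula, f2: Formula) -> str:
    surplus1, surplus2, _ = isobar_delta(f1, f2)
    if len(surplus1) == 0 and len(surplus2) == 0:
        return "isomeric"
    return f"{formula_format(surplus1) or '-'} vs {formula_format(surplus2) or '-'}"


def find_isobaric_conflicts(
    db: CandidateDatabase, other: CandidateDatabase, resolution: float
) -> list[IsobarConflict]:
    """Precursor pairs closer than the FWHM peak width implied by ``resolution``.

    A pair conflicts when |mz_a - mz_b| < mz/R, i.e. the two [M+H]+ peaks are
    not baseline-separable at the given resolving power.  Pairs with identical
    composition are skipped; each conflict is labeled with its formula
    difference class ("O vs CH4", "C2 vs H8O", ...).
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    conflicts: list[IsobarConflict] = []
    other_mz = other._mh
    for cand in db:
        width = cand.mz_mh / resolution
        lo = np.searchsorted(other_mz, cand.mz_mh - width, side="left")
        hi = np.searchsorted(other_mz, cand.mz_mh + width, side="right")
        for j in range(lo, hi):
            rival = other.candidates[j]
            if rival.tag.token_multiset == cand.tag.token_multiset:
                continue
            conflicts.append(
                IsobarConflict(
                    name_a=cand.name,
                    name_b=rival.name,
                    mz_a=cand.mz_mh,
                    mz_b=rival.mz_mh,
                    delta_m=cand.mz_mh - rival.mz_mh,
                    label=_difference_label(
                        cand.tag.neutral_formula + PROTON,
                        rival.tag.neutral_formula + PROTON,
                    ),
                )
            )
    return conflicts


def _tokenize_tag_name(name: str) -> list[str]:
    tokens: list[str] = []
    i = 0
    two_letter = {"Pn", "Ln", "Ep", "Dp", "Dh"}
    while i < len(name):
        ch = name[i]
        if ch == "-":
            i += 1
            continue
        rest = name[i:]
        m = _NDD_TOKEN_RE.match(rest)
        if m:
            tokens.append(m.group(1))
            i += m.end()
            continue
        m = _FUFA_TOKEN_RE.match(rest)
        if m:
            tokens.append(m.group(1))
            i += m.end()
            continue
        if rest[:2] in two_letter:
            tokens.append(rest[:2])
            i += 2
            continue
        if ch.isalpha() and ch.isupper():
            tokens.append(ch)
            i += 1
            continue
        raise ValueError(f"cannot tokenize TAG name {name!r} at position {i}")
    return tokens


def parse_tag_name(name: str, blocks: BuildingBlockSet | None = None) -> TagComposition:
    """Parse a canonical TAG name like ``"LL9M5"`` or ``"15:0-Ln9D5"``.

    The prefix ``tri`` denotes three identical fatty acids ("tri9M5").
    """
    text = name.strip()
    if text.startswith("tri"):
        fa = parse_fa_token(text[3:], blocks)
        return build_tag(fa, fa, fa)
    tokens = _tokenize_tag_name(text)
    if len(tokens) != 3:
        raise ValueError(
            f"TAG name {name!r} resolves to {len(tokens)} fatty acids, expected 3 "
            f"(tokens: {tokens})"
        )
    fas = [parse_fa_token(t, blocks) for t in tokens]
    return build_tag(*fas)
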