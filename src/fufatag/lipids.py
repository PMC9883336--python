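"""Fatty-acid building blocks: conventional fatty acids and furan fatty acids.

Furan fatty acids (FuFAs) carry a furan ring mid-chain: an odd-numbered
carboxyalkyl chain (typically 7-13 C) in alpha-position, a short alkyl chain
(3 or 5 C) in alpha'-position, and one (M) or two (D) ring methyls.  The
number-letter-number short form <carboxy><M|D><alkyl> (e.g. 9M5 =
9-(3-methyl-5-pentylfuran-2-yl)-nonanoic acid) encodes the full structure.

Formula rules
-------------
conventional n:d   ->  C_n H_(2n-2d) O2
FuFA (any p, q)    ->  C_n H_(2n-6) O3 with n = p + q + 4 + methyls
                       (one ring + two ring double bonds + carboxyl group
                        = 4 degrees of unsaturation)

Double-bond positions and geometry of conventional fatty acids are not
modeled: the MS2 screen cannot resolve them, so an FA is identified by its
carbon count and double-bond count only.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import yaml

from .formula import Formula, HYDROXYL, ion_mz, IonSpec, monoisotopic_mass

__all__ = [
    "ConventionalFA",
    "FuFA",
    "FattyAcid",
    "BuildingBlockSet",
    "parse_fufa_short_form",
    "format_fufa_short_form",
    "fa_neutral_formula",
    "acyl_cation_formula",
    "acyl_cation_mz",
    "default_building_blocks",
    "core_building_blocks",
    "is_fufa",
]

_FUFA_RE = re.compile(r"^(\d+)([MD])(\d+)$")
_NDD_RE = re.compile(r"^(\d+):(\d+)$")


@dataclass(frozen=True)
class ConventionalFA:
    """A straight-chain fatty acid identified by carbons:double_bonds."""

    carbons: int
    double_bonds: int
    token: str
    trivial_name: str | None = None

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError("fatty acid needs at least 2 carbons")
        if self.double_bonds < 0 or self.double_bonds > (self.carbons - 2) // 2:
            raise ValueError(
                f"{self.carbons}:{self.double_bonds} exceeds the maximum "
                "double-bond count for this chain length"
            )

    @property
    def neutral_formula(self) -> Formula:
        n, d = self.carbons, self.double_bonds
        return Formula(C=n, H=2 * n - 2 * d, O=2)

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.neutral_formula)


@dataclass(frozen=True)
class FuFA:
    """A furan fatty acid in number-letter-number nomenclature."""

    carboxy_len: int
    methylation: str  # "M" (beta-methyl) or "D" (beta,beta'-dimethyl)
    alkyl_len: int

    def __post_init__(self) -> None:
        if self.methylation not in ("M", "D"):
            raise ValueError("methylation must be 'M' or 'D'")
        if self.carboxy_len < 1 or self.alkyl_len < 1:
            raise ValueError("chain lengths must be positive")

    @property
    def token(self) -> str:
        return f"{self.carboxy_len}{self.methylation}{self.alkyl_len}"

    @property
    def methyl_count(self) -> int:
        return 1 if self.methylation == "M" else 2

    @property
    def carbons(self) -> int:
        # furan ring contributes 4 carbons, ring methyls 1 or 2
        return self.carboxy_len + self.alkyl_len + 4 + self.methyl_count

    @property
    def neutral_formula(self) -> Formula:
        n = self.carbons
        return Formula(C=n, H=2 * n - 6, O=3)

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.neutral_formula)


FattyAcid = Union[ConventionalFA, FuFA]


def is_fufa(fa: FattyAcid) -> bool:
    return isinstance(fa, FuFA)


def parse_fufa_short_form(text: str, allow_even: bool = False) -> FuFA:
    """Parse a short form like ``"9M5"`` into a :class:`FuFA`.

    Natural FuFAs have odd chain lengths; even lengths are rejected unless
    ``allow_even`` is set, in which case a warning is emitted instead.
    """
    match = _FUFA_RE.match(text.strip())
    if not match:
        raise ValueError(f"malformed FuFA short form {text!r} (expected e.g. '9M5')")
    p, letter, q = int(match.group(1)), match.group(2), int(match.group(3))
    if p % 2 == 0 or q % 2 == 0:
        if allow_even:
            warnings.warn(
                f"FuFA {text!r} has an even chain length; natural FuFAs are odd",
                stacklevel=2,
            )
        else:
            raise ValueError(
                f"FuFA {text!r} has an even chain length; pass allow_even=True "
                "to accept it anyway"
            )
    return FuFA(carboxy_len=p, methylation=letter, alkyl_len=q)


def format_fufa_short_form(fufa: FuFA) -> str:
    return fufa.token


def fa_neutral_formula(fa: FattyAcid) -> Formula:
    return fa.neutral_formula


def acyl_cation_formula(fa: FattyAcid) -> Formula:
    """Acylium [RCO]+ atom inventory: the neutral acid minus a hydroxyl.

    For FuFAs this is the [FCO]+ ion (formally [FuFA-OH]+, alpha-cleavage),
    the base peak of FuFA-TAG MS2 spectra.
    """
    return fa.neutral_formula - HYDROXYL


def acyl_cation_mz(fa: FattyAcid, electron_correction: bool = False) -> float:
    return ion_mz(
        IonSpec(acyl_cation_formula(fa), adduct=None, electron_correction=electron_correction)
    )


@dataclass(frozen=True)
class BuildingBlockSet:
    """The fatty-acid universe a candidate database is enumerated from."""

    conventional: tuple[ConventionalFA, ...]
    furan: tuple[FuFA, ...]
    description: str = ""

    def __post_init__(self) -> None:
        tokens = [fa.token for fa in self.conventional] + [f.token for f in self.furan]
        dupes = {t for t in tokens if tokens.count(t) > 1}
        if dupes:
            raise ValueError(f"duplicate fatty-acid short names: {sorted(dupes)}")

    @property
    def all(self) -> tuple[FattyAcid, ...]:
        return self.conventional + self.furan

    def get(self, token: str) -> FattyAcid:
        for fa in self.all:
            if fa.token == token:
                return fa
        raise KeyError(f"unknown fatty-acid token {token!r}")

    def __contains__(self, token: str) -> bool:
        return any(fa.token == token for fa in self.all)

    # -- serialization: one record per fatty acid, human-editable ---------
    def to_records(self) -> list[dict]:
        records: list[dict] = []
        for fa in self.conventional:
            records.append(
                {
                    "name": fa.token,
                    "type": "conventional",
                    "carbons": fa.carbons,
                    "double_bonds": fa.double_bonds,
                    **({"trivial": fa.trivial_name} if fa.trivial_name else {}),
                }
            )
        for fu in self.furan:
            records.append(
                {
                    "name": fu.token,
                    "type": "furan",
                    "carboxy": fu.carboxy_len,
                    "methylation": fu.methylation,
                    "alkyl": fu.alkyl_len,
                }
            )
        return records

    @classmethod
    def from_records(cls, records: list[dict], description: str = "") -> "BuildingBlockSet":
        conventional: list[ConventionalFA] = []
        furan: list[FuFA] = []
        for rec in records:
            kind = rec.get("type")
            if kind == "conventional":
                conventional.append(
                    ConventionalFA(
                        carbons=int(rec["carbons"]),
                        double_bonds=int(rec["double_bonds"]),
                        token=str(rec["name"]),
                        trivial_name=rec.get("trivial"),
                    )
                )
            elif kind == "furan":
                fufa = FuFA(
                    carboxy_len=int(rec["carboxy"]),
                    methylation=str(rec["methylation"]),
                    alkyl_len=int(rec["alkyl"]),
                )
                if fufa.token != str(rec["name"]):
                    raise ValueError(
                        f"furan record name {rec['name']!r} does not match "
                        f"its parameters ({fufa.token})"
                    )
                furan.append(fufa)
            else:
                raise ValueError(f"unknown fatty-acid record type {kind!r}")
        return cls(tuple(conventional), tuple(furan), description=description)

    def save(self, path: str | Path) -> None:
        payload = {"description": self.description, "fatty_acids": self.to_records()}
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "BuildingBlockSet":
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls.from_records(
            payload["fatty_acids"], description=payload.get("description", "")
        )


def _conv(carbons: int, double_bonds: int, token: str, trivial: str) -> ConventionalFA:
    return ConventionalFA(carbons, double_bonds, token, trivial)


_DEFAULT_CONVENTIONAL = (
    _conv(15, 0, "15:0", "pentadecanoic acid"),
    _conv(16, 0, "P", "palmitic acid"),
    _conv(16, 1, "Pn", "palmitoleic acid"),
    _conv(17, 0, "17:0", "margaric acid"),
    _conv(18, 0, "S", "stearic acid"),
    _conv(18, 1, "O", "oleic acid"),
    _conv(18, 2, "L", "linoleic acid"),
    _conv(18, 3, "Ln", "alpha-linolenic acid"),
    _conv(20, 5, "Ep", "eicosapentaenoic acid"),
    _conv(22, 5, "Dp", "docosapentaenoic acid"),
    _conv(22, 6, "Dh", "docosahexaenoic acid"),
)

# The eight most relevant FuFAs plus the four acylium-isomer partners with a
# shorter (7M5, 7D5) or longer (13M3, 13D3) carboxyalkyl chain.  13M3 is kept
# although it is the rarest member; each [FCO]+ mass is shared by exactly two
# set members.
_DEFAULT_FUFA_TOKENS = (
    "7M5", "7D5",
    "9M3", "9D3", "9M5", "9D5",
    "11M3", "11D3", "11M5", "11D5",
    "13M3", "13D3",
)

# The six food-relevant FuFAs x seven characteristic conventional fatty acids
# used for the published candidate list of one-FuFA TAGs.
_CORE_FUFA_TOKENS = ("9M5", "11M3", "9D5", "11D3", "11D5", "13D3")
_CORE_CONV_TOKENS = ("P", "O", "L", "Ln", "Ep", "Dp", "Dh")


def default_building_blocks() -> BuildingBlockSet:
    """Full default set: 11 conventional FAs and 12 FuFAs.

    Covers everything observed in the mushroom screen (including 15:0, 17:0,
    Pn, S and the minor FuFA 7D5) on top of the core fish/plant-oil set.
    """
    return BuildingBlockSet(
        conventional=_DEFAULT_CONVENTIONAL,
        furan=tuple(parse_fufa_short_form(t) for t in _DEFAULT_FUFA_TOKENS),
        description="default extended set (11 conventional FAs, 12 FuFAs)",
    )


def core_building_blocks() -> BuildingBlockSet:
    """The six relevant FuFAs with the seven characteristic conventional FAs."""
    full = default_building_blocks()
    return BuildingBlockSet(
        conventional=tuple(full.get(t) for t in _CORE_CONV_TOKENS),
        furan=tuple(full.get(t) for t in _CORE_FUFA_TOKENS),
        description="core screening set (7 conventional FAs, 6 FuFAs)",
    )


def parse_fa_token(token: str, blocks: BuildingBlockSet | None = None) -> FattyAcid:
    """Resolve a single fatty-acid token: letter code, n:d style, or FuFA.

    Letter codes resolve against ``blocks`` when given, otherwise against
    the default building-block set.
    """
    token = token.strip()
    if blocks is None:
        blocks = default_building_blocks()
    if token in blocks:
        return blocks.get(token)
    match = _NDD_RE.match(token)
    if match:
        return ConventionalFA(int(match.group(1)), int(match.group(2)), token)
    if _FUFA_RE.match(token):
        return parse_fufa_short_form(token)
    raise ValueError(f"unknown fatty-acid token {token!r}")
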