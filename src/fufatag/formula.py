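"""Monoisotopic mass arithmetic for molecular formulas and positive ions.

Everything downstream (building blocks, TAG assembly, fragment prediction,
ppm matching) reduces to exact-mass sums over small element inventories, so
this module owns the element table, the :class:`Formula` container, ion m/z
computation, ppm errors and the resolution arithmetic used to reason about
nominally isobaric lipid species.

Atomic monoisotopic masses are the CODATA/AME values carried to >= 9
decimal places (12C = 12 exactly by definition).  Positive-ion m/z values
are by default plain atom-inventory sums (no electron-mass subtraction),
which is the convention that reproduces published 4-decimal lipid tables;
physically correct electron subtraction (0.000549 Da per charge) can be
switched on per ion.
"""

from __future__ import annotations

import re
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "Formula",
    "IonSpec",
    "formula_parse",
    "formula_format",
    "monoisotopic_mass",
    "ion_mz",
    "ppm_error",
    "required_resolution",
    "isobar_delta",
    "round_half_up",
]

#: Monoisotopic atomic masses in Da (CODATA / AME2020; 12C defines the scale).
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
}

#: Electron rest mass in Da.
ELECTRON_MASS = 0.00054857990907

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def round_half_up(value: float, ndigits: int) -> float:
    """Round with ties away from zero, as printed tables do (not banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


class Formula(Mapping):
    """Immutable element -> count map for a neutral molecule or an ion's atoms.

    Counts are non-negative integers; zero counts are dropped, so
    ``Formula(C=1, H=0) == Formula(C=1)``.  Addition and subtraction are
    element-wise; subtracting below zero raises ``ValueError``.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kwargs: int):
        merged: dict[str, int] = {}
        for source in (counts or {}), kwargs:
            for element, count in source.items():
                merged[element] = merged.get(element, 0) + int(count)
        for element, count in merged.items():
            if count < 0:
                raise ValueError(f"negative count for element {element!r}: {count}")
        self._counts = {e: c for e, c in sorted(merged.items()) if c}

    # -- Mapping protocol -------------------------------------------------
    def __getitem__(self, element: str) -> int:
        return self._counts[element]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def get(self, element: str, default: int = 0) -> int:
        return self._counts.get(element, default)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for element, count in other.items():
            counts[element] = counts.get(element, 0) + count
        return Formula(counts)

    def __sub__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for element, count in other.items():
            counts[element] = counts.get(element, 0) - count
            if counts[element] < 0:
                raise ValueError(
                    f"cannot remove {count} x {element} from {self}: "
                    "subtraction below zero"
                )
        return Formula(counts)

    def __mul__(self, n: int) -> "Formula":
        if n < 0:
            raise ValueError("multiplier must be non-negative")
        return Formula({e: c * n for e, c in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Formula):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == {e: c for e, c in other.items() if c}
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    def __repr__(self) -> str:
        return f"Formula({formula_format(self)!r})"

    def __str__(self) -> str:
        return formula_format(self)

    @classmethod
    def parse(cls, text: str) -> "Formula":
        return formula_parse(text)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


#: Common small formulas used throughout TAG arithmetic.
WATER = Formula(H=2, O=1)
HYDROXYL = Formula(H=1, O=1)
PROTON = Formula(H=1)  # added as an H atom when electron correction is off
AMMONIUM = Formula(N=1, H=4)
GLYCEROL = Formula(C=3, H=8, O=3)

_ADDUCTS: dict[str | None, Formula] = {
    "H": PROTON,
    "NH4": AMMONIUM,
    None: Formula(),
}


def formula_parse(text: str) -> Formula:
    """Parse a Hill-notation formula string like ``"C22H38O3"``.

    Each element symbol may be followed by an optional positive integer.
    Unknown element symbols (anything not in :data:`MONOISOTOPIC_MASS`)
    and malformed input raise ``ValueError``.
    """
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_RE.finditer(text):
        if match.start() != pos:
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        element, digits = match.group(1), match.group(2)
        if element not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol {element!r} in {text!r}")
        if digits == "":
            count = 1
        else:
            count = int(digits)
            if count == 0:
                raise ValueError(f"zero count for {element!r} in {text!r}")
        counts[element] = counts.get(element, 0) + count
        pos = match.end()
    if pos != len(text) or (not counts and text):
        raise ValueError(f"malformed formula string {text!r}")
    return Formula(counts)


def formula_format(formula: Mapping[str, int]) -> str:
    """Format in Hill order: C first, H second, remaining elements sorted."""
    items = {e: c for e, c in formula.items() if c}
    ordered: list[tuple[str, int]] = []
    for special in ("C", "H"):
        if special in items:
            ordered.append((special, items.pop(special)))
    ordered.extend(sorted(items.items()))
    return "".join(f"{e}{c if c != 1 else ''}" for e, c in ordered)


def monoisotopic_mass(formula: Mapping[str, int]) -> float:
    """Exact mass in Da: sum of count x monoisotopic atomic mass."""
    try:
        return sum(MONOISOTOPIC_MASS[e] * c for e, c in formula.items())
    except KeyError as exc:
        raise ValueError(f"unknown element symbol {exc.args[0]!r}") from None


@dataclass(frozen=True)
class IonSpec:
    """A positive ion: neutral (or fragment) atom inventory plus adduct.

    ``adduct`` is ``"H"`` for [M+H]+, ``"NH4"`` for [M+NH4]+ or ``None`` for
    fragment cations whose formula already is the full atom inventory.
    ``electron_correction`` subtracts one electron mass per charge when True;
    the default (False) matches printed lipidomics tables.
    """

    formula: Formula
    adduct: str | None = "H"
    charge: int = 1
    electron_correction: bool = False

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("only positive ions are modeled; charge must be >= 1")
        if self.adduct not in _ADDUCTS:
            raise ValueError(f"unknown adduct {self.adduct!r}")


def ion_mz(ion: IonSpec) -> float:
    """m/z of a positive ion = (inventory mass + adduct mass [- e-]) / charge."""
    mass = monoisotopic_mass(ion.formula) + monoisotopic_mass(_ADDUCTS[ion.adduct])
    if ion.electron_correction:
        mass -= ELECTRON_MASS * ion.charge
    return mass / ion.charge


def ppm_error(measured: float, calculated: float) -> float:
    """Signed relative mass error, (measured - calculated)/calculated x 1e6."""
    if calculated <= 0:
        raise ValueError("calculated m/z must be positive")
    return (measured - calculated) / calculated * 1e6


def required_resolution(reference_mz: float, delta_m: float) -> float:
    """Resolution m/dm needed to separate two peaks delta_m apart."""
    if delta_m <= 0:
        raise ValueError("delta_m must be positive")
    return reference_mz / delta_m


def isobar_delta(f1: Formula, f2: Formula) -> tuple[Formula, Formula, float]:
    """Element-wise surplus of each formula over the other, and signed dm.

    Returns ``(surplus1, surplus2, mass(f1) - mass(f2))``.  For the classic
    nominal-isobar pair C22H38O3 vs C23H42O2 this yields (O, CH4, -0.0364).
    """
    surplus1: dict[str, int] = {}
    surplus2: dict[str, int] = {}
    for element in set(f1) | set(f2):
        diff = f1.get(element, 0) - f2.get(element, 0)
        if diff > 0:
            surplus1[element] = diff
        elif diff < 0:
            surplus2[element] = -diff
    return (
        Formula(surplus1),
        Formula(surplus2),
        monoisotopic_mass(f1) - monoisotopic_mass(f2),
    )
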