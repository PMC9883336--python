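"""Synthetic MS2 spectra with the statistical structure the screen assumes.

Two generators live here:

* :func:`simulate_spectrum` — Monte-Carlo spectra for any TAG: every
  predicted fragment with Gaussian ppm mass error, an intensity hierarchy
  headed by the [FCO]+ base peak, and uniformly placed decoy peaks.
* :func:`mushroom_fixture` — a fully deterministic reconstruction of the 18
  FuFA-TAG spectra observed in king oyster mushroom, built solely from the
  published observed m/z values and [FCO]+ intensities; the intensities of
  the remaining ions are arbitrary sub-maximal constants.

The default intensity model encodes what clean FuFA-TAG spectra look like:
[FCO]+ is the base peak, diacyl ions are prominent, furan-core and
McLafferty ions are minor, the surviving precursor is small.  Decoy peaks
emulate unrelated chemical background.  Chromatographic peak shape,
isotope envelopes and real detector noise are not modeled.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .fragments import fragment_set
from .spectra import Ms2Spectrum
from .tags import TagComposition

__all__ = [
    "SimulationParams",
    "simulate_spectrum",
    "decoy_spectrum",
    "isobar_challenge",
    "mushroom_fixture",
    "MUSHROOM_ROWS",
    "write_manifest",
]

#: Signed displacement of the interfering species relative to the FuFA-TAG
#: ion, Da: O-vs-CH4 partners (extra CH4 for an O) sit 0.0364 Da above,
#: polyunsaturated C2-vs-H8O partners 0.0575 Da below.
ISOBAR_OFFSETS = {"O_vs_CH4": +0.036394, "C2_vs_H8O": -0.057515}


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the spectrum generator (relative intensities vs [FCO]+ = 1)."""

    sigma_ppm: float = 1.0
    intensity_fco: float = 1.0
    intensity_diacyl: float = 0.4
    intensity_core: float = 0.12
    intensity_mclafferty: float = 0.1
    intensity_precursor: float = 0.1
    base_intensity: float = 1e5
    decoy_peaks: int = 15
    decoy_mz_range: tuple[float, float] = (60.0, 1000.0)
    decoy_intensity_range: tuple[float, float] = (0.005, 0.05)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_ppm < 0:
            raise ValueError("sigma_ppm must be >= 0")
        for name in (
            "intensity_fco", "intensity_diacyl", "intensity_core",
            "intensity_mclafferty", "intensity_precursor", "base_intensity",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.decoy_peaks < 0:
            raise ValueError("decoy_peaks must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _perturb(mz: float, sigma_ppm: float, rng: np.random.Generator) -> float:
    if sigma_ppm == 0:
        return mz
    return mz * (1.0 + rng.normal(0.0, sigma_ppm) * 1e-6)


def simulate_spectrum(
    tag: TagComposition,
    params: SimulationParams = SimulationParams(),
    rng: np.random.Generator | None = None,
    spectrum_id: str | None = None,
    electron_correction: bool = False,
) -> Ms2Spectrum:
    """One synthetic MS2 spectrum of ``tag`` under the given noise model."""
    rng = params.rng() if rng is None else rng
    fs = fragment_set(tag, electron_correction)
    scale = params.base_intensity
    mzs: list[float] = []
    intens: list[float] = []

    def add(mz: float, rel: float) -> None:
        mzs.append(_perturb(mz, params.sigma_ppm, rng))
        intens.append(rel * scale)

    for ion in fs.fco:
        add(ion.mz, params.intensity_fco)
    for ion in fs.diacyl:
        add(ion.mz, params.intensity_diacyl)
    for ion in fs.furan_core:
        add(ion.mz, params.intensity_core)
    for ion in fs.mclafferty:
        add(ion.mz, params.intensity_mclafferty)
    add(fs.precursor_mh, params.intensity_precursor)

    lo, hi = params.decoy_mz_range
    ilo, ihi = params.decoy_intensity_range
    for _ in range(params.decoy_peaks):
        mzs.append(rng.uniform(lo, hi))
        intens.append(rng.uniform(ilo, ihi) * scale)

    precursor = _perturb(fs.precursor_mh, params.sigma_ppm, rng)
    return Ms2Spectrum(
        spectrum_id=spectrum_id or f"sim-{tag.name}",
        precursor_mz=precursor,
        mz=np.array(mzs),
        intensity=np.array(intens),
        metadata={"generator": "simulate_spectrum", "tag": tag.name},
    )


def decoy_spectrum(
    params: SimulationParams = SimulationParams(),
    rng: np.random.Generator | None = None,
    precursor_range: tuple[float, float] = (820.0, 1030.0),
    spectrum_id: str = "decoy",
) -> Ms2Spectrum:
    """A spectrum of pure background: random precursor, decoy peaks only."""
    rng = params.rng() if rng is None else rng
    n = max(params.decoy_peaks, 1)
    lo, hi = params.decoy_mz_range
    ilo, ihi = params.decoy_intensity_range
    return Ms2Spectrum(
        spectrum_id=spectrum_id,
        precursor_mz=rng.uniform(*precursor_range),
        mz=rng.uniform(lo, hi, size=n),
        intensity=rng.uniform(ilo, ihi, size=n) * params.base_intensity,
        metadata={"generator": "decoy_spectrum"},
    )


def isobar_challenge(
    tag: TagComposition,
    interference_class: str,
    params: SimulationParams = SimulationParams(),
    rng: np.random.Generator | None = None,
    electron_correction: bool = False,
) -> Ms2Spectrum:
    """Simulated spectrum plus nominal-isobar interference peaks.

    Adds peaks offset by the exact-mass gap of the chosen class
    (+0.0364 Da for "O_vs_CH4", -0.0575 Da for "C2_vs_H8O") next to the
    precursor and the [FCO]+ ion, emulating an unresolved interfering
    species.  A zero-intensity-weighted coincident offset simply sums.
    """
    if interference_class not in ISOBAR_OFFSETS:
        raise ValueError(
            f"unknown interference class {interference_class!r}; "
            f"expected one of {sorted(ISOBAR_OFFSETS)}"
        )
    offset = ISOBAR_OFFSETS[interference_class]
    rng = params.rng() if rng is None else rng
    spec = simulate_spectrum(tag, params, rng, electron_correction=electron_correction)
    fs = fragment_set(tag, electron_correction)
    extra_mz = [fs.precursor_mh + offset]
    extra_int = [params.intensity_fco * params.base_intensity]
    for ion in fs.fco:
        extra_mz.append(ion.mz + offset)
        extra_int.append(params.intensity_fco * params.base_intensity)
    mz = np.concatenate([spec.mz, extra_mz])
    intensity = np.concatenate([spec.intensity, extra_int])
    # coincident peaks (offset 0 would duplicate an m/z) are summed
    order = np.argsort(mz)
    mz, intensity = mz[order], intensity[order]
    keep_mz: list[float] = []
    keep_int: list[float] = []
    for m, i in zip(mz, intensity):
        if keep_mz and m == keep_mz[-1]:
            keep_int[-1] += i
        else:
            keep_mz.append(float(m))
            keep_int.append(float(i))
    return Ms2Spectrum(
        spectrum_id=f"{spec.spectrum_id}+{interference_class}",
        precursor_mz=spec.precursor_mz,
        mz=np.array(keep_mz),
        intensity=np.array(keep_int),
        metadata={**spec.metadata, "interference": interference_class},
    )


# ---------------------------------------------------------------------------
# Deterministic king-oyster-mushroom fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MushroomRow:
    """One identified FuFA-TAG of the mushroom screen, as published.

    ``diagnostic`` holds the observed McLafferty, furan-core and [FCO]+
    m/z (in that order); ``diacyl`` the observed [M-RCOO]+ m/z values.
    ``intensity`` is the published [FCO]+ base-peak intensity divided by
    1000 (the table's convention).
    """

    name: str
    rt_min: float
    neutral_formula: str
    mz_mh: float
    diagnostic: tuple[float, float, float]
    diacyl: tuple[float, ...]
    carbon_number: int
    intensity: float
    fufa_only: bool = False


MUSHROOM_ROWS: tuple[MushroomRow, ...] = (
    MushroomRow("XY9D5", 20.80, "C57H96O7", 893.7233,
              (123.0808, 179.1432, 305.2478), (), 54, 570, fufa_only=True),
    MushroomRow("LL7D5", 20.80, "C57H96O7", 893.7233,
              (123.0808, 179.1432, 277.2165), (599.5031, 613.4835), 54, 284),
    MushroomRow("15:0-Ln9D5", 21.65, "C56H96O7", 881.7230,
              (123.0808, 179.1432, 305.2479), (559.4725, 601.4830, 639.4975), 53, 1010),
    MushroomRow("LL9M5", 21.66, "C58H98O7", 907.7379,
              (109.0653, 165.1276, 291.2321), (599.5036, 627.4988), 55, 230),
    MushroomRow("L9D59D5", 21.89, "C61H102O8", 963.7649,
              (123.0808, 179.1431, 305.2480), (641.5142, 683.5248), 58, 9980),
    MushroomRow("PnL9D5", 22.03, "C57H98O7", 895.7386,
              (123.0807, 179.1431, 305.2478), (573.4880, 615.4988, 641.5142), 54, 2110),
    MushroomRow("LO7D5", 22.14, "C57H98O7", 895.7384,
              (123.0807, 179.1431, 277.2164), (601.5197, 613.4827, 615.4984), 54, 278),
    MushroomRow("LL9D5", 22.24, "C59H100O7", 921.7543,
              (123.0807, 179.1431, 305.2479), (599.5035, 641.5142), 56, 66800),
    MushroomRow("15:0-L9D5", 22.83, "C56H98O7", 883.7387,
              (123.0808, 179.1431, 305.2479), (561.4880, 603.4987, 641.5143), 53, 3770),
    MushroomRow("LO9M5", 23.30, "C58H100O7", 909.7537,
              (109.0653, 165.1275, 291.2321), (601.5195, 627.4985, 629.5150), 55, 339),
    MushroomRow("O9D59D5", 23.34, "C61H104O8", 965.7803,
              (123.0808, 179.1431, 305.2478), (643.5302, 683.5249), 58, 1430),
    MushroomRow("LO9D5", 23.71, "C59H102O7", 923.7696,
              (123.0807, 179.1430, 305.2478), (601.5192, 641.5139, 643.5297), 56, 29100),
    MushroomRow("15:0-O9D5", 24.34, "C56H100O7", 885.7546,
              (123.0808, 179.1432, 305.2478), (563.5038, 603.4987, 643.5302), 53, 1280),
    MushroomRow("17:0-L9D5", 24.59, "C58H102O7", 911.7698,
              (123.0807, 179.1432, 305.2477), (589.5192, 631.5297, 641.5143), 55, 815),
    MushroomRow("OO9M5", 24.69, "C58H102O7", 911.7711,
              (109.0653, 165.1274, 291.2321), (603.5348, 629.5142), 55, 121),
    MushroomRow("PO9D5", 25.13, "C57H102O7", 899.7696,
              (123.0807, 179.1431, 305.2479), (577.5192, 617.5142, 643.5298), 54, 9550),
    MushroomRow("OO9D5", 25.18, "C59H104O7", 925.7855,
              (123.0807, 179.1431, 305.2479), (603.5349, 643.5300), 56, 10100),
    MushroomRow("OS9D5", 26.80, "C59H106O7", 927.8011,
              (123.0808, 179.1431, 305.2477), (605.5505, 643.5300, 645.5455), 56, 977),
)

# Sub-maximal relative intensities for the ions whose heights the published
# table does not report; kept below the [FCO]+ base peak so the strict
# base-peak mode also passes on single-TAG rows.
_FIXTURE_REL = {"mclafferty": 0.15, "furan_core": 0.10, "diacyl": 0.40, "precursor": 0.08}
_FIXTURE_INTENSITY_SCALE = 1000.0  # published values are intensity / 1000


def mushroom_fixture() -> list[Ms2Spectrum]:
    """The 18 mushroom FuFA-TAG spectra, rebuilt from published values.

    Deterministic — no random numbers: peak positions are the observed m/z
    values, the [FCO]+ height is the published intensity x 1000, and the
    remaining ions get fixed sub-maximal heights.
    """
    spectra: list[Ms2Spectrum] = []
    for index, row in enumerate(MUSHROOM_ROWS):
        fco_height = row.intensity * _FIXTURE_INTENSITY_SCALE
        mcl, core, fco = row.diagnostic
        mzs = [mcl, core, fco]
        heights = [
            _FIXTURE_REL["mclafferty"] * fco_height,
            _FIXTURE_REL["furan_core"] * fco_height,
            fco_height,
        ]
        for diacyl_mz in row.diacyl:
            mzs.append(diacyl_mz)
            heights.append(_FIXTURE_REL["diacyl"] * fco_height)
        mzs.append(row.mz_mh)
        heights.append(_FIXTURE_REL["precursor"] * fco_height)
        spectra.append(
            Ms2Spectrum(
                spectrum_id=f"mushroom-{index + 1:02d}-{row.name}",
                precursor_mz=row.mz_mh,
                mz=np.array(mzs),
                intensity=np.array(heights),
                rt_min=row.rt_min,
                metadata={
                    "generator": "mushroom_fixture",
                    "expected_name": row.name,
                    "expected_carbon_number": row.carbon_number,
                    "expected_fufa_only": row.fufa_only,
                },
            )
        )
    return spectra


def write_manifest(
    path: str | Path,
    params: SimulationParams,
    files: Sequence[str],
    extra: dict | None = None,
) -> None:
    """Record generator parameters and outputs for reproducibility."""
    payload = {"params": asdict(params), "files": list(files)}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
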