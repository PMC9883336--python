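"""Centroided MS2 spectrum container, readers/writers and peak matching.

Supported formats: mzML (read and a minimal writer), MGF (read/write via
pyteomics) and a human-diffable tab-separated peak-list dialect (long
format, one row per peak; see docs/peaklist-format.md).  Profile-mode data
are rejected — the screen assumes instrument-centroided peaks.

Retention time is carried through for reporting only; identification is
purely mass-based.
"""

from __future__ import annotations

import base64
import logging
import struct
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple
from xml.sax.saxutils import escape

import numpy as np
from pyteomics import mgf as _mgf

from .formula import ppm_error

__all__ = [
    "Peak",
    "Ms2Spectrum",
    "read_mzml",
    "read_mgf",
    "read_peaklist_tsv",
    "read_spectra",
    "write_mgf",
    "write_peaklist_tsv",
    "write_mzml",
    "match_peak",
    "base_peak",
]

logger = logging.getLogger(__name__)


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass
class Ms2Spectrum:
    """A centroided MS2 peak list with its precursor m/z."""

    spectrum_id: str
    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray
    rt_min: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if np.any(self.mz <= 0):
            raise ValueError("peak m/z values must be positive")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if self.precursor_mz is None or self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(float(m), float(i)) for m, i in zip(self.mz, self.intensity)]


def match_peak(
    spectrum: Ms2Spectrum, target_mz: float, tol_ppm: float = 4.0
) -> Peak | None:
    """Most intense peak within tol_ppm of ``target_mz`` (ties: smallest |ppm|)."""
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    lo = np.searchsorted(spectrum.mz, target_mz * (1 - tol_ppm * 1e-6), side="left")
    hi = np.searchsorted(spectrum.mz, target_mz * (1 + tol_ppm * 1e-6), side="right")
    best: Peak | None = None
    best_key: tuple[float, float] | None = None
    for i in range(lo, hi):
        mz = float(spectrum.mz[i])
        if abs(ppm_error(mz, target_mz)) > tol_ppm:
            continue
        key = (-float(spectrum.intensity[i]), abs(ppm_error(mz, target_mz)))
        if best_key is None or key < best_key:
            best_key = key
            best = Peak(mz, float(spectrum.intensity[i]))
    return best


def base_peak(spectrum: Ms2Spectrum) -> Peak:
    """Maximum-intensity peak; ties broken by lower m/z."""
    if len(spectrum) == 0:
        raise ValueError("cannot take the base peak of an empty spectrum")
    idx = int(np.argmax(spectrum.intensity))  # argmax returns first (= lowest m/z) tie
    return Peak(float(spectrum.mz[idx]), float(spectrum.intensity[idx]))


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

_MZML_NS = "{http://psi.hupo.org/ms/mzml}"

# cvParam accessions understood by the reader
_ACC_MS_LEVEL = "MS:1000511"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_64BIT = "MS:1000523"
_ACC_32BIT = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def _cv_accessions(element) -> dict[str, dict]:
    params: dict[str, dict] = {}
    for cv in element.iter(f"{_MZML_NS}cvParam"):
        params[cv.get("accession", "")] = cv.attrib
    return params


def _decode_binary_array(bda) -> np.ndarray | None:
    params = _cv_accessions(bda)
    binary = bda.find(f"{_MZML_NS}binary")
    raw = base64.b64decode((binary.text or "").strip()) if binary is not None else b""
    if _ACC_ZLIB in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_32BIT in params else "<f8"
    values = np.frombuffer(raw, dtype=dtype).astype(float)
    if _ACC_MZ_ARRAY in params:
        return ("mz", values)  # type: ignore[return-value]
    if _ACC_INT_ARRAY in params:
        return ("intensity", values)  # type: ignore[return-value]
    return None


def read_mzml(path: str | Path, require_centroid: bool = True) -> Iterator[Ms2Spectrum]:
    """Yield the MS-level-2 spectra of an mzML file.

    A self-contained reader for centroided mzML 1.1 (64/32-bit arrays,
    zlib or no compression).  Scans without a precursor annotation are
    logged and skipped; profile spectra raise unless ``require_centroid``
    is False.
    """
    import xml.etree.ElementTree as ET

    for event, element in ET.iterparse(str(path), events=("end",)):
        if element.tag != f"{_MZML_NS}spectrum":
            continue
        spectrum_id = element.get("id", "")
        params = _cv_accessions(element)
        level = params.get(_ACC_MS_LEVEL, {}).get("value")
        if level != "2":
            element.clear()
            continue
        if _ACC_PROFILE in params and _ACC_CENTROID not in params:
            if require_centroid:
                raise ValueError(
                    f"spectrum {spectrum_id!r} is profile data; centroided input "
                    "is required (pass require_centroid=False to override)"
                )
            warnings.warn(f"accepting profile spectrum {spectrum_id!r}")
        selected = element.find(
            f"{_MZML_NS}precursorList/{_MZML_NS}precursor/"
            f"{_MZML_NS}selectedIonList/{_MZML_NS}selectedIon"
        )
        precursor = None
        if selected is not None:
            value = _cv_accessions(selected).get(_ACC_SELECTED_MZ, {}).get("value")
            if value is not None:
                precursor = float(value)
        if precursor is None:
            logger.error("MS2 scan %r lacks a precursor m/z; skipped", spectrum_id)
            element.clear()
            continue
        rt = None
        scan = element.find(f"{_MZML_NS}scanList/{_MZML_NS}scan")
        if scan is not None:
            start = _cv_accessions(scan).get(_ACC_SCAN_START)
            if start is not None:
                rt = float(start["value"])
                if start.get("unitName", "minute").lower().startswith("second"):
                    rt /= 60.0
        arrays: dict[str, np.ndarray] = {}
        for bda in element.iter(f"{_MZML_NS}binaryDataArray"):
            decoded = _decode_binary_array(bda)
            if decoded is not None:
                kind, values = decoded
                arrays[kind] = values
        yield Ms2Spectrum(
            spectrum_id=spectrum_id,
            precursor_mz=precursor,
            mz=arrays.get("mz", np.empty(0)),
            intensity=arrays.get("intensity", np.empty(0)),
            rt_min=rt,
        )
        element.clear()


def _encode_array(values: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{len(values)}d", *values)).decode("ascii")


def write_mzml(spectra: Iterable[Ms2Spectrum], path: str | Path) -> None:
    """Write a minimal centroid mzML file (64-bit, uncompressed arrays)."""
    spectra = list(spectra)
    out: list[str] = []
    out.append('<?xml version="1.0" encoding="utf-8"?>')
    out.append(
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">'
        "<cvList count=\"1\">"
        '<cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/'
        'HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/></cvList>'
        '<fileDescription><fileContent>'
        '<cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>'
        "</fileContent></fileDescription>"
        '<softwareList count="1"><software id="fufatag" version="0.1.0"/></softwareList>'
        '<instrumentConfigurationList count="1">'
        '<instrumentConfiguration id="IC1"/></instrumentConfigurationList>'
        '<dataProcessingList count="1"><dataProcessing id="DP1">'
        '<processingMethod order="1" softwareRef="fufatag"/>'
        "</dataProcessing></dataProcessingList>"
        '<run id="run1" defaultInstrumentConfigurationRef="IC1">'
        f'<spectrumList count="{len(spectra)}" defaultDataProcessingRef="DP1">'
    )
    for index, spec in enumerate(spectra):
        mz_b64 = _encode_array(spec.mz)
        int_b64 = _encode_array(spec.intensity)
        rt = spec.rt_min if spec.rt_min is not None else 0.0
        out.append(
            f'<spectrum index="{index}" id="{escape(spec.spectrum_id, {chr(34): "&quot;"})}" '
            f'defaultArrayLength="{len(spec)}">'
            '<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>'
            '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>'
            '<scanList count="1"><scan>'
            f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
            f'value="{rt!r}" unitName="minute" unitAccession="UO:0000031"/>'
            "</scan></scanList>"
            '<precursorList count="1"><precursor><selectedIonList count="1"><selectedIon>'
            f'<cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" '
            f'value="{spec.precursor_mz!r}"/>'
            "</selectedIon></selectedIonList></precursor></precursorList>"
            '<binaryDataArrayList count="2">'
            f'<binaryDataArray encodedLength="{len(mz_b64)}">'
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>'
            f"<binary>{mz_b64}</binary></binaryDataArray>"
            f'<binaryDataArray encodedLength="{len(int_b64)}">'
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>'
            f"<binary>{int_b64}</binary></binaryDataArray>"
            "</binaryDataArrayList></spectrum>"
        )
    out.append("</spectrumList></run></mzML>")
    Path(path).write_text("\n".join(out), encoding="utf-8")


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------

def read_mgf(path: str | Path) -> Iterator[Ms2Spectrum]:
    """Yield spectra from an MGF file (BEGIN/END IONS blocks with PEPMASS)."""
    path = Path(path)
    if path.stat().st_size == 0:
        warnings.warn(f"empty spectrum file {path}")
        return
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            if not pepmass or pepmass[0] is None:
                logger.error("MGF block %r lacks PEPMASS; skipped", params.get("title"))
                continue
            rt = params.get("rtinseconds")
            yield Ms2Spectrum(
                spectrum_id=str(params.get("title", "")),
                precursor_mz=float(pepmass[0]),
                mz=entry.get("m/z array", np.empty(0)),
                intensity=entry.get("intensity array", np.empty(0)),
                rt_min=float(rt) / 60.0 if rt is not None else None,
            )


def write_mgf(spectra: Iterable[Ms2Spectrum], path: str | Path) -> None:
    entries = []
    for spec in spectra:
        params = {"title": spec.spectrum_id, "pepmass": round(spec.precursor_mz, 6)}
        if spec.rt_min is not None:
            params["rtinseconds"] = round(spec.rt_min * 60.0, 3)
        entries.append(
            {
                "params": params,
                "m/z array": np.round(spec.mz, 6),
                "intensity array": spec.intensity,
            }
        )
    with open(path, "w", encoding="utf-8") as handle:
        _mgf.write(
            entries, handle, fragment_format="%.6f %.6f",
            write_charges=False, use_numpy=True,
        )


# ---------------------------------------------------------------------------
# TSV peak-list dialect (long format; docs/peaklist-format.md)
# ---------------------------------------------------------------------------

_TSV_HEADER = ["spectrum_id", "precursor_mz", "rt_min", "mz", "intensity"]


def read_peaklist_tsv(path: str | Path) -> Iterator[Ms2Spectrum]:
    """Read the long-format TSV dialect (one row per peak, UTF-8)."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or all(not ln.strip() for ln in lines):
        warnings.warn(f"empty spectrum file {path}")
        return
    header = lines[0].rstrip("\n").split("\t")
    if header != _TSV_HEADER:
        raise ValueError(
            f"unexpected TSV header {header!r}; expected {_TSV_HEADER!r}"
        )
    current_id: str | None = None
    precursor: float | None = None
    rt: float | None = None
    mzs: list[float] = []
    intens: list[float] = []

    def flush() -> Ms2Spectrum | None:
        if current_id is None:
            return None
        return Ms2Spectrum(
            spectrum_id=current_id,
            precursor_mz=float(precursor),  # type: ignore[arg-type]
            mz=np.array(mzs),
            intensity=np.array(intens),
            rt_min=rt,
        )

    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 tab-separated fields")
        sid, prec_s, rt_s, mz_s, int_s = fields
        try:
            prec = float(prec_s)
            mz = float(mz_s)
            inten = float(int_s)
            rt_val = float(rt_s) if rt_s not in ("", "NA") else None
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from None
        if sid != current_id:
            spec = flush()
            if spec is not None:
                yield spec
            current_id, precursor, rt = sid, prec, rt_val
            mzs, intens = [], []
        mzs.append(mz)
        intens.append(inten)
    spec = flush()
    if spec is not None:
        yield spec


def write_peaklist_tsv(spectra: Iterable[Ms2Spectrum], path: str | Path) -> None:
    lines = ["\t".join(_TSV_HEADER)]
    for spec in spectra:
        rt_s = "" if spec.rt_min is None else f"{spec.rt_min:.4f}"
        for mz, inten in zip(spec.mz, spec.intensity):
            lines.append(
                f"{spec.spectrum_id}\t{spec.precursor_mz:.6f}\t{rt_s}"
                f"\t{mz:.6f}\t{inten:.6g}"
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_spectra(path: str | Path, fmt: str = "auto") -> Iterator[Ms2Spectrum]:
    """Dispatch on format: 'mzml', 'mgf', 'tsv' or 'auto' (by extension)."""
    path = Path(path)
    if fmt == "auto":
        fmt = {".mzml": "mzml", ".mgf": "mgf", ".tsv": "tsv", ".txt": "tsv"}.get(
            path.suffix.lower(), ""
        )
        if not fmt:
            raise ValueError(f"cannot infer spectrum format from {path.name!r}")
    reader = {"mzml": read_mzml, "mgf": read_mgf, "tsv": read_peaklist_tsv}.get(fmt)
    if reader is None:
        raise ValueError(f"unsupported spectrum format {fmt!r}")
    yield from reader(path)
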