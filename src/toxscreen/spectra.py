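"""Centroided tandem-mass-spectrum containers and I/O.

The in-memory model mirrors what a QqTOF instrument produces in
data-dependent acquisition (DDA): a time-ordered run of survey (MS1)
and product-ion (MS2) scans, each a centroided peak list with precursor
m/z, retention time and collision energy.  Supported on-disk forms are
MGF (via :mod:`pyteomics.mgf`), standard centroided mzML (a built-in
minimal reader), a small self-describing XML dialect ("mzml-lite") used
for loss-free round trips of simulated runs, and a plain-text
per-spectrum peak-list export.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import base64
import zlib

import numpy as np
from pyteomics import mgf as _mgf

from .errors import DomainError, ParseError, UnsupportedDialectError

#: Survey (MS1) scan range of the acquisition method, m/z.
MS1_SCAN_RANGE = (100.0, 700.0)
#: Product-ion (MS2) scan range, m/z.
MS2_SCAN_RANGE = (50.0, 700.0)
#: Collision energy assumed when metadata carries none, eV.
DEFAULT_COLLISION_ENERGY = 35.0


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass(frozen=True)
class Spectrum:
    """One centroided spectrum.

    Peaks are normalised at construction: sorted ascending by m/z and
    duplicate m/z values merged by intensity summation, so downstream
    peak matching is well defined.

    Parameters
    ----------
    mz, intensities
        Peak positions (Th, > 0) and abundances (counts, >= 0).
    precursor_mz
        Selected-ion m/z for MS2 scans; ``None`` for survey scans.
    retention_time
        Seconds since run start.
    collision_energy
        eV; ``None`` for survey scans.
    ms_level
        1 (survey) or 2 (product-ion).
    scan_id
        Opaque identifier, preserved through I/O.
    """

    mz: np.ndarray
    intensities: np.ndarray
    precursor_mz: float | None = None
    retention_time: float = 0.0
    collision_energy: float | None = None
    ms_level: int = 2
    scan_id: str = ""

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float).ravel()
        inten = np.asarray(self.intensities, dtype=float).ravel()
        if mz.shape != inten.shape:
            raise DomainError("mz and intensities must have equal length")
        if mz.size and (np.any(mz <= 0) or np.any(~np.isfinite(mz))):
            raise DomainError("all m/z values must be finite and > 0")
        if inten.size and (np.any(inten < 0) or np.any(~np.isfinite(inten))):
            raise DomainError("all intensities must be finite and >= 0")
        if self.ms_level not in (1, 2):
            raise DomainError(f"ms_level must be 1 or 2, got {self.ms_level}")
        if self.retention_time < 0:
            raise DomainError("retention_time must be >= 0")
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        if mz.size > 1:
            # merge exact-duplicate centroids by intensity summation
            uniq, inverse = np.unique(mz, return_inverse=True)
            if uniq.size != mz.size:
                summed = np.zeros_like(uniq)
                np.add.at(summed, inverse, inten)
                mz, inten = uniq, summed
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensities", inten)

    # -- convenience ---------------------------------------------------
    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(float(m), float(i)) for m, i in zip(self.mz, self.intensities)]

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensities.max()) if self.n_peaks else 0.0

    @property
    def total_ion_current(self) -> float:
        return float(self.intensities.sum())

    def with_peaks(self, mz: np.ndarray, intensities: np.ndarray) -> "Spectrum":
        return replace(self, mz=mz, intensities=intensities)


@dataclass
class Run:
    """A time-ordered acquisition: list of spectra plus free-form metadata
    (sample id, dilution factor, ...).  Spectra are stably sorted by
    retention time at construction."""

    spectra: list[Spectrum] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spectra = sorted(self.spectra, key=lambda s: s.retention_time)

    def __len__(self) -> int:
        return len(self.spectra)

    def ms2_spectra(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 2]

    def ms1_spectra(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 1]


# ---------------------------------------------------------------------------
# intensity cutoff
# ---------------------------------------------------------------------------

def apply_intensity_cutoff(spectrum: Spectrum, cutoff_factor: float) -> Spectrum:
    """Drop peaks below ``cutoff_factor`` x base-peak intensity.

    The threshold is relative to the most intense peak of the spectrum,
    so the operation is invariant to uniform intensity scaling and the
    base peak is always retained.  Ties at the boundary are kept
    (``>=``).  An empty spectrum passes through unchanged.
    """
    if not 0 <= cutoff_factor < 1:
        raise DomainError(
            f"cutoff_factor must be in [0, 1), got {cutoff_factor}")
    if spectrum.n_peaks == 0 or cutoff_factor == 0:
        return spectrum
    threshold = cutoff_factor * spectrum.base_peak_intensity
    keep = spectrum.intensities >= threshold
    return spectrum.with_peaks(spectrum.mz[keep], spectrum.intensities[keep])


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------

def read_mgf(path: str | Path) -> Run:
    """Read an MGF file into a :class:`Run`.

    ``PEPMASS`` maps to ``precursor_mz``, ``RTINSECONDS`` to
    ``retention_time``; a missing ``COLLISION_ENERGY`` defaults to
    35 eV (the acquisition value).  An empty file yields an empty run.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[Spectrum] = []
    try:
        with _mgf.read(str(path), use_index=False) as reader:
            for i, rec in enumerate(reader):
                spectra.append(_spectrum_from_mgf_record(rec, i))
    except ParseError:
        raise
    except Exception as exc:  # pyteomics raises plain ValueErrors
        raise ParseError(
            f"{path}: malformed MGF near block {len(spectra) + 1}: {exc}"
        ) from exc
    return Run(spectra=spectra, metadata={"source": str(path)})


def _spectrum_from_mgf_record(rec: dict, index: int) -> Spectrum:
    params = rec.get("params", {})
    pepmass = params.get("pepmass")
    precursor = float(pepmass[0]) if pepmass is not None else None
    ms_level = int(params.get("mslevel", 2))
    ce = params.get("collision_energy")
    if ce is not None:
        ce = float(ce)
    elif ms_level == 2:
        ce = DEFAULT_COLLISION_ENERGY
    return Spectrum(
        mz=rec["m/z array"],
        intensities=rec["intensity array"],
        precursor_mz=precursor,
        retention_time=float(params.get("rtinseconds", 0.0)),
        collision_energy=ce,
        ms_level=ms_level,
        scan_id=str(params.get("title", f"index={index}")),
    )


def write_mgf(run: Run, path: str | Path) -> Path:
    """Write a run as MGF; inverse of :func:`read_mgf` to 6 decimals.

    MS1 spectra are written with ``MSLEVEL=1`` and no ``PEPMASS`` so
    that the full run round-trips.
    """
    path = Path(path)
    records = []
    for spec in run.spectra:
        params: dict = {"title": spec.scan_id,
                        "rtinseconds": spec.retention_time,
                        "mslevel": spec.ms_level}
        if spec.precursor_mz is not None:
            params["pepmass"] = spec.precursor_mz
        if spec.collision_energy is not None:
            params["collision_energy"] = spec.collision_energy
        records.append({"m/z array": spec.mz,
                        "intensity array": spec.intensities,
                        "params": params})
    with path.open("w") as handle:
        _mgf.write(records, handle, write_charges=False,
                   fragment_format="%.6f %.6f")
    return path


# ---------------------------------------------------------------------------
# mzML / mzml-lite
# ---------------------------------------------------------------------------

_LITE_ROOT = "mzml_lite"


def write_mzml_lite(run: Run, path: str | Path) -> Path:
    """Write the simplified centroided-run XML dialect.

    Layout: ``<mzml_lite><spectrum msLevel rt ce precursorMz scanId>``
    with one ``mz intensity`` pair per line of text.  Numeric fields use
    ``repr`` so the reader reproduces the in-memory run exactly.
    """
    path = Path(path)
    root = ET.Element(_LITE_ROOT)
    for key, value in run.metadata.items():
        root.set(str(key), str(value))
    for spec in run.spectra:
        el = ET.SubElement(root, "spectrum")
        el.set("msLevel", str(spec.ms_level))
        el.set("rt", repr(float(spec.retention_time)))
        el.set("scanId", spec.scan_id)
        if spec.precursor_mz is not None:
            el.set("precursorMz", repr(float(spec.precursor_mz)))
        if spec.collision_energy is not None:
            el.set("ce", repr(float(spec.collision_energy)))
        el.text = "\n".join(
            f"{float(m)!r} {float(i)!r}"
            for m, i in zip(spec.mz, spec.intensities))
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)
    return path


def read_mzml_lite(path: str | Path) -> Run:
    """Read centroided mzML (standard, via pyteomics) or the simplified
    dialect written by :func:`write_mzml_lite`.

    Profile-mode mzML raises :class:`UnsupportedDialectError`; the
    workflow assumes centroided data.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        root_tag = next(ET.iterparse(str(path), events=("start",)))[1].tag
    except ET.ParseError as exc:
        raise ParseError(f"{path}: not well-formed XML: {exc}") from exc
    if root_tag == _LITE_ROOT:
        return _read_lite(path)
    if root_tag.rsplit("}", 1)[-1] in ("mzML", "indexedmzML"):
        return _read_standard_mzml(path)
    raise UnsupportedDialectError(f"{path}: unrecognised root element {root_tag!r}")


def _read_lite(path: Path) -> Run:
    root = ET.parse(str(path)).getroot()
    spectra = []
    for el in root.iter("spectrum"):
        pairs = [line.split() for line in (el.text or "").split("\n") if line.strip()]
        mz = np.array([float(p[0]) for p in pairs])
        inten = np.array([float(p[1]) for p in pairs])
        prec = el.get("precursorMz")
        ce = el.get("ce")
        spectra.append(Spectrum(
            mz=mz, intensities=inten,
            precursor_mz=float(prec) if prec is not None else None,
            retention_time=float(el.get("rt", "0")),
            collision_energy=float(ce) if ce is not None else None,
            ms_level=int(el.get("msLevel", "2")),
            scan_id=el.get("scanId", ""),
        ))
    return Run(spectra=spectra, metadata=dict(root.attrib))


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(element: ET.Element) -> dict[str, str]:
    return {child.get("name", ""): child.get("value", "")
            for child in element if _local(child.tag) == "cvParam"}


def _decode_binary_array(array_el: ET.Element) -> tuple[np.ndarray, dict]:
    params = {}
    payload = b""
    for child in array_el.iter():
        if _local(child.tag) == "cvParam":
            params[child.get("name", "")] = child.get("value", "")
        elif _local(child.tag) == "binary":
            payload = base64.b64decode((child.text or "").strip())
    if "zlib compression" in params:
        payload = zlib.decompress(payload)
    dtype = np.float32 if "32-bit float" in params else np.float64
    return np.frombuffer(payload, dtype=dtype).astype(float), params


def _read_standard_mzml(path: Path) -> Run:
    """Minimal reader for standard centroided mzML: decodes the
    uncompressed or zlib-compressed 32/64-bit float binary arrays and
    the scan/precursor cvParams the workflow needs."""
    spectra = []
    root = ET.parse(str(path)).getroot()
    for spec_el in root.iter():
        if _local(spec_el.tag) != "spectrum":
            continue
        params = _cv_params(spec_el)
        if "profile spectrum" in params:
            raise UnsupportedDialectError(
                f"{path}: profile-mode spectra are not supported; "
                "centroid with MSConvert first")
        ms_level = int(params.get("ms level", 2))
        rt, precursor, ce = 0.0, None, None
        mz = inten = None
        for el in spec_el.iter():
            tag = _local(el.tag)
            if tag == "scan":
                for child in el:
                    if (_local(child.tag) == "cvParam"
                            and child.get("name") == "scan start time"):
                        rt = float(child.get("value", "0"))
                        if child.get("unitName", "minute") == "minute":
                            rt *= 60.0
            elif tag == "selectedIon":
                value = _cv_params(el).get("selected ion m/z")
                if value is not None:
                    precursor = float(value)
            elif tag == "activation":
                value = _cv_params(el).get("collision energy")
                if value is not None:
                    ce = float(value)
            elif tag == "binaryDataArray":
                arr, arr_params = _decode_binary_array(el)
                if "m/z array" in arr_params:
                    mz = arr
                elif "intensity array" in arr_params:
                    inten = arr
        if mz is None or inten is None:
            raise ParseError(
                f"{path}: spectrum {spec_el.get('id')!r} lacks m/z or "
                "intensity arrays")
        if ms_level == 2 and ce is None:
            ce = DEFAULT_COLLISION_ENERGY
        spectra.append(Spectrum(
            mz=mz, intensities=inten, precursor_mz=precursor,
            retention_time=rt, collision_energy=ce, ms_level=ms_level,
            scan_id=str(spec_el.get("id", spec_el.get("index", "")))))
    return Run(spectra=spectra, metadata={"source": str(path)})


# ---------------------------------------------------------------------------
# plain-text peak-list export
# ---------------------------------------------------------------------------

def export_ascii_peaklists(run: Run, directory: str | Path,
                           ms_level: int = 2) -> list[Path]:
    """Write one plain-text peak list per spectrum: a header line
    ``precursor_mz rt ce`` followed by tab-separated mz/intensity rows.
    This is the exchange form handed to the library-search engine."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for i, spec in enumerate(run.spectra):
        if spec.ms_level != ms_level:
            continue
        name = spec.scan_id.replace("/", "_").replace(" ", "_") or f"spectrum_{i}"
        target = directory / f"{name}.txt"
        with target.open("w") as fh:
            fh.write(f"{spec.precursor_mz or 0.0:.6f} "
                     f"{spec.retention_time:.3f} "
                     f"{spec.collision_energy or 0.0:.1f}\n")
            for m, inten in zip(spec.mz, spec.intensities):
                fh.write(f"{m:.6f}\t{inten:.6f}\n")
        written.append(target)
    return written
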