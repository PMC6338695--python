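"""Multi-collision-energy tandem mass spectral reference library.

Each library entry pairs one compound (name, [M+H]+ m/z, octanol-water
logP) with curated product-ion spectra acquired across a grid of
collision energies (5-50 eV), covering the compound's breakdown curve.
Libraries persist as MSP-like text, one record per reference spectrum,
grouped by compound id.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ConsistencyError, ParseError
from .spectra import Spectrum, apply_intensity_cutoff

#: Precursor m/z agreement required between a compound record and each
#: of its reference spectra, Th.
PRECURSOR_CONSISTENCY_TOL = 0.01
#: Collision-energy range spanned by the reference spectra, eV.
CE_RANGE = (5.0, 50.0)


@dataclass(frozen=True)
class CompoundRecord:
    """Identity metadata for one library compound."""

    name: str
    precursor_mz: float  # [M+H]+, Th
    compound_id: str
    logp: float | None = None

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ConsistencyError(
                f"{self.compound_id}: precursor_mz must be > 0")


@dataclass(frozen=True)
class LibraryEntry:
    """One compound plus its curated reference spectra, sorted by CE."""

    compound: CompoundRecord
    reference_spectra: tuple[Spectrum, ...]

    def __post_init__(self) -> None:
        spectra = tuple(sorted(self.reference_spectra,
                               key=lambda s: s.collision_energy or 0.0))
        if not spectra:
            raise ConsistencyError(
                f"{self.compound.compound_id}: entry needs >= 1 reference spectrum")
        seen_ce = set()
        for spec in spectra:
            ce = spec.collision_energy
            if ce is None or not CE_RANGE[0] <= ce <= CE_RANGE[1]:
                raise ConsistencyError(
                    f"{self.compound.compound_id}: collision energy {ce} "
                    f"outside {CE_RANGE}")
            if ce in seen_ce:
                raise ConsistencyError(
                    f"{self.compound.compound_id}: duplicate collision energy {ce}")
            seen_ce.add(ce)
            if spec.precursor_mz is None or abs(
                    spec.precursor_mz - self.compound.precursor_mz
            ) > PRECURSOR_CONSISTENCY_TOL:
                raise ConsistencyError(
                    f"{self.compound.compound_id}: spectrum {spec.scan_id!r} "
                    f"precursor {spec.precursor_mz} inconsistent with compound "
                    f"precursor {self.compound.precursor_mz}")
        object.__setattr__(self, "reference_spectra", spectra)

    @property
    def collision_energies(self) -> tuple[float, ...]:
        return tuple(s.collision_energy for s in self.reference_spectra)


@dataclass
class SpectralLibrary:
    entries: list[LibraryEntry] = field(default_factory=list)
    version: str = "0"

    def __post_init__(self) -> None:
        ids = [e.compound.compound_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise ConsistencyError(f"duplicate compound ids: {sorted(dupes)}")
        self._precursors = np.array(
            [e.compound.precursor_mz for e in self.entries])

    @property
    def n_entries(self) -> int:
        return len(self.entries)

    @property
    def n_spectra(self) -> int:
        return sum(len(e.reference_spectra) for e in self.entries)

    @property
    def precursor_array(self) -> np.ndarray:
        """Entry precursor m/z values in library order (for candidate
        filtering)."""
        return self._precursors

    def __iter__(self):
        return iter(self.entries)

    def get(self, compound_id: str) -> LibraryEntry | None:
        for entry in self.entries:
            if entry.compound.compound_id == compound_id:
                return entry
        return None

    @property
    def compound_ids(self) -> set[str]:
        return {e.compound.compound_id for e in self.entries}


# ---------------------------------------------------------------------------
# curation
# ---------------------------------------------------------------------------

def curate_spectrum(spectrum: Spectrum,
                    cutoff_factor: float = 0.01,
                    noise_mzs: Iterable[float] = (),
                    mz_match_tol: float = 0.01) -> Spectrum:
    """Curate a raw product-ion spectrum for the library: drop
    low-abundance peaks (below ``cutoff_factor`` x base peak), then
    remove known-unspecific signals (solvent/background ions) within
    ``mz_match_tol`` of any m/z on the exclusion list.

    The two stages are ordered so the base peak survives the intensity
    cutoff but can still be removed if it is itself a listed background
    ion.  Idempotent and order-stable.
    """
    out = apply_intensity_cutoff(spectrum, cutoff_factor)
    noise = np.asarray(sorted(noise_mzs), dtype=float)
    if noise.size == 0 or out.n_peaks == 0:
        return out
    dist = np.abs(out.mz[:, None] - noise[None, :]).min(axis=1)
    keep = dist > mz_match_tol
    return out.with_peaks(out.mz[keep], out.intensities[keep])


def build_entry(compound: CompoundRecord,
                raw_spectra: Sequence[Spectrum],
                cutoff_factor: float = 0.01,
                noise_mzs: Iterable[float] = (),
                mz_match_tol: float = 0.01) -> LibraryEntry:
    """Curate a set of raw product-ion spectra into a library entry.

    Every raw spectrum must carry the compound's precursor within
    +/-0.01 Th and a distinct collision energy; violations raise
    :class:`ConsistencyError` naming the offending spectrum.
    """
    for spec in raw_spectra:
        if spec.precursor_mz is None or abs(
                spec.precursor_mz - compound.precursor_mz
        ) > PRECURSOR_CONSISTENCY_TOL:
            raise ConsistencyError(
                f"{compound.compound_id}: raw spectrum {spec.scan_id!r} "
                f"precursor {spec.precursor_mz} does not match compound "
                f"precursor {compound.precursor_mz} within "
                f"{PRECURSOR_CONSISTENCY_TOL}")
    curated = tuple(
        curate_spectrum(s, cutoff_factor, noise_mzs, mz_match_tol)
        for s in raw_spectra)
    return LibraryEntry(compound=compound, reference_spectra=curated)


# ---------------------------------------------------------------------------
# MSP-like persistence (matchms-backed)
# ---------------------------------------------------------------------------

_NUM_PEAKS_RE = re.compile(r"^num\s*peaks\s*:\s*(\d+)", re.IGNORECASE)
_PEAK_LINE_RE = re.compile(r"^\s*\d+(?:\.\d+)?[\s;]+\d")
_FIELD_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_ ]*:")


def _validate_msp_text(path: Path) -> None:
    """Strict structural pass matchms does not perform: every record
    must declare PrecursorMZ, and the peak-line count must equal the
    declared ``Num Peaks``."""
    declared: int | None = None
    counted = 0
    start_line = 0
    has_precursor = False
    in_record = False

    def close(line_no: int) -> None:
        if declared is not None and counted != declared:
            raise ParseError(
                f"{path}:{start_line}: record declares 'Num Peaks: {declared}' "
                f"but contains {counted} peak lines")
        if in_record and not has_precursor:
            raise ParseError(
                f"{path}:{start_line}: record is missing PrecursorMZ")

    with Path(path).open() as fh:
        for line_no, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if _FIELD_RE.match(stripped):
                m = _NUM_PEAKS_RE.match(stripped)
                if m:
                    declared = int(m.group(1))
                    counted = 0
                elif stripped.lower().startswith(("name:", "compound_name:")):
                    close(line_no)
                    in_record = True
                    has_precursor = False
                    declared = None
                    counted = 0
                    start_line = line_no
                if re.match(r"^precursor[_ ]?mz\s*:", stripped, re.IGNORECASE):
                    has_precursor = True
            elif declared is not None and _PEAK_LINE_RE.match(stripped):
                counted += 1
    close(line_no if "line_no" in locals() else 0)


def write_msp(library: SpectralLibrary, path: str | Path) -> Path:
    """Persist a library as MSP-like text, one record per reference
    spectrum carrying Name, CompoundID, PrecursorMZ, CollisionEnergy and
    LogP.  An empty library yields an empty file."""
    from matchms import Spectrum as MatchmsSpectrum
    from matchms.exporting import save_as_msp

    path = Path(path)
    if path.exists():
        path.unlink()  # save_as_msp appends
    records = []
    for entry in library.entries:
        comp = entry.compound
        for spec in entry.reference_spectra:
            meta = {
                "compound_name": comp.name,
                "compound_id": comp.compound_id,
                "precursor_mz": float(comp.precursor_mz),
                "collision_energy": float(spec.collision_energy),
            }
            if comp.logp is not None:
                meta["logp"] = float(comp.logp)
            records.append(MatchmsSpectrum(
                mz=spec.mz.astype(float), intensities=spec.intensities.astype(float),
                metadata=meta, metadata_harmonization=False))
    if records:
        save_as_msp(records, str(path))
    else:
        path.write_text("")
    return path


def read_msp(path: str | Path) -> SpectralLibrary:
    """Read an MSP-like library file; inverse of :func:`write_msp`."""
    from matchms.importing import load_from_msp

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not path.read_text().strip():
        return SpectralLibrary(entries=[])
    _validate_msp_text(path)

    grouped: dict[str, dict] = {}
    for rec in load_from_msp(str(path), metadata_harmonization=True):
        meta = rec.metadata
        cid = str(meta.get("compound_id") or meta.get("compound_name"))
        precursor = meta.get("precursor_mz")
        if precursor is None:
            raise ParseError(f"{path}: record {cid!r} lacks PrecursorMZ")
        logp = meta.get("logp")
        group = grouped.setdefault(cid, {
            "name": str(meta.get("compound_name", cid)),
            "precursor_mz": float(precursor),
            "logp": float(logp) if logp is not None else None,
            "spectra": [],
        })
        ce = meta.get("collision_energy")
        group["spectra"].append(Spectrum(
            mz=rec.peaks.mz, intensities=rec.peaks.intensities,
            precursor_mz=float(precursor),
            collision_energy=float(ce) if ce is not None else None,
            ms_level=2,
            scan_id=f"{cid}_ce{float(ce):g}" if ce is not None else cid,
        ))
    entries = []
    for cid, group in grouped.items():
        compound = CompoundRecord(name=group["name"],
                                  precursor_mz=group["precursor_mz"],
                                  compound_id=cid, logp=group["logp"])
        entries.append(LibraryEntry(compound=compound,
                                    reference_spectra=tuple(group["spectra"])))
    return SpectralLibrary(entries=entries)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibraryStats:
    n_entries: int
    n_spectra: int
    ce_histogram: dict  # collision energy -> spectrum count
    n_with_logp: int
    logp_range: tuple[float, float] | None


def library_stats(library: SpectralLibrary) -> LibraryStats:
    """Entry/spectrum counts, collision-energy coverage histogram, and
    logP coverage of a library."""
    ce_hist: dict[float, int] = {}
    for entry in library.entries:
        for ce in entry.collision_energies:
            ce_hist[ce] = ce_hist.get(ce, 0) + 1
    logps = [e.compound.logp for e in library.entries
             if e.compound.logp is not None]
    return LibraryStats(
        n_entries=library.n_entries,
        n_spectra=library.n_spectra,
        ce_histogram=dict(sorted(ce_hist.items())),
        n_with_logp=len(logps),
        logp_range=(min(logps), max(logps)) if logps else None,
    )
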