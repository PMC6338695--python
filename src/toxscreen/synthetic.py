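"""Synthetic QqTOF DDA data: reference libraries, matrix background,
spiked runs and dilution series.

This module stands in for the wet lab.  It emulates, at the level of
centroided peak lists, the acquisition behaviour that drives the
screening workflow's performance characteristics:

* **Breakdown curves** — each analyte carries a fragment template whose
  intensities follow smooth unimodal functions of collision energy
  (rise after an appearance energy, fall at high energy) while the
  precursor survival decays; reference spectra are generated on the
  10-step 5-50 eV grid.
* **DDA duty cycle** — one survey scan followed by the top-N (default
  8) most intense precursors above a 100-count trigger threshold, with
  dynamic exclusion for 30 s after 2 selections; acquisition spectra
  are drawn at 35 eV with a +/-10 eV collision-energy spread (modelled
  by averaging the template over 30-40 eV).
* **Matrix background** — broadly eluting background ions, a
  configurable fraction with fractional isotope spacing emulating
  multiply charged salivary peptides, competing for duty cycles.
* **Dilution series** — the seven standard spiking levels; MS1 response
  scales with the neat-oral-fluid concentration because the workflow
  normalises every specimen to the same neat-volume equivalent before
  extraction, which is why the extraction-dilution factor does not
  affect detectability.

Every generator is a pure function of its parameters and a seed.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConsistencyError, DomainError
from .library import CompoundRecord, LibraryEntry, SpectralLibrary, build_entry
from .spectra import (MS1_SCAN_RANGE, MS2_SCAN_RANGE, Run, Spectrum)

#: Reference-library collision-energy grid, eV.
DEFAULT_CE_GRID = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0)
#: Standard spiking levels, ng/mL neat oral fluid.
STANDARD_LEVELS = (1.0, 2.5, 5.0, 10.0, 25.0, 50.0, 100.0)
#: Default multiplicative (log-normal sigma) intensity noise of MS2 peaks.
DEFAULT_MS2_NOISE_SIGMA = 0.15
#: Default shot-to-shot multiplicative noise of MS1 responses.
DEFAULT_MS1_NOISE_SIGMA = 0.10
#: Counts below which simulated peaks fall under the detection floor.
INTENSITY_FLOOR = 1.0


@dataclass(frozen=True)
class FragmentTemplate:
    """One product ion of an analyte's breakdown curve."""

    mz: float
    appearance_ce: float  # eV at which the fragment starts to form
    max_rel_intensity: float  # peak of the curve, relative to precursor base


@dataclass(frozen=True)
class AnalyteProfile:
    """Ground-truth model of one compound: identity, fragmentation
    template, chromatographic peak and MS1 response factor."""

    compound: CompoundRecord
    fragments: tuple[FragmentTemplate, ...]
    rt_apex: float  # s
    rt_width: float  # gaussian sigma, s
    height_per_ng_ml: float  # MS1 apex counts per ng/mL neat concentration

    def __post_init__(self) -> None:
        if self.height_per_ng_ml <= 0:
            raise DomainError("height_per_ng_ml must be > 0")
        for frag in self.fragments:
            if frag.mz >= self.compound.precursor_mz + 0.5:
                raise ConsistencyError(
                    f"{self.compound.compound_id}: fragment {frag.mz} above "
                    f"precursor {self.compound.precursor_mz}")

    # -- breakdown model ----------------------------------------------
    def fragment_intensity(self, frag: FragmentTemplate, ce: float) -> float:
        """Unimodal log-normal-shaped curve in (ce - appearance_ce):
        zero at and below the appearance energy, maximal ~12 eV above
        it, declining at high energy."""
        x = ce - frag.appearance_ce
        if x <= 0:
            return 0.0
        return frag.max_rel_intensity * math.exp(
            -0.5 * (math.log(x / 12.0) / 0.7) ** 2)

    def precursor_survival(self, ce: float) -> float:
        """Fraction of the precursor surviving activation at ``ce``."""
        return math.exp(-max(ce - 5.0, 0.0) / 12.0)

    def template_at(self, ce: float, ce_spread: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        """Relative peak list at one collision energy; with a spread,
        intensities are averaged over [ce - spread/2, ce + spread/2]
        (5-point grid), emulating a collision-energy ramp."""
        if ce_spread > 0:
            ces = np.linspace(ce - ce_spread / 2.0, ce + ce_spread / 2.0, 5)
        else:
            ces = [ce]
        mzs = [self.compound.precursor_mz] + [f.mz for f in self.fragments]
        rels = np.zeros(len(mzs))
        for c in ces:
            rels[0] += self.precursor_survival(c)
            for k, frag in enumerate(self.fragments, start=1):
                rels[k] += self.fragment_intensity(frag, c)
        rels /= len(ces)
        return np.asarray(mzs), rels

    # -- (de)serialisation for manifests / CLI ------------------------
    def to_dict(self) -> dict:
        return {
            "compound_id": self.compound.compound_id,
            "name": self.compound.name,
            "precursor_mz": self.compound.precursor_mz,
            "logp": self.compound.logp,
            "fragments": [[f.mz, f.appearance_ce, f.max_rel_intensity]
                          for f in self.fragments],
            "rt_apex": self.rt_apex,
            "rt_width": self.rt_width,
            "height_per_ng_ml": self.height_per_ng_ml,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "AnalyteProfile":
        return cls(
            compound=CompoundRecord(
                name=data["name"], precursor_mz=data["precursor_mz"],
                compound_id=data["compound_id"], logp=data.get("logp")),
            fragments=tuple(FragmentTemplate(*f) for f in data["fragments"]),
            rt_apex=data["rt_apex"], rt_width=data["rt_width"],
            height_per_ng_ml=data["height_per_ng_ml"])


@dataclass(frozen=True)
class DdaParams:
    """Duty-cycle parameters of the data-dependent acquisition."""

    top_n: int = 8
    trigger_threshold: float = 100.0  # counts
    exclusion_after: int = 2  # selections before exclusion starts
    exclusion_window: float = 30.0  # s
    survey_range: tuple[float, float] = MS1_SCAN_RANGE
    msms_range: tuple[float, float] = MS2_SCAN_RANGE
    ce: float = 35.0  # eV
    ce_spread: float = 10.0  # eV, full width
    accumulation_time: float = 0.1  # s per scan
    cycle_overhead: float = 0.05  # s

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise DomainError("top_n must be >= 1")
        if self.trigger_threshold <= 0 or self.exclusion_window <= 0:
            raise DomainError("thresholds must be positive")

    @property
    def cycle_time(self) -> float:
        """Duration of one duty cycle: (1 + top_n) accumulations plus
        overhead."""
        return (1 + self.top_n) * self.accumulation_time + self.cycle_overhead


# ---------------------------------------------------------------------------
# reference spectra and libraries
# ---------------------------------------------------------------------------

def _child_rng(seed: int, *keys: object) -> np.random.Generator:
    """Deterministic per-object generator derived from (seed, keys).
    Uses a stable digest (not ``hash()``) so results are reproducible
    across processes."""
    digest = zlib.crc32(repr(keys).encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence((seed, digest)))


def generate_breakdown_spectra(profile: AnalyteProfile,
                               ce_grid: Sequence[float] = DEFAULT_CE_GRID,
                               seed: int = 0,
                               base_intensity: float = 1000.0,
                               jitter_sigma: float = 0.05) -> list[Spectrum]:
    """Reference product-ion spectra of one compound across a collision
    energy grid, one spectrum per CE, with a small multiplicative
    log-normal jitter.  Deterministic given the seed."""
    if not ce_grid:
        raise DomainError("ce_grid must be non-empty")
    spectra = []
    for ce in ce_grid:
        rng = _child_rng(seed, profile.compound.compound_id, float(ce))
        mzs, rels = profile.template_at(float(ce))
        inten = rels * base_intensity
        if jitter_sigma > 0:
            inten = inten * rng.lognormal(0.0, jitter_sigma, size=inten.size)
        keep = ((inten >= INTENSITY_FLOOR)
                & (mzs >= MS2_SCAN_RANGE[0]) & (mzs <= MS2_SCAN_RANGE[1]))
        spectra.append(Spectrum(
            mz=mzs[keep], intensities=inten[keep],
            precursor_mz=profile.compound.precursor_mz,
            retention_time=profile.rt_apex,
            collision_energy=float(ce), ms_level=2,
            scan_id=f"{profile.compound.compound_id}_ce{ce:g}"))
    return spectra


def generate_library(n_compounds: int,
                     seed: int = 0,
                     precursor_range: tuple[float, float] = (150.0, 650.0),
                     isobar_fraction: float = 0.0,
                     ce_grid: Sequence[float] = DEFAULT_CE_GRID,
                     run_duration: float = 300.0,
                     cutoff_factor: float = 0.01,
                     ) -> tuple[SpectralLibrary, dict[str, AnalyteProfile]]:
    """Generate a curated reference library plus its ground-truth
    analyte profiles.

    ``isobar_fraction`` of the compounds are arranged into pairs whose
    precursors agree within 0.01 Th (stressing the relative score);
    all other precursors are kept > 0.05 Th apart.
    """
    if n_compounds < 1:
        raise DomainError("n_compounds must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    n_paired = int(isobar_fraction * n_compounds) // 2 * 2

    precursors: list[float] = []
    while len(precursors) < n_compounds - n_paired // 2:
        cand = float(rng.uniform(*precursor_range))
        if all(abs(cand - p) > 0.05 for p in precursors):
            precursors.append(cand)
    # isobaric partners duplicate the first n_paired/2 precursors
    for i in range(n_paired // 2):
        precursors.append(precursors[i] + float(rng.uniform(-0.008, 0.008)))

    profiles: dict[str, AnalyteProfile] = {}
    entries: list[LibraryEntry] = []
    for i, prec in enumerate(precursors):
        cid = f"CPD{i:04d}"
        n_frag = int(rng.integers(4, 9))
        frag_mzs: list[float] = []
        while len(frag_mzs) < n_frag:
            cand = float(rng.uniform(60.0, prec - 20.0))
            if all(abs(cand - m) > 0.2 for m in frag_mzs):
                frag_mzs.append(cand)
        fragments = tuple(
            FragmentTemplate(
                mz=m,
                appearance_ce=float(rng.uniform(5.0, 30.0)),
                max_rel_intensity=float(rng.uniform(0.2, 1.0)))
            for m in sorted(frag_mzs))
        compound = CompoundRecord(
            name=f"compound-{i:04d}", precursor_mz=prec, compound_id=cid,
            logp=float(np.round(rng.normal(2.8, 1.6), 2)))
        profile = AnalyteProfile(
            compound=compound, fragments=fragments,
            rt_apex=float(rng.uniform(0.1, 0.9) * run_duration),
            rt_width=float(rng.uniform(3.0, 5.0)),
            height_per_ng_ml=float(rng.lognormal(math.log(40.0), 0.5)))
        profiles[cid] = profile
        raw = generate_breakdown_spectra(profile, ce_grid, seed=seed)
        entries.append(build_entry(compound, raw, cutoff_factor=cutoff_factor))
    library = SpectralLibrary(entries=entries, version=f"synthetic-seed{seed}")
    return library, profiles


def generate_query_spectra(profile: AnalyteProfile,
                           n: int = 10,
                           seed: int = 0,
                           ce: float = 35.0,
                           ce_spread: float = 10.0,
                           base_intensity: float = 1000.0,
                           noise_sigma: float = DEFAULT_MS2_NOISE_SIGMA,
                           mz_jitter: float = 0.002) -> list[Spectrum]:
    """Noisy acquisition-like product-ion spectra of one analyte at the
    working collision energy (template averaged over the CE spread),
    with multiplicative log-normal intensity noise and a small gaussian
    precursor m/z error."""
    rng = _child_rng(seed, "query", profile.compound.compound_id)
    mzs, rels = profile.template_at(ce, ce_spread)
    queries = []
    for k in range(n):
        inten = rels * base_intensity * rng.lognormal(0.0, noise_sigma,
                                                      size=rels.size)
        keep = ((inten >= INTENSITY_FLOOR)
                & (mzs >= MS2_SCAN_RANGE[0]) & (mzs <= MS2_SCAN_RANGE[1]))
        prec = profile.compound.precursor_mz + float(rng.normal(0.0, mz_jitter))
        queries.append(Spectrum(
            mz=mzs[keep], intensities=inten[keep], precursor_mz=prec,
            retention_time=profile.rt_apex, collision_energy=ce, ms_level=2,
            scan_id=f"{profile.compound.compound_id}_q{k}"))
    return queries


# ---------------------------------------------------------------------------
# matrix background
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatrixPeak:
    mz: float
    intensity: float  # mean survey intensity, counts
    phase: float  # slow elution-envelope phase, radians
    charge: int  # 1 for singly charged chemical noise, >1 for peptides


@dataclass(frozen=True)
class MatrixBackground:
    """Broadly eluting background-ion model for blank oral-fluid
    matrix.  ``ms1_peaks(t)`` returns the survey peak list at time t;
    the envelope never drops to zero, so a blank-matrix run's TIC stays
    strictly above a reagent blank's at all times."""

    peaks: tuple[MatrixPeak, ...]
    envelope_period: float = 240.0  # s

    def ms1_peaks(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        if not self.peaks:
            return np.empty(0), np.empty(0)
        mz = np.array([p.mz for p in self.peaks])
        mean = np.array([p.intensity for p in self.peaks])
        phase = np.array([p.phase for p in self.peaks])
        envelope = 0.6 + 0.4 * np.sin(
            2.0 * math.pi * t / self.envelope_period + phase)
        return mz, mean * envelope

    def ms2_peaks(self, precursor_mz: float, intensity: float,
                  seed: int) -> tuple[np.ndarray, np.ndarray]:
        """Unspecific fragment list for a selected background precursor
        (deterministic in the precursor and seed)."""
        rng = _child_rng(seed, "matrix-ms2", round(precursor_mz, 3))
        n = int(rng.integers(3, 8))
        mz = rng.uniform(MS2_SCAN_RANGE[0], max(precursor_mz, 51.0), size=n)
        rel = rng.uniform(0.05, 0.6, size=n)
        return mz, rel * intensity


def generate_matrix_background(intensity_scale: float = 2000.0,
                               n_peaks: int = 60,
                               multiply_charged_fraction: float = 0.3,
                               seed: int = 0,
                               avoid_mzs: Sequence[float] = (),
                               avoid_tol: float = 0.011) -> MatrixBackground:
    """Generate a background model: ``n_peaks`` ions with log-normal
    mean intensities around ``intensity_scale``; a fraction appear as
    fractional-spacing isotope clusters (charge 2-3, emulating multiply
    charged salivary peptides).  Background m/z values stay clear of
    ``avoid_mzs`` (e.g. library precursors) by ``avoid_tol``."""
    if n_peaks < 0:
        raise DomainError("n_peaks must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    avoid = np.asarray(sorted(avoid_mzs), dtype=float)

    def clear(mz: float) -> bool:
        return avoid.size == 0 or np.abs(avoid - mz).min() > avoid_tol

    peaks: list[MatrixPeak] = []
    n_clusters = int(round(n_peaks * multiply_charged_fraction))
    while len(peaks) < n_peaks:
        remaining = n_peaks - len(peaks)
        charged = n_clusters > 0 and remaining >= 3
        base = float(rng.uniform(*MS1_SCAN_RANGE))
        intensity = float(rng.lognormal(math.log(intensity_scale), 0.6))
        phase = float(rng.uniform(0.0, 2.0 * math.pi))
        if charged:
            z = int(rng.integers(2, 4))
            spacing = 1.00335 / z
            cluster = [base + k * spacing for k in range(3)]
            if all(clear(m) and m <= MS1_SCAN_RANGE[1] for m in cluster):
                ratios = (1.0, 0.7, 0.4)
                for m, r in zip(cluster, ratios):
                    peaks.append(MatrixPeak(m, intensity * r, phase, z))
                n_clusters -= 1
        else:
            if clear(base):
                peaks.append(MatrixPeak(base, intensity, phase, 1))
    return MatrixBackground(peaks=tuple(peaks[:n_peaks]))


# ---------------------------------------------------------------------------
# DDA simulation
# ---------------------------------------------------------------------------

@dataclass
class SelectionEvent:
    time: float
    precursor_mz: float
    intensity: float
    source: str  # compound_id or "matrix"
    scan_id: str


@dataclass
class SimulationTruth:
    """Ground truth of one simulated run."""

    events: list[SelectionEvent] = field(default_factory=list)
    ms2_source: dict = field(default_factory=dict)  # scan_id -> source
    spiked: dict = field(default_factory=dict)  # compound_id -> ng/mL

    @property
    def analytes_with_ms2(self) -> set[str]:
        return {e.source for e in self.events if e.source != "matrix"}

    def selections_of(self, source: str) -> list[SelectionEvent]:
        return [e for e in self.events if e.source == source]


class _ExclusionList:
    """Dynamic-exclusion bookkeeping: a precursor is banned for
    ``window`` seconds once it has been selected ``after`` times; the
    occurrence count restarts when the ban expires."""

    def __init__(self, after: int, window: float, mz_tol: float = 0.02):
        self.after = after
        self.window = window
        self.mz_tol = mz_tol
        self._state: dict[float, list] = {}  # key mz -> [count, excluded_until]

    def _key(self, mz: float) -> float:
        for key in self._state:
            if abs(key - mz) <= self.mz_tol:
                return key
        return mz

    def is_excluded(self, mz: float, t: float) -> bool:
        state = self._state.get(self._key(mz))
        return state is not None and t < state[1]

    def record_selection(self, mz: float, t: float) -> None:
        key = self._key(mz)
        state = self._state.setdefault(key, [0, -math.inf])
        state[0] += 1
        if state[0] >= self.after:
            state[1] = t + self.window
            state[0] = 0


def simulate_dda_run(analytes: Sequence[tuple[AnalyteProfile, float]],
                     matrix: MatrixBackground | None = None,
                     dda: DdaParams = DdaParams(),
                     duration: float = 300.0,
                     seed: int = 0,
                     ms1_noise_sigma: float = DEFAULT_MS1_NOISE_SIGMA,
                     ms2_noise_sigma: float = DEFAULT_MS2_NOISE_SIGMA,
                     mz_jitter: float = 0.002,
                     ) -> tuple[Run, SimulationTruth]:
    """Simulate one DDA acquisition of spiked (analyte, ng/mL neat)
    pairs over a matrix background.

    Per duty cycle: a survey scan of all eluting species, then MS2 of
    the ``top_n`` most intense precursors at or above the trigger
    threshold that are not dynamically excluded.  MS2 spectra are drawn
    from the analyte's breakdown template at the working CE (averaged
    over the spread) scaled by the live precursor intensity, with
    multiplicative log-normal noise; background precursors yield
    unspecific fragment lists.  Returns the run plus the full
    selection-event ground truth.
    """
    if duration < dda.cycle_time:
        raise DomainError("duration must cover at least one duty cycle")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 3)))
    truth = SimulationTruth(
        spiked={p.compound.compound_id: conc for p, conc in analytes if conc > 0})
    exclusion = _ExclusionList(dda.exclusion_after, dda.exclusion_window)
    spectra: list[Spectrum] = []
    active = [(p, c) for p, c in analytes if c > 0]

    n_cycles = int(duration / dda.cycle_time)
    for cycle in range(n_cycles):
        t = cycle * dda.cycle_time
        mzs: list[float] = []
        intens: list[float] = []
        sources: list[str] = []
        templates: dict[int, AnalyteProfile] = {}
        for profile, conc in active:
            apex = conc * profile.height_per_ng_ml
            level = apex * math.exp(
                -0.5 * ((t - profile.rt_apex) / profile.rt_width) ** 2)
            if level < INTENSITY_FLOOR:
                continue
            level *= float(rng.lognormal(0.0, ms1_noise_sigma))
            mz_obs = profile.compound.precursor_mz + float(
                rng.normal(0.0, mz_jitter))
            if not dda.survey_range[0] <= mz_obs <= dda.survey_range[1]:
                continue
            templates[len(mzs)] = profile
            mzs.append(mz_obs)
            intens.append(level)
            sources.append(profile.compound.compound_id)
        if matrix is not None:
            bg_mz, bg_int = matrix.ms1_peaks(t)
            for m, i in zip(bg_mz, bg_int):
                if i >= INTENSITY_FLOOR:
                    mzs.append(float(m))
                    intens.append(float(i))
                    sources.append("matrix")

        ms1_id = f"cycle{cycle}_ms1"
        spectra.append(Spectrum(
            mz=np.array(mzs) if mzs else np.empty(0),
            intensities=np.array(intens) if intens else np.empty(0),
            precursor_mz=None, retention_time=t, collision_energy=None,
            ms_level=1, scan_id=ms1_id))

        # precursor selection: top-N above trigger, not excluded
        order = np.argsort(intens)[::-1] if intens else []
        selected = []
        for idx in order:
            if len(selected) >= dda.top_n:
                break
            if intens[idx] < dda.trigger_threshold:
                break  # sorted descending: nothing further qualifies
            if exclusion.is_excluded(mzs[idx], t):
                continue
            selected.append(int(idx))
        for rank, idx in enumerate(selected):
            exclusion.record_selection(mzs[idx], t)
            scan_id = f"cycle{cycle}_ms2_{rank}"
            rt = t + dda.accumulation_time * (1 + rank)
            if sources[idx] == "matrix":
                frag_mz, frag_int = matrix.ms2_peaks(mzs[idx], intens[idx],
                                                     seed)
            else:
                profile = templates[idx]
                frag_mz, rels = profile.template_at(dda.ce, dda.ce_spread)
                frag_int = rels * intens[idx]
            frag_int = frag_int * rng.lognormal(0.0, ms2_noise_sigma,
                                                size=frag_int.size)
            keep = ((frag_int >= INTENSITY_FLOOR)
                    & (frag_mz >= dda.msms_range[0])
                    & (frag_mz <= dda.msms_range[1]))
            spectrum = Spectrum(
                mz=np.asarray(frag_mz)[keep],
                intensities=np.asarray(frag_int)[keep],
                precursor_mz=mzs[idx], retention_time=rt,
                collision_energy=dda.ce, ms_level=2, scan_id=scan_id)
            spectra.append(spectrum)
            truth.events.append(SelectionEvent(
                time=t, precursor_mz=mzs[idx], intensity=intens[idx],
                source=sources[idx], scan_id=scan_id))
            truth.ms2_source[scan_id] = sources[idx]

    run = Run(spectra=spectra,
              metadata={"duration_s": duration, "seed": seed,
                        "n_cycles": n_cycles})
    return run, truth


# ---------------------------------------------------------------------------
# dilution experiments
# ---------------------------------------------------------------------------

def generate_dilution_experiment(profiles: Sequence[AnalyteProfile],
                                 levels: Sequence[float] = STANDARD_LEVELS,
                                 extraction_volume_ul: float = 400.0,
                                 v_oral_fluid_ul: float = 500.0,
                                 dda: DdaParams = DdaParams(),
                                 matrix: MatrixBackground | None = None,
                                 duration: float = 300.0,
                                 seed: int = 0,
                                 ) -> tuple[dict[float, Run], list[dict]]:
    """Simulate one spiked run per concentration level.

    The specimen model follows the collection-device workflow: oral
    fluid is mixed with the extraction solution (dilution factor
    (v_of + v_ext)/v_of), but a constant neat-oral-fluid equivalent is
    processed, so the on-column amount — and hence the simulated MS1
    response — depends only on the neat concentration.  The per-level
    child seeds depend on the seed and level alone, so two experiments
    differing only in extraction volume produce identical runs and
    identical detection ground truth.

    Returns ``{level: Run}`` plus a manifest with one row per compound
    and level: neat and in-device concentrations, dilution factor and
    expected detectability (noise-free apex response >= trigger).
    """
    if not levels:
        raise DomainError("levels must be non-empty")
    if extraction_volume_ul < 0 or v_oral_fluid_ul <= 0:
        raise DomainError("volumes must be positive")
    dilution_factor = (v_oral_fluid_ul + extraction_volume_ul) / v_oral_fluid_ul
    runs: dict[float, Run] = {}
    manifest: list[dict] = []
    for level in sorted(levels):
        child_seed = (seed * 1000 + int(round(level * 10))) % (2**31)
        analytes = [(p, float(level)) for p in profiles]
        run, truth = simulate_dda_run(
            analytes, matrix=matrix, dda=dda, duration=duration,
            seed=child_seed)
        run.metadata.update({
            "level_ngml": float(level),
            "extraction_volume_ul": extraction_volume_ul,
            "dilution_factor": dilution_factor,
        })
        runs[float(level)] = run
        for profile in profiles:
            apex = level * profile.height_per_ng_ml
            manifest.append({
                "compound_id": profile.compound.compound_id,
                "logp": profile.compound.logp,
                "level_ngml": float(level),
                "device_conc_ngml": float(level) / dilution_factor,
                "dilution_factor": dilution_factor,
                "expected_detectable": bool(apex >= dda.trigger_threshold),
                "got_ms2": profile.compound.compound_id
                           in truth.analytes_with_ms2,
            })
    return runs, manifest


def expected_loi(profile: AnalyteProfile,
                 levels: Sequence[float] = STANDARD_LEVELS,
                 trigger_threshold: float = 100.0) -> float | None:
    """The generating detectability threshold: the lowest level whose
    noise-free apex MS1 response reaches the trigger threshold."""
    for level in sorted(levels):
        if level * profile.height_per_ng_ml >= trigger_threshold:
            return float(level)
    return None
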