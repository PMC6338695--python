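"""Tandem mass spectral library search with match-probability scoring.

The identification engine proceeds in four stages:

1. **Candidate filtering** — library entries whose [M+H]+ m/z lies
   within an absolute precursor tolerance (default +/-0.01 Th) of the
   query's selected-ion m/z.
2. **Per-spectrum similarity** — a 0-100 score between the query and
   one reference spectrum: peaks are matched one-to-one within an m/z
   tolerance by an optimal (Hungarian) assignment maximising the summed
   geometric mean of matched intensities, and the score is

       100 * sum_matched sqrt(Iq * Ir) / sqrt(sum(Iq) * sum(Ir)),

   i.e. the cosine similarity of square-root-scaled intensity vectors.
   The score is symmetric, invariant to uniform intensity scaling, and
   100 exactly when the spectra are identical up to scaling.
3. **Compound-level scoring** — the *match probability* ``amp`` against
   a compound's multi-collision-energy reference set (best-matching
   reference spectrum by default; see :class:`SearchParams`), and the
   *relative* score ``ramp`` = 100 * amp / (sum of amps over all
   precursor-matched candidates), expressing how strongly the compound
   dominates its isobaric competitors.
4. **Decision rule** — a tentative positive identification requires
   amp > 5.0, ramp > 40.0 and precursor error within tolerance; expert
   review then confirms or rejects each tentative hit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import ContractViolation, DomainError
from .library import LibraryEntry, SpectralLibrary
from .spectra import Run, Spectrum, apply_intensity_cutoff


@dataclass(frozen=True)
class SearchParams:
    """Search-engine parameters.

    Defaults follow the screening workflow: absolute precursor and
    fragment m/z tolerances of 0.01 Th, relative intensity cutoff 0.01,
    and positive-identification thresholds amp > 5.0, ramp > 40.0
    (strict inequalities).

    ``amp_aggregate`` selects how per-reference-spectrum similarities
    combine into the compound score: ``"best"`` (default) takes the
    best-matching collision energy, ``"mean"`` averages over the whole
    breakdown-curve set.
    """

    precursor_tol: float = 0.01
    mz_match_tol: float = 0.01
    intensity_cutoff_factor: float = 0.01
    amp_threshold: float = 5.0
    ramp_threshold: float = 40.0
    amp_aggregate: str = "best"

    def __post_init__(self) -> None:
        if self.precursor_tol <= 0 or self.mz_match_tol <= 0:
            raise DomainError("tolerances must be > 0")
        if not (0 <= self.amp_threshold <= 100 and 0 <= self.ramp_threshold <= 100):
            raise DomainError("score thresholds must lie in [0, 100]")
        if self.amp_aggregate not in ("best", "mean"):
            raise DomainError("amp_aggregate must be 'best' or 'mean'")


@dataclass(frozen=True)
class MatchResult:
    """Compound-level scores for one query spectrum."""

    compound_id: str
    amp: float
    ramp: float
    precursor_error: float  # signed, query - library, Th
    n_reference_spectra_used: int
    best_reference_ce: float | None


#: review_status values an Identification may carry.
REVIEW_STATUSES = ("auto_tentative", "confirmed", "rejected", "unreviewed")


@dataclass
class Identification:
    """A (tentative or reviewed) compound hit in a run."""

    compound_id: str
    scan_id: str
    match: MatchResult
    review_status: str = "auto_tentative"
    retention_time: float = 0.0
    compound_name: str = ""


# ---------------------------------------------------------------------------
# stage 1: candidate filtering
# ---------------------------------------------------------------------------

def candidate_filter(query: Spectrum, library: SpectralLibrary,
                     precursor_tol: float = 0.01) -> list[LibraryEntry]:
    """Entries whose precursor lies within ``precursor_tol`` of the
    query's, in library order.  Isobaric entries are all returned;
    disambiguation is left to the relative score."""
    if query.ms_level != 2:
        raise ContractViolation("candidate_filter requires an MS2 query")
    if query.precursor_mz is None or library.n_entries == 0:
        return []
    mask = np.abs(library.precursor_array - query.precursor_mz) <= precursor_tol
    return [library.entries[i] for i in np.nonzero(mask)[0]]


# ---------------------------------------------------------------------------
# stage 2: per-spectrum similarity
# ---------------------------------------------------------------------------

def spectrum_similarity(query: Spectrum, reference: Spectrum,
                        mz_match_tol: float = 0.01) -> float:
    """Similarity score in [0, 100] between two centroided spectra.

    Peak matching is a one-to-one assignment restricted to pairs within
    ``mz_match_tol``; among feasible assignments the one maximising the
    summed geometric-mean intensity of matched pairs is chosen (solved
    exactly with the Hungarian algorithm).  Empty input yields 0 with a
    warning rather than an error.
    """
    if query.n_peaks == 0 or reference.n_peaks == 0:
        warnings.warn("spectrum_similarity: empty spectrum scores 0",
                      stacklevel=2)
        return 0.0
    norm = np.sqrt(query.intensities.sum() * reference.intensities.sum())
    if norm == 0:
        return 0.0
    matched = _matched_intensity_sum(query, reference, mz_match_tol)
    return float(100.0 * matched / norm)


def _matched_intensity_sum(query: Spectrum, reference: Spectrum,
                           mz_match_tol: float) -> float:
    """Maximum of sum sqrt(Iq*Ir) over one-to-one peak assignments with
    |dmz| <= tol."""
    dmz = np.abs(query.mz[:, None] - reference.mz[None, :])
    feasible = dmz <= mz_match_tol
    if not feasible.any():
        return 0.0
    weight = np.where(
        feasible,
        np.sqrt(query.intensities[:, None] * reference.intensities[None, :]),
        0.0)
    rows, cols = linear_sum_assignment(weight, maximize=True)
    return float(weight[rows, cols].sum())


# ---------------------------------------------------------------------------
# stage 3: compound-level amp / ramp
# ---------------------------------------------------------------------------

def _amp(query: Spectrum, entry: LibraryEntry,
         params: SearchParams) -> tuple[float, float | None]:
    """Compound match probability and the collision energy of the
    best-matching reference spectrum."""
    sims = [spectrum_similarity(query, ref, params.mz_match_tol)
            for ref in entry.reference_spectra]
    best_idx = int(np.argmax(sims))
    best_ce = entry.reference_spectra[best_idx].collision_energy
    if params.amp_aggregate == "mean":
        return float(np.mean(sims)), best_ce
    return float(sims[best_idx]), best_ce


def score_compound(query: Spectrum, entry: LibraryEntry,
                   candidates_context: Sequence[LibraryEntry],
                   params: SearchParams = SearchParams()) -> MatchResult:
    """amp/ramp scores for one candidate within its candidate set.

    ``candidates_context`` must be the :func:`candidate_filter` output
    for this query and must contain ``entry``.  ramp normalises amp over
    the context, so it is 100 for a sole positive candidate and 0 when
    every candidate scores 0.
    """
    ids = [e.compound.compound_id for e in candidates_context]
    if entry.compound.compound_id not in ids:
        raise ContractViolation(
            f"entry {entry.compound.compound_id!r} not in candidate context")
    amps = {e.compound.compound_id: _amp(query, e, params)
            for e in candidates_context}
    return _build_result(query, entry, amps, params)


def _build_result(query: Spectrum, entry: LibraryEntry,
                  amps: Mapping[str, tuple[float, float | None]],
                  params: SearchParams) -> MatchResult:
    cid = entry.compound.compound_id
    amp, best_ce = amps[cid]
    total = sum(a for a, _ in amps.values())
    ramp = 100.0 * amp / total if total > 0 else 0.0
    return MatchResult(
        compound_id=cid, amp=amp, ramp=ramp,
        precursor_error=float(query.precursor_mz - entry.compound.precursor_mz),
        n_reference_spectra_used=len(entry.reference_spectra),
        best_reference_ce=best_ce)


# ---------------------------------------------------------------------------
# stage 4: per-spectrum identification and run-level screening
# ---------------------------------------------------------------------------

def identify_spectrum(query: Spectrum, library: SpectralLibrary,
                      params: SearchParams = SearchParams(),
                      ) -> tuple[list[MatchResult], Identification | None]:
    """Search one MS2 spectrum against the library.

    Returns all candidate :class:`MatchResult`s ranked by amp
    (descending; ties broken by higher ramp, smaller absolute precursor
    error, then compound id) and, when the top result clears both score
    thresholds, a tentative :class:`Identification`.
    """
    if query.ms_level != 2:
        raise ContractViolation("identify_spectrum requires an MS2 query")
    cleaned = apply_intensity_cutoff(query, params.intensity_cutoff_factor)
    candidates = candidate_filter(cleaned, library, params.precursor_tol)
    if not candidates:
        return [], None
    amps = {e.compound.compound_id: _amp(cleaned, e, params)
            for e in candidates}
    results = [_build_result(cleaned, e, amps, params) for e in candidates]
    results.sort(key=lambda r: (-r.amp, -r.ramp, abs(r.precursor_error),
                                r.compound_id))
    top = results[0]
    hit = None
    if (top.amp > params.amp_threshold and top.ramp > params.ramp_threshold
            and abs(top.precursor_error) <= params.precursor_tol):
        entry = next(e for e in candidates
                     if e.compound.compound_id == top.compound_id)
        hit = Identification(
            compound_id=top.compound_id, scan_id=query.scan_id, match=top,
            review_status="auto_tentative",
            retention_time=query.retention_time,
            compound_name=entry.compound.name)
    return results, hit


@dataclass
class ScreeningReport:
    """Outcome of screening one run: spectrum-level tentative hits plus
    one deduplicated identification per compound (best amp kept)."""

    spectra_searched: int = 0
    spectrum_hits: list[Identification] = field(default_factory=list)
    identifications: list[Identification] = field(default_factory=list)
    run_metadata: dict = field(default_factory=dict)

    @property
    def n_tentative_spectrum_level(self) -> int:
        return len(self.spectrum_hits)

    @property
    def compounds(self) -> set[str]:
        return {ident.compound_id for ident in self.identifications}

    def by_status(self, status: str) -> list[Identification]:
        return [i for i in self.identifications if i.review_status == status]


def screen_run(run: Run, library: SpectralLibrary,
               params: SearchParams = SearchParams()) -> ScreeningReport:
    """Search every MS2 spectrum of a run and aggregate tentative hits
    per compound, keeping the highest-amp spectrum for each."""
    report = ScreeningReport(run_metadata=dict(run.metadata))
    best: dict[str, Identification] = {}
    for spec in run.ms2_spectra():
        report.spectra_searched += 1
        _, hit = identify_spectrum(spec, library, params)
        if hit is None:
            continue
        report.spectrum_hits.append(hit)
        kept = best.get(hit.compound_id)
        if kept is None or hit.match.amp > kept.match.amp:
            best[hit.compound_id] = replace_identification(hit)
    report.identifications = sorted(best.values(),
                                    key=lambda i: i.compound_id)
    return report


def replace_identification(hit: Identification) -> Identification:
    return Identification(
        compound_id=hit.compound_id, scan_id=hit.scan_id, match=hit.match,
        review_status=hit.review_status, retention_time=hit.retention_time,
        compound_name=hit.compound_name)


def review_hits(report: ScreeningReport,
                oracle: Mapping[str, bool] | Callable[[str], bool | None],
                ) -> dict[str, int]:
    """Expert-review stage: confirm or reject every tentative hit.

    ``oracle`` maps compound id to truth (in tests, the simulator's
    ground truth; in practice the reviewer's verdicts).  Hits the oracle
    does not cover become ``unreviewed`` and are flagged in the returned
    counts.  Both spectrum-level hits and deduplicated identifications
    are updated; counts refer to spectrum-level hits.
    """
    lookup: Callable[[str], bool | None]
    if callable(oracle):
        lookup = oracle
    else:
        lookup = lambda cid: oracle.get(cid)  # noqa: E731
    def apply(ident: Identification) -> str:
        verdict = lookup(ident.compound_id)
        if verdict is None:
            ident.review_status = "unreviewed"
        else:
            ident.review_status = "confirmed" if verdict else "rejected"
        return ident.review_status

    counts = {"confirmed": 0, "rejected": 0, "unreviewed": 0}
    for ident in report.spectrum_hits:
        counts[apply(ident)] += 1
    for ident in report.identifications:
        apply(ident)
    return counts
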