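"""Identification engine: candidate filtering, similarity kernel,
amp/ramp scoring, decision rule, run screening and review."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from toxscreen import (ContractViolation, Identification, MatchResult,
                       ScreeningReport, SearchParams, SpectralLibrary,
                       Spectrum, candidate_filter, identify_spectrum,
                       review_hits, score_compound, screen_run,
                       spectrum_similarity)
from toxscreen.library import CompoundRecord, LibraryEntry
from toxscreen.search import replace_identification
from toxscreen.synthetic import generate_library, generate_query_spectra

from conftest import random_ms2_spectrum


def brute_force_similarity(query: Spectrum, reference: Spectrum,
                           tol: float = 0.01) -> float:
    """Independent oracle: exhaustive search over all one-to-one peak
    assignments feasible within the m/z tolerance."""
    nq, nr = query.n_peaks, reference.n_peaks
    pairs = [(i, j) for i in range(nq) for j in range(nr)
             if abs(query.mz[i] - reference.mz[j]) <= tol]
    best = 0.0
    for k in range(0, min(nq, nr) + 1):
        for combo in itertools.permutations(pairs, k):
            if (len({i for i, _ in combo}) == k
                    and len({j for _, j in combo}) == k):
                total = sum(
                    math.sqrt(query.intensities[i] * reference.intensities[j])
                    for i, j in combo)
                best = max(best, total)
    norm = math.sqrt(query.intensities.sum() * reference.intensities.sum())
    return 100.0 * best / norm if norm else 0.0


def single_ref_entry(cid: str, precursor: float,
                     mz, intensities) -> LibraryEntry:
    spec = Spectrum(mz=mz, intensities=intensities, precursor_mz=precursor,
                    collision_energy=35.0, scan_id=f"{cid}_ref")
    return LibraryEntry(
        compound=CompoundRecord(name=cid, precursor_mz=precursor,
                                compound_id=cid),
        reference_spectra=(spec,))


# ---------------------------------------------------------------------------
# candidate filtering
# ---------------------------------------------------------------------------

class TestCandidateFilter:
    @pytest.fixture()
    def library(self):
        return SpectralLibrary(entries=[
            single_ref_entry("A", 310.2166, [100.0], [10.0]),
            single_ref_entry("B", 310.2300, [100.0], [10.0]),
            single_ref_entry("C", 310.2166, [150.0], [10.0]),
        ])

    def query(self, precursor):
        return Spectrum(mz=[100.0], intensities=[10.0],
                        precursor_mz=precursor)

    def test_within_tolerance_included(self, library):
        hits = candidate_filter(self.query(310.2171), library, 0.01)
        assert [e.compound.compound_id for e in hits] == ["A", "C"]

    def test_beyond_tolerance_excluded(self, library):
        hits = candidate_filter(self.query(310.2171), library, 0.01)
        assert "B" not in {e.compound.compound_id for e in hits}

    def test_isobars_both_returned(self, library):
        hits = candidate_filter(self.query(310.2166), library, 0.01)
        assert len(hits) == 2  # no premature disambiguation


# ---------------------------------------------------------------------------
# similarity kernel
# ---------------------------------------------------------------------------

class TestSpectrumSimilarity:
    def test_self_match_is_100(self):
        spec = random_ms2_spectrum(np.random.default_rng(0))
        assert spectrum_similarity(spec, spec) == pytest.approx(100.0)

    def test_disjoint_peaks_score_zero(self):
        a = Spectrum(mz=[100.0, 200.0], intensities=[1.0, 1.0])
        b = Spectrum(mz=[150.0, 250.0], intensities=[1.0, 1.0])
        assert spectrum_similarity(a, b) == 0.0

    def test_worked_example_matches_oracle(self):
        query = Spectrum(mz=[100.0, 150.0], intensities=[100.0, 50.0])
        ref = Spectrum(mz=[100.005, 200.0], intensities=[80.0, 20.0])
        expected = brute_force_similarity(query, ref)
        # one matched pair: 100*sqrt(100*80)/sqrt(150*100) = 73.0297...
        assert expected == pytest.approx(73.02967433402215)
        assert spectrum_similarity(query, ref) == pytest.approx(expected)

    def test_symmetric(self):
        rng = np.random.default_rng(5)
        a, b = (random_ms2_spectrum(rng, n_peaks=8) for _ in range(2))
        assert spectrum_similarity(a, b) == pytest.approx(
            spectrum_similarity(b, a))

    def test_empty_spectrum_warns_and_scores_zero(self):
        a = Spectrum(mz=[], intensities=[])
        b = Spectrum(mz=[100.0], intensities=[1.0])
        with pytest.warns(UserWarning):
            assert spectrum_similarity(a, b) == 0.0

    @given(seed=st.integers(0, 200))
    def test_equals_exhaustive_assignment_oracle(self, seed):
        """On small spectra (<= 6 peaks) the kernel equals the brute
        force over all one-to-one assignments, including spectra with
        ambiguous (overlapping-tolerance) matches."""
        rng = np.random.default_rng(seed)
        nq, nr = rng.integers(1, 7), rng.integers(1, 7)
        # cluster m/z values so tolerance windows overlap frequently
        qmz = np.sort(rng.uniform(100.0, 100.05, size=nq))
        rmz = np.sort(rng.uniform(100.0, 100.05, size=nr))
        query = Spectrum(mz=qmz + np.arange(nq) * 1e-4,
                         intensities=rng.uniform(1, 100, size=nq))
        ref = Spectrum(mz=rmz + np.arange(nr) * 1e-4,
                       intensities=rng.uniform(1, 100, size=nr))
        assert spectrum_similarity(query, ref, 0.01) == pytest.approx(
            brute_force_similarity(query, ref, 0.01))

    @given(seed=st.integers(0, 100), scale=st.floats(0.01, 1000.0))
    def test_invariant_to_uniform_intensity_scaling(self, seed, scale):
        rng = np.random.default_rng(seed)
        a = random_ms2_spectrum(rng, n_peaks=6)
        b = random_ms2_spectrum(rng, n_peaks=6)
        scaled = a.with_peaks(a.mz, a.intensities * scale)
        assert spectrum_similarity(scaled, b) == pytest.approx(
            spectrum_similarity(a, b))

    def test_agrees_with_matchms_cosine_hungarian(self):
        """Independent cross-check: matchms' exact-assignment cosine on
        square-root-scaled intensities computes the same kernel."""
        from matchms import Spectrum as MSpectrum
        from matchms.similarity import CosineHungarian

        rng = np.random.default_rng(21)
        for _ in range(10):
            a = random_ms2_spectrum(rng, n_peaks=10)
            b = random_ms2_spectrum(rng, n_peaks=10)
            ma = MSpectrum(mz=a.mz, intensities=np.sqrt(a.intensities),
                           metadata={}, metadata_harmonization=False)
            mb = MSpectrum(mz=b.mz, intensities=np.sqrt(b.intensities),
                           metadata={}, metadata_harmonization=False)
            score = float(CosineHungarian(tolerance=0.01).pair(ma, mb)["score"])
            assert spectrum_similarity(a, b, 0.01) == pytest.approx(
                100.0 * score, abs=1e-9)


# ---------------------------------------------------------------------------
# amp / ramp
# ---------------------------------------------------------------------------

def entries_with_amps():
    """Three isobaric single-reference entries whose amps against the
    one-peak query are exactly 60, 30 and 10 (amps sum to 100, so ramps
    equal amps)."""
    # query has a single peak; similarity = 100*sqrt(x/(x+y)) where x is
    # the matched reference intensity and y the unmatched remainder
    entries = [
        single_ref_entry("E60", 400.0, [100.0, 200.0], [36.0, 64.0]),
        single_ref_entry("E30", 400.0, [100.0, 200.0], [9.0, 91.0]),
        single_ref_entry("E10", 400.0, [100.0, 200.0], [1.0, 99.0]),
    ]
    query = Spectrum(mz=[100.0], intensities=[50.0], precursor_mz=400.0)
    return query, entries


class TestCompoundScoring:
    def test_ramp_normalisation_oracle(self):
        query, entries = entries_with_amps()
        results = [score_compound(query, e, entries) for e in entries]
        assert [r.amp for r in results] == pytest.approx([60.0, 30.0, 10.0])
        assert [r.ramp for r in results] == pytest.approx([60.0, 30.0, 10.0])
        assert sum(r.ramp for r in results) == pytest.approx(100.0)

    def test_sole_candidate_gets_ramp_100(self):
        query, entries = entries_with_amps()
        result = score_compound(query, entries[0], [entries[0]])
        assert result.ramp == pytest.approx(100.0)

    def test_equal_candidates_split_evenly(self):
        query, entries = entries_with_amps()
        twins = [entries[0], single_ref_entry("E60b", 400.0,
                                              [100.0, 200.0], [36.0, 64.0])]
        results = [score_compound(query, e, twins) for e in twins]
        assert [r.ramp for r in results] == pytest.approx([50.0, 50.0])

    def test_zero_amp_candidate_does_not_dilute(self):
        query, entries = entries_with_amps()
        blank = single_ref_entry("E0", 400.0, [300.0], [10.0])  # no match
        before = score_compound(query, entries[0], entries)
        after = score_compound(query, entries[0], entries + [blank])
        assert after.amp == before.amp and after.ramp == before.ramp

    def test_positive_competitor_strictly_dilutes(self):
        query, entries = entries_with_amps()
        before = score_compound(query, entries[0], entries[:2])
        after = score_compound(query, entries[0], entries)
        assert after.amp == before.amp
        assert after.ramp < before.ramp

    def test_entry_outside_context_rejected(self):
        query, entries = entries_with_amps()
        with pytest.raises(ContractViolation):
            score_compound(query, entries[0], entries[1:])

    def test_all_zero_amps_give_zero_ramp(self):
        query = Spectrum(mz=[100.0], intensities=[50.0], precursor_mz=400.0)
        blank = single_ref_entry("E0", 400.0, [300.0], [10.0])
        result = score_compound(query, blank, [blank])
        assert result.amp == 0.0 and result.ramp == 0.0


# ---------------------------------------------------------------------------
# identification decision rule
# ---------------------------------------------------------------------------

class TestIdentifySpectrum:
    def test_passing_hit_is_tentative_positive(self):
        query, entries = entries_with_amps()
        library = SpectralLibrary(entries=entries)
        results, hit = identify_spectrum(query, library)
        assert results[0].compound_id == "E60"
        assert hit is not None and hit.review_status == "auto_tentative"

    def test_amp_threshold_is_strict(self):
        # sole candidate with amp < 5 despite ramp = 100
        query = Spectrum(mz=[100.0], intensities=[50.0], precursor_mz=400.0)
        weak = single_ref_entry("W", 400.0, [100.0, 200.0], [1.0, 400.0])
        library = SpectralLibrary(entries=[weak])
        results, hit = identify_spectrum(query, library)
        assert results[0].amp == pytest.approx(100.0 / math.sqrt(401.0))
        assert results[0].amp < 5.0
        assert results[0].ramp == pytest.approx(100.0)
        assert hit is None

    def test_ramp_threshold_is_strict(self):
        # two equal isobars -> ramp 50 each: passes; three -> 33.3: fails
        query = Spectrum(mz=[100.0], intensities=[50.0], precursor_mz=400.0)
        mk = lambda cid: single_ref_entry(cid, 400.0, [100.0], [10.0])
        lib3 = SpectralLibrary(entries=[mk("A"), mk("B"), mk("C")])
        _, hit = identify_spectrum(query, lib3)
        assert hit is None  # 33.3 < 40

    def test_empty_candidate_set_returns_nothing(self):
        query = Spectrum(mz=[100.0], intensities=[50.0], precursor_mz=999.0)
        _, hit = identify_spectrum(
            query, SpectralLibrary(entries=[
                single_ref_entry("A", 400.0, [100.0], [1.0])]))
        assert hit is None

    def test_noisy_query_identifies_true_compound(self, seeded_library):
        library, profiles = seeded_library
        cid, profile = next(iter(profiles.items()))
        query = generate_query_spectra(profile, n=1, seed=3)[0]
        results, hit = identify_spectrum(query, library)
        assert hit is not None and hit.compound_id == cid


# ---------------------------------------------------------------------------
# run screening and review
# ---------------------------------------------------------------------------

def make_report(hits_per_compound: dict) -> ScreeningReport:
    report = ScreeningReport(spectra_searched=sum(hits_per_compound.values()))
    for cid, n in hits_per_compound.items():
        for k in range(n):
            match = MatchResult(compound_id=cid, amp=50.0 + k, ramp=90.0,
                                precursor_error=0.0,
                                n_reference_spectra_used=1,
                                best_reference_ce=35.0)
            report.spectrum_hits.append(Identification(
                compound_id=cid, scan_id=f"{cid}_{k}", match=match))
        report.identifications.append(
            replace_identification(report.spectrum_hits[-1]))
    return report


class TestScreenAndReview:
    def test_empty_run_yields_empty_report(self, seeded_library):
        library, _ = seeded_library
        report = screen_run(__import__("toxscreen").Run(), library)
        assert report.spectra_searched == 0
        assert report.identifications == []

    def test_repeat_spectra_deduplicate_per_compound(self, seeded_library):
        library, profiles = seeded_library
        cid, profile = next(iter(profiles.items()))
        from toxscreen import Run
        run = Run(spectra=generate_query_spectra(profile, n=3, seed=2))
        report = screen_run(run, library)
        assert report.n_tentative_spectrum_level == 3
        assert len(report.identifications) == 1
        best = report.identifications[0]
        assert best.match.amp == max(
            h.match.amp for h in report.spectrum_hits)

    def test_review_counts_match_verdicts(self):
        """A review oracle rejecting 83 of 230 tentative hits leaves 147
        confirmed."""
        report = make_report({"true_cpd": 147, "false_cpd": 83})
        counts = review_hits(report, {"true_cpd": True, "false_cpd": False})
        assert counts == {"confirmed": 147, "rejected": 83, "unreviewed": 0}

    def test_all_true_oracle_rejects_nothing(self):
        report = make_report({"a": 3, "b": 2})
        counts = review_hits(report, lambda cid: True)
        assert counts["rejected"] == 0 and counts["confirmed"] == 5

    def test_uncovered_compound_flagged_unreviewed(self):
        report = make_report({"a": 2, "mystery": 1})
        counts = review_hits(report, {"a": True})
        assert counts["unreviewed"] == 1
        statuses = {i.compound_id: i.review_status
                    for i in report.identifications}
        assert statuses["mystery"] == "unreviewed"

    def test_empty_report_unchanged(self):
        report = ScreeningReport()
        assert review_hits(report, {}) == {
            "confirmed": 0, "rejected": 0, "unreviewed": 0}
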