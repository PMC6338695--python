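"""Qualitative method-validation layer for the screening workflow.

Implements the performance metrics a forensic screening assay is judged
by: selectivity/specificity on blank matrix, sensitivity (false-negative
rate), limits of identification (LOI) from dilution series at seven
standard concentration levels, the logP applicability window of the
reversed-phase workflow, extraction-dilution arithmetic for
collection-device specimens, and Venn-style agreement analysis between
the non-targeted method and a targeted reference method, including a
cause-partition of reference-only positives.

All percentages are reported to one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import DomainError
from .library import SpectralLibrary

#: Standard spiking levels of the dilution series, ng/mL neat oral fluid.
STANDARD_LEVELS = (1.0, 2.5, 5.0, 10.0, 25.0, 50.0, 100.0)
#: logP applicability window of the reversed-phase workflow (inclusive).
LOGP_WINDOW = (0.5, 5.5)
#: Concentration below which misses are attributed to limited detection
#: capability, ng/mL.
LOW_CONCENTRATION_NGML = 5.0

_MISS_CATEGORIES = ("no_reference_spectrum", "outside_logp_window",
                    "below_5ngml", "other")


def _pct(numerator: float, denominator: float) -> float:
    return round(100.0 * numerator / denominator, 1)


# ---------------------------------------------------------------------------
# selectivity / specificity / sensitivity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectivityResult:
    n_spectra: int
    n_tentative: int
    n_false_positive: int
    specificity: float  # percent, one decimal


def compute_selectivity(n_spectra: int, n_tentative: int,
                        n_false_positive: int) -> SelectivityResult:
    """Specificity of automated library search on blank-matrix runs:
    100 * (spectra searched - false positives) / spectra searched.

    The denominator is the total number of product-ion spectra searched,
    so specificity + 100*FP/n_spectra = 100 exactly.
    """
    if not 0 <= n_false_positive <= n_tentative <= n_spectra:
        raise DomainError(
            f"counts must satisfy 0 <= false positives ({n_false_positive}) "
            f"<= tentative ({n_tentative}) <= spectra ({n_spectra})")
    return SelectivityResult(
        n_spectra=n_spectra, n_tentative=n_tentative,
        n_false_positive=n_false_positive,
        specificity=_pct(n_spectra - n_false_positive, n_spectra))


def compute_fn_rate(identifiable_spectra: int, missed: int) -> float:
    """False-negative rate (percent) among spectra whose true compound
    is covered by the library.  0/0 is undefined and returns NaN."""
    if missed > identifiable_spectra:
        raise DomainError("missed cannot exceed identifiable_spectra")
    if identifiable_spectra == 0:
        return math.nan
    return _pct(missed, identifiable_spectra)


# ---------------------------------------------------------------------------
# limits of identification
# ---------------------------------------------------------------------------

@dataclass
class DilutionSeries:
    """Identification outcomes for one compound across a concentration
    series (levels sorted ascending at construction)."""

    compound_id: str
    levels: list[tuple[float, bool]]  # (concentration ng/mL, identified)
    logp: float | None = None

    def __post_init__(self) -> None:
        if not self.levels:
            raise DomainError("a dilution series needs >= 1 level")
        if any(c <= 0 for c, _ in self.levels):
            raise DomainError("concentrations must be positive")
        self.levels = sorted(self.levels, key=lambda lv: lv[0])


@dataclass(frozen=True)
class LoiResult:
    compound_id: str
    loi: float | None  # ng/mL; None = not detected at any level
    inconsistent: bool  # identified at a low level but not a higher one

    @property
    def detected(self) -> bool:
        return self.loi is not None

    def __str__(self) -> str:
        if self.loi is None:
            return "not detected"
        flag = " (inconsistent)" if self.inconsistent else ""
        return f"{self.loi:g} ng/mL{flag}"


def determine_loi(series: DilutionSeries) -> LoiResult:
    """Limit of identification: the minimum concentration at which the
    compound was identified.  A gap in the identified set above that
    minimum (identified low but missed higher) keeps the same minimum
    but is flagged inconsistent."""
    identified = [c for c, ok in series.levels if ok]
    if not identified:
        return LoiResult(series.compound_id, None, False)
    loi = min(identified)
    inconsistent = any(c > loi and not ok for c, ok in series.levels)
    return LoiResult(series.compound_id, loi, inconsistent)


def loi_summary(results: Sequence[LoiResult],
                logps: Mapping[str, float] | None = None,
                threshold: float = 5.0) -> dict:
    """Share of compounds with LOI <= ``threshold`` ng/mL, tallied both
    over all compounds and over the logP applicability window only
    (compounds without a logP value count as in-window for the second
    tally's denominator exclusion, i.e. are excluded)."""
    logps = logps or {}
    n_all = len(results)
    low_all = sum(1 for r in results if r.loi is not None and r.loi <= threshold)
    in_window = [r for r in results
                 if logps.get(r.compound_id) is not None
                 and logp_window_class(logps[r.compound_id]) == "in_window"]
    low_win = sum(1 for r in in_window
                  if r.loi is not None and r.loi <= threshold)
    return {
        "n_compounds": n_all,
        "n_loi_le_threshold": low_all,
        "pct_loi_le_threshold": _pct(low_all, n_all) if n_all else math.nan,
        "n_in_window": len(in_window),
        "n_in_window_loi_le_threshold": low_win,
        "pct_in_window_loi_le_threshold":
            _pct(low_win, len(in_window)) if in_window else math.nan,
        "threshold_ngml": threshold,
    }


# ---------------------------------------------------------------------------
# logP applicability window
# ---------------------------------------------------------------------------

def logp_window_class(logp: float | None) -> str:
    """Classify a compound by the workflow's logP applicability window
    [0.5, 5.5]: below it, too polar (lost in extraction or suppressed);
    above it, too apolar (retained on sorbent/column).  Boundaries are
    inclusive to the window; a missing value classifies as unknown."""
    if logp is None:
        return "unknown"
    if not math.isfinite(logp):
        raise DomainError("logp must be finite")
    if logp < LOGP_WINDOW[0]:
        return "too_polar"
    if logp > LOGP_WINDOW[1]:
        return "too_apolar"
    return "in_window"


# ---------------------------------------------------------------------------
# dilution-factor arithmetic
# ---------------------------------------------------------------------------

def neat_concentration(measured_conc: float, v_oral_fluid_ul: float,
                       v_extraction_ul: float) -> float:
    """Convert a concentration measured in the collection-device mixture
    (oral fluid + extraction solution) back to neat oral fluid:
    measured * (v_of + v_ext) / v_of."""
    if v_oral_fluid_ul <= 0:
        raise DomainError("oral fluid volume must be > 0")
    if v_extraction_ul < 0:
        raise DomainError("extraction volume must be >= 0")
    return measured_conc * (v_oral_fluid_ul + v_extraction_ul) / v_oral_fluid_ul


# ---------------------------------------------------------------------------
# two-method agreement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MethodComparison:
    """Venn agreement between two identification sets of
    (sample, compound) pairs."""

    both: int
    only_a: int
    only_b: int
    pct_both: float
    pct_only_a: float
    pct_only_b: float
    ids_both: frozenset = frozenset()
    ids_only_a: frozenset = frozenset()
    ids_only_b: frozenset = frozenset()

    @property
    def total(self) -> int:
        return self.both + self.only_a + self.only_b


def compare_methods(ids_a: Iterable, ids_b: Iterable) -> MethodComparison:
    """Partition the union of two methods' identifications into
    both / A-only / B-only, with percentages of the union total."""
    a, b = set(ids_a), set(ids_b)
    inter, only_a, only_b = a & b, a - b, b - a
    total = len(inter) + len(only_a) + len(only_b)
    if total == 0:
        return MethodComparison(0, 0, 0, math.nan, math.nan, math.nan)
    return MethodComparison(
        both=len(inter), only_a=len(only_a), only_b=len(only_b),
        pct_both=_pct(len(inter), total),
        pct_only_a=_pct(len(only_a), total),
        pct_only_b=_pct(len(only_b), total),
        ids_both=frozenset(inter), ids_only_a=frozenset(only_a),
        ids_only_b=frozenset(only_b))


# ---------------------------------------------------------------------------
# cause partition of reference-only positives
# ---------------------------------------------------------------------------

@dataclass
class MissExplanation:
    partition: dict = field(default_factory=dict)  # category -> list of misses
    counts: dict = field(default_factory=dict)
    percentages: dict = field(default_factory=dict)
    flagged: list = field(default_factory=list)  # misses absent from all tables


def explain_misses(only_b: Iterable,
                   library: SpectralLibrary | set | None = None,
                   logp_table: Mapping[str, float] | None = None,
                   concentration_table: Mapping | None = None,
                   ) -> MissExplanation:
    """Partition identifications obtained by the reference method only
    into causes, each miss assigned to the FIRST matching category:

    1. ``no_reference_spectrum`` — compound absent from the library;
    2. ``outside_logp_window`` — logP outside [0.5, 5.5];
    3. ``below_5ngml`` — measured concentration below 5.0 ng/mL;
    4. ``other`` — none of the above (including misses absent from all
       auxiliary tables, which are additionally flagged).

    Misses are (sample, compound) pairs; the concentration table may be
    keyed by pair or by compound.
    """
    covered: set[str] | None  # None = no library information supplied
    if library is None:
        covered = None
    elif isinstance(library, SpectralLibrary):
        covered = library.compound_ids
    else:
        covered = set(library)
    logp_table = logp_table or {}
    concentration_table = concentration_table or {}

    partition: dict[str, list] = {c: [] for c in _MISS_CATEGORIES}
    flagged = []
    misses = sorted(set(only_b))
    for miss in misses:
        sample, compound = miss if isinstance(miss, tuple) else (None, miss)
        conc = concentration_table.get(miss,
                                       concentration_table.get(compound))
        logp = logp_table.get(compound)
        if covered is not None and compound not in covered:
            partition["no_reference_spectrum"].append(miss)
        elif logp is not None and logp_window_class(logp) != "in_window":
            partition["outside_logp_window"].append(miss)
        elif conc is not None and conc < LOW_CONCENTRATION_NGML:
            partition["below_5ngml"].append(miss)
        else:
            partition["other"].append(miss)
            if logp is None and conc is None:
                flagged.append(miss)
    n = len(misses)
    counts = {c: len(v) for c, v in partition.items()}
    percentages = {c: (_pct(len(v), n) if n else math.nan)
                   for c, v in partition.items()}
    return MissExplanation(partition=partition, counts=counts,
                           percentages=percentages, flagged=flagged)
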