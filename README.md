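# toxscreen

Non-targeted LC-MS/MS drug screening for forensic and clinical
toxicology: tandem mass spectral library search with compound-level
match-probability scoring, a data-dependent-acquisition (DDA)
simulator, and the qualitative validation layer used to judge a
screening assay.

## The problem

Comprehensive drug screening in specimens such as oral fluid records
product-ion (MS/MS) spectra of *any* sufficiently abundant precursor —
no predefined analyte list — and identifies compounds afterwards by
searching the spectra against a curated reference library. Each library
entry holds one compound's spectra across ten collision energies
(5–50 eV), covering its breakdown curve. `toxscreen` implements this
identification engine and everything needed to validate it:
selectivity/specificity on blank matrix, sensitivity (false-negative
rate), limits of identification (LOI) from seven-level dilution series,
the logP applicability window of reversed-phase workflows, and
Venn-style agreement with a targeted reference method. Because no public
raw dataset accompanies the workflow, a first-class synthetic module
emulates QqTOF DDA acquisition — breakdown curves, matrix background,
top-N precursor selection with dynamic exclusion — with full ground
truth for every generated spectrum.

## Scoring model

For a query spectrum *q* and a reference spectrum *r*, peaks are matched
one-to-one within an m/z tolerance of ±0.01 Th (optimal assignment), and

    S(q, r) = 100 · Σ_matched √(I_q · I_r) / √(Σ I_q · Σ I_r)

i.e. the cosine similarity of square-root-scaled intensity vectors,
ranging 0–100 and equal to 100 exactly when the spectra agree up to
uniform intensity scaling. Candidate compounds are the library entries
whose [M+H]⁺ m/z lies within ±0.01 Th of the query precursor. Per
candidate:

* **amp** (average match probability, 0–100): the compound-level score
  against its multi-collision-energy reference set (best-matching
  reference spectrum by default; set-mean available),
* **ramp** (relative average match probability, 0–100):
  100 · amp / Σ amp over all precursor-matched candidates — how strongly
  the candidate dominates its isobaric competitors.

A hit is a tentative positive identification iff amp > 5.0 **and**
ramp > 40.0 **and** the precursor error is within ±0.01 Th; an expert
review stage then confirms or rejects it.

## Worked example

```python
import toxscreen as tx

# a 50-compound synthetic reference library with ground-truth profiles
library, profiles = tx.generate_library(50, seed=1)
print(library.n_entries, library.n_spectra)        # 50 500

# spike ten analytes at 50 ng/mL over matrix background and acquire
matrix = tx.generate_matrix_background(seed=1, avoid_mzs=library.precursor_array)
analytes = [(profiles[c], 50.0) for c in list(profiles)[:10]]
run, truth = tx.simulate_dda_run(analytes, matrix=matrix, duration=300, seed=2)
print(len(run), len(run.ms2_spectra()))            # 1502 1187

# screen the run and review against the simulator's ground truth
report = tx.screen_run(run, library)
print(report.spectra_searched,                     # 1187
      report.n_tentative_spectrum_level,           # 20
      sorted(report.compounds) == sorted(truth.analytes_with_ms2))  # True
counts = tx.review_hits(report, {c: True for c in truth.spiked})
print(counts)   # {'confirmed': 20, 'rejected': 0, 'unreviewed': 0}
```

All 1187 matrix-derived spectra score below threshold (no candidates
share their precursors), the ten spiked analytes each yield two
product-ion spectra before dynamic exclusion mutes them, and every one
identifies its true compound — the zero-false-negative property the
engine is designed for.

Validation metrics are plain arithmetic on count structures:

```python
tx.compute_selectivity(11437, 230, 83).specificity   # 99.3 (%)
tx.neat_concentration(10.0, 500.0, 400.0)            # 18.0 (ng/mL)
```

A `toxscreen` console script wraps the same API
(`toxscreen simulate library|run|dilution`, `toxscreen screen`,
`toxscreen validate selectivity|loi|compare`).

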