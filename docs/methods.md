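# Methods

## Scope and shape

`toxscreen` is organised as five cooperating modules: spectrum
containers and I/O (`spectra`), the multi-collision-energy reference
library (`library`), the identification engine (`search`), the
validation metrics (`validation`), and the synthetic data generators
(`synthetic`). The generators are first-class, tested code: they define
the study conditions under which every workflow-level property is
demonstrated.

## Spectrum model and I/O

Spectra are centroided peak lists. Two normalisations happen at
construction, so every downstream operation sees a canonical object:
peaks are sorted ascending by m/z, and exact-duplicate centroids are
merged by intensity summation (matching is otherwise ill-defined).
Runs are time-ordered lists of spectra.

Supported formats: MGF (via pyteomics; `PEPMASS` → precursor,
`RTINSECONDS` → retention time, missing collision energy defaults to
the 35 eV acquisition value), standard centroided mzML (a built-in
reader decodes the base64/zlib 32- or 64-bit float arrays and the
scan/precursor controlled-vocabulary parameters; profile-mode files are
rejected because the workflow assumes centroids), a self-describing
"mzml-lite" XML dialect used for loss-free round trips of simulated
runs, and a one-file-per-spectrum plain-text peak-list export (header
`precursor_mz rt ce`, then tab-separated rows) as the ASCII exchange
form handed to external search tools. MGF round trips are guaranteed to
six decimal places; mzml-lite round trips are exact.

The relative intensity cutoff retains peaks with intensity ≥
factor × base peak (ties kept, so the base peak always survives and the
operation is idempotent, monotone in the factor, and invariant to
uniform intensity scaling). The default factor is 0.01.

## Reference library

An entry pairs a compound record (name, [M+H]⁺ m/z, octanol–water logP
carried in the library so validation needs no external lookup) with
curated product-ion spectra at distinct collision energies in
[5, 50] eV, each agreeing with the compound precursor within ±0.01 Th —
enforced at construction, so a well-formed library cannot violate the
invariants. Curation applies the intensity cutoff and then removes
known-unspecific signals. "Unspecific" is operationalised as an
explicit exclusion m/z list (empty by default): the underlying
instrument workflows do not publish a rule, and an explicit list is
reproducible and testable. The same 0.01 cutoff factor is used at
curation and search time.

Persistence is MSP-like text (one record per reference spectrum with
`NAME`, `COMPOUND_ID`, `PRECURSOR_MZ`, `COLLISION_ENERGY`, `LOGP`,
`NUM PEAKS`), read and written through matchms behind the module
surface, with a strict structural pre-validation (declared peak counts
must match, every record needs a precursor) because lenient parsing
would silently mask corrupt libraries.

## Identification engine

* **Candidate filter**: absolute precursor tolerance ±0.01 Th (not
  ppm). All isobars are returned; disambiguation is the relative
  score's job.
* **Similarity kernel**: `100 · Σ_matched √(I_q I_r) / √(Σ I_q Σ I_r)`
  over a one-to-one peak matching within ±0.01 Th. The matching is the
  *optimal* assignment (Hungarian algorithm, maximising the matched
  geometric-mean intensity sum) rather than a nearest-Δm/z greedy pass:
  the optimal assignment provably equals the exhaustive search over all
  one-to-one assignments, which is the oracle the test suite holds the
  kernel to, and it removes order-dependence when tolerance windows
  overlap. The kernel is symmetric, scale-invariant, and 100 exactly
  iff the spectra agree up to uniform scaling on all peaks.
* **amp**: by default the best-matching reference spectrum of the
  entry's collision-energy set. A set-mean variant
  (`SearchParams.amp_aggregate="mean"`) is provided behind the same
  interface. The best-CE default was chosen because it gives the engine
  two properties the workflow's guarantees rest on: a library spectrum
  searched against its own library scores amp = 100 exactly
  (self-identification), and a query acquired at one collision energy
  is judged against the reference most comparable to it rather than
  penalised by the far ends of the breakdown curve. The set-mean
  variant under-scores single-CE queries for exactly that reason.
* **ramp**: 100 · amp / Σ amp over the candidate set; 100 for a sole
  positive candidate, 0 when every candidate scores 0. ramp sums to 100
  whenever any candidate has positive amp, and adding a positive-amp
  competitor strictly dilutes everyone else.
* **Decision rule**: strict inequalities amp > 5.0 and ramp > 40.0 plus
  precursor error within tolerance, yielding an `auto_tentative`
  identification. Ranking ties break by higher ramp, smaller absolute
  precursor error, then compound id — an arbitrary but deterministic
  order.
* **Run screening** searches every MS2 spectrum and deduplicates hits
  per compound, keeping the highest-amp spectrum; spectrum-level and
  compound-level tallies are both reported since published counts can
  be read either way. **Review** maps an oracle (ground truth in tests,
  an expert's verdicts in practice) over all tentative hits; uncovered
  compounds become `unreviewed` and are flagged rather than guessed.

The absolute amp/ramp values of this kernel are this package's own
scoring model; published scores from proprietary engines with
undisclosed formulas are not expected to be reproduced number-for-number,
only the score ranges, roles and decision thresholds.

## Validation metrics

All percentages are rounded to one decimal. Specificity uses the total
number of spectra searched as denominator — with 11,437 blank-matrix
spectra and 83 expert-rejected false positives this yields 99.3%, and
specificity + 100·FP/n is exactly 100 by construction. The
false-negative rate is tallied over spectra whose true compound the
library covers; 0/0 is undefined (NaN), not silently zero. The LOI of
a dilution series is the minimum identified concentration; a gap above
the minimum (identified low, missed higher) keeps that minimum but is
flagged inconsistent, and LOI is monotone: adding an identified lower
level can never raise it. The logP applicability window is [0.5, 5.5]
with inclusive boundaries (only strictly outside values are classed
problematic). Neat-fluid concentrations scale by
(v_oral_fluid + v_extraction)/v_oral_fluid; a zero extraction volume is
the identity. Two-method agreement partitions the union of
(sample, compound) identifications into both/only-A/only-B.
Reference-only misses are explained by the first matching cause in a
fixed priority order — no reference spectrum, outside the logP window,
concentration below 5 ng/mL, other — mirroring how such analyses remove
the no-spectrum cases before attributing the remainder; misses covered
by no auxiliary table land in "other" and are flagged.

## Synthetic data model

* **Breakdown curves.** Fragment intensity is a unimodal log-normal
  shape in (CE − appearance CE): zero below the appearance energy,
  maximal ~12 eV above it (σ = 0.7 in log space), declining at high
  energy. Precursor survival decays as exp(−(CE−5)/12). These shapes
  are this package's modelling choice; only their qualitative form
  (rise, peak, fall across 5–50 eV) matters to the workflow.
* **Reference spectra** are generated on the ten-step 5–50 eV grid at
  base intensity 1000 with a mild multiplicative log-normal jitter
  (σ = 0.05); peaks below 1 count or outside the 50–700 MS/MS scan
  range are dropped.
* **Libraries.** Compounds get 4–8 fragments (≥ 0.2 Th apart), random
  appearance energies in 5–30 eV, logP ~ N(2.8, 1.6²) (so a realistic
  minority falls outside the applicability window), [M+H]⁺ drawn in
  150–650 Th with non-isobaric precursors kept > 0.05 Th apart; a
  configurable fraction is arranged into isobaric pairs (within
  0.01 Th) to stress the relative score.
* **DDA duty cycle.** One survey scan plus top-8 dependent scans, all
  100 ms accumulation, 50 ms overhead → 0.95 s cycles. Precursors must
  reach 100 counts, are chosen top-N by intensity, and enter a 30 s
  exclusion after 2 selections (the occurrence count restarts when the
  ban expires). MS2 spectra are the analyte template at 35 eV averaged
  over a ±5 eV spread (5-point grid), scaled by the live survey
  intensity, with multiplicative log-normal noise (σ = 0.15) and a
  1-count floor. Survey responses are gaussian chromatographic peaks
  (height × ng/mL) with shot-to-shot noise σ = 0.10 and a small
  precursor m/z jitter (σ = 0.002 Th, comfortably inside the ±0.01
  tolerance). Every selection is logged as ground truth.
* **Matrix background** is a set of broadly eluting ions (sinusoidal
  envelope bounded away from zero, so blank-matrix TIC strictly exceeds
  a reagent blank's) with a configurable fraction of fractional-spacing
  isotope clusters (charge 2–3) emulating multiply charged salivary
  peptides; background m/z avoids library precursors by > 0.011 Th
  unless overlap is requested. Background intensity scales are invented
  and config-exposed; no quantitative matrix figures exist to calibrate
  them against.
* **Dilution series** use the seven standard levels (1, 2.5, 5, 10, 25,
  50, 100 ng/mL). The specimen model normalises every sample to the
  same neat-oral-fluid equivalent before extraction, so simulated
  responses depend only on the neat concentration while the recorded
  dilution factor varies — which is precisely why detection capability
  is independent of the extraction volume, and why the per-level child
  seeds (functions of seed and level only) make the 400 µL and 4 mL
  variants bit-identical.

## What the synthetic data does and does not show

Passing tests demonstrate the engine's *structural* guarantees: zero
false negatives for spectra whose compound the library covers,
self-identification of reference spectra, exact scoring identities,
duty-cycle compliance, and dilution-independent LOI recovery. The
generators do not model ion suppression beyond a scalar response,
chromatographic peak-shape pathology, isotope patterns beyond
charge-state spacing, chimeric MS2 spectra, or real spectral ambiguity
between structurally related drugs — so specimen-scale figures
(population LOI distributions, false-positive rates against a
1709-compound library, patient-sample compound counts) are *not*
reproduced numerically here, only their arithmetic and their scaled
synthetic analogues.

## Numerical choices and degenerate inputs

Score ties rank deterministically (see above). Empty spectra score 0
with a warning rather than raising. Boundary ties at the intensity
cutoff are retained. Problem sizes in tests and the acceptance script
(50-compound libraries, 300 s runs, 10 queries per compound) were
chosen as the smallest instances at which every property is exercised
with comfortable statistical margin; all generators accept larger
sizes, and a 1709-entry library builds in a few seconds.

## Known limitations

The amp/ramp kernel is a documented, swappable scoring model, not a
reimplementation of any proprietary engine's undisclosed formula.
mzML support covers centroided spectra with uncompressed or
zlib-compressed float arrays (the subset MSConvert emits for this
workflow); vendor raw files, negative-mode ESI, multiply charged
candidate precursors, retention-time scoring and quantification are out
of scope.
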