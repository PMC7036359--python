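# Methods

This note records the models, algorithms and numerical choices behind
`cellspm`, including the places where the underlying procedure left design
room and what was decided there.

## Data model

A **peak list** is one cell's centroided spectrum: strictly ascending
positive m/z with positive intensities. Zero-intensity entries are dropped
and exact duplicate m/z rows merged (by intensity sum) at construction, so
every downstream operation can assume a clean, sorted spectrum. A
**spectrum record** attaches identity labels (genus, optional species and
strain), acquisition polarity, dataset of origin (culture collection or
field isolate) and resolution mode; a **database** is a set of records
with distinct ids sharing one resolution mode. The nominal acquisition
window m/z 100–1000 is informational only: out-of-range peaks are accepted
with a warning, since the window is an instrument setting, not a property
of the method.

## Preprocessing

The chain is fixed: *denoise → blank subtraction → (optional integer
conversion) → base-peak normalization*, applied once when a database is
built.

**Denoising.** Centroid lists carry no profile baseline from which to read
a noise level, so one is estimated from the intensity vector itself:
`noise = 1.4826 × MAD` (median absolute deviation, Gaussian-consistent
scaling); if the MAD is zero (a majority of identical intensities) the
fallback is 20% of the median, and if that is also zero nothing is
removed. Peaks below `snr × noise` are discarded (`snr = 5` by default).
Two consequences are worth knowing. First, on spectra whose intensities
are one broad (e.g. log-normal) signal population, a spread-based
threshold is aggressive: it retains roughly the top decile of peaks by
intensity. Identification then rests on the most intense, most
reproducible part of the fingerprint, which the tests show is sufficient
at both genus and species level. Second, a spread-based filter is **not
idempotent**: re-estimating the MAD on already-filtered intensities raises
the estimate (the surviving peaks carry the spread), so a second pass
would remove more. Denoising is therefore a one-shot operation; the rest
of the chain (blank subtraction, integer conversion, normalization) *is*
idempotent and is property-tested as such.

**Blank subtraction.** Any peak within ±`tol_ppm` of a medium-blank peak
is removed, the half-width computed from the blank (reference) m/z. The
default tolerance reuses the 5 ppm matching window.

**Integer-mass conversion.** m/z values are rounded half-to-even (the
rounding rule is centralized so it can be swapped) and coincident peaks
merged by intensity sum; total intensity is conserved to machine
precision. Spectra left with fewer than `min_peaks = 2` peaks — which
genuinely happens when sparse spectra collapse onto few integers — are
removed from the database with their ids reported.

**Normalization.** Intensities are divided by the base-peak intensity;
the maximum of the output is exactly 1.0. The unit scale (1.0, not 100)
keeps scores dimensionless.

## Peak alignment

Query and reference peaks may pair when the query m/z lies within
±`tol_ppm` of the reference m/z, the half-width computed from the
**reference** side — the database is treated as the calibrated standard,
which deliberately breaks exact query/reference symmetry. Among all
feasible one-to-one pairings the aligner returns the maximum-cardinality
matching of minimum total |Δm/z|, solved exactly (Jonker–Volgenant) on the
connected components of the candidate graph. With 5 ppm windows almost
every component is a single unambiguous pair, so the exact solve costs no
more than a nearest-neighbour sweep, but it is order-independent and
correct in crowded m/z regions where greedy acceptance can strand a peak
whose only partner was taken. Ties (equal |Δm/z|) are broken toward the
lower-m/z reference, then the lower-m/z query, via epsilon terms in the
cost matrix (1e-9/1e-12 per index — far below any physically meaningful
mass difference). A brute-force enumeration oracle over all matchings
confirms agreement on hundreds of random small instances whenever the
optimum is unique. Integer-mass matching uses the same algorithm with
±500 ppm, which at m/z ≤ 1000 is ±0.5, i.e. exact integer equality.

Aligned spectra become two equal-length intensity vectors over matched
pairs plus each side's unmatched peaks (the other side contributing 0),
so each vector sums to its spectrum's total intensity.

## Similarity measures

Three measures on the aligned vectors, each bounded in [0,1], symmetric,
1 iff the vectors coincide and 0 iff their supports are disjoint:
`Cos = ⟨a,b⟩/(‖a‖‖b‖)`; `Eu = 1 − ‖a−b‖²/(‖a‖²+‖b‖²) = 2⟨a,b⟩/(‖a‖²+‖b‖²)`;
`iEu` the same ratio with per-coordinate weights `wᵢ = aᵢ + bᵢ`, which
up-weights agreement on intense peaks. The relative-Euclidean forms were
chosen so that the identical→1 and disjoint→0 limits hold exactly; each
measure sits behind a registry so alternative formulations can be swapped
without touching the pipeline. All three are monotone under perturbing a
single matched intensity away from equality (property-tested).

## Identification and confidence

A query is scored against every reference sharing its polarity and
carrying a label at the requested level; the ranking is deterministic
(score descending, then reference id ascending) and the rank-1 entry is
the prediction. Species-level runs restrict both queries and references to
records with species labels, so genus-only field isolates participate only
at genus level. Leave-one-out evaluation queries every record against the
database minus itself; queries whose exclusion empties the candidate set
are recorded as unevaluable rather than dropped.

The **bootstrap confidence** of a prediction resamples the query's peak
indices with replacement at the original count; a peak drawn k times
appears once at k× its intensity, and the replicate is re-normalized. This
perturbs both peak presence (a fraction 1/e of peaks drops out on average)
and the intensity pattern, which is exactly what the stability of a top
hit should be probed against. The confidence is the fraction of
`n_bootstrap = 500` replicates (100 in the reduced test configurations)
whose top-hit label matches the original query's top-hit label — agreement
is measured against the original top hit, not a replicate majority. One
seeded generator drives a run; per-query child seeds are spawned from it
so results do not depend on evaluation order.

## Classifier assessment

Assessment treats "the top hit is correct" as the positive class and a
classifier score (similarity or confidence) as the decision variable.
Confusion matrices index true × predicted labels over the sorted union of
observed labels. Overall accuracy (trace/total) carries an exact
Clopper–Pearson 95% interval — conservative, and standard for
confusion-matrix reporting. ROC curves sweep thresholds at midpoints
between consecutive distinct scores plus ±∞ sentinels, so they start at
(0,0) and end at (1,1) in FPR coordinates; the trapezoidal AUC then equals
the Mann–Whitney pairwise probability with ties rank-averaged, which a
brute-force pairwise oracle confirms in the tests. AUC word ratings use
bands ≥0.9 excellent, [0.8,0.9) good, [0.7,0.8) fair, [0.6,0.7) poor,
[0.5,0.6) fail, <0.5 worse-than-chance. Sensitivity/error-rate tables
define, at threshold t, sensitivity = (correct with score ≥ t)/n and
error = (incorrect with score ≥ t)/(all with score ≥ t), and report for
each error cap the smallest threshold with error strictly below the cap
(which maximizes sensitivity); unachievable caps are flagged rather than
silently skipped. Note that a single confidently wrong top hit can make a
small error cap unachievable even when overall accuracy is high — at high
thresholds few identifications remain, so one error dominates the rate.

## Synthetic data

The generator produces labeled datasets with the features that make
single-cell fingerprint identification work and fail:

- **Taxonomy.** `n_genera = 9` genera × `species_per_genus = 2` species ×
  `cells_per_species = 20` cells by default. Each species in each polarity
  has a fingerprint of `fingerprint_size = 80` peaks, of which
  `genus_share = 0.8` (the genus core, m/z *and* mean intensities) is
  common to congeneric species. Fingerprint m/z are drawn from a
  three-band mixture — 100–330 (weight 0.6), 430–660 (0.3), 760–880 (0.1)
  — with at least 50 ppm spacing inside a fingerprint; the sparse high-m/z
  band gets a 5× mean-intensity boost ("few but pronounced" peaks). Band
  weights and boosts are calibration choices exposed in the config.
- **Cells.** A cell detects each fingerprint peak with probability
  `presence_prob = 0.85`; detected intensities are the fingerprint mean
  times log-normal noise (`intensity_cv = 0.5`), m/z jittered within
  ±2 ppm. `background_peaks = 15` uniform low-intensity peaks (5% of the
  typical fingerprint scale) and the 10-peak medium blank (jittered,
  to be removed by preprocessing) are added. The per-cell peak count is
  therefore binomial-plus-background and varies realistically.
- **Polarities and field isolates.** Cells split deterministically between
  polarities (`positive_fraction`); fingerprints are drawn per polarity.
  Optionally the last `n_field_genera` genera are emitted as field
  isolates whose records carry no species label, mimicking morphology-only
  genus identification; the ground-truth table retains the generating
  species.

What the generator does **not** emulate: isotope patterns, real metabolite
chemistry, correlated peak intensities, mass-calibration drift, or the
heavy-tailed per-cell peak counts (thousands of peaks) of real
acquisitions. Passing tests therefore demonstrate that the pipeline's
logic and statistics behave as designed under realistic structure, not
that any particular real-world accuracy will be reached.

## Test and reproduction problem sizes

The test suite and `scripts/acceptance.py` use reduced problem sizes
chosen to keep full runs to a few minutes while leaving every effect
clearly measurable: the standard dataset runs with 10 cells per species
(360 → 180 records), and the noisy bootstrap configuration uses 6 genera ×
2 species × 8 single-polarity cells with 100 bootstrap replicates. At
those sizes the observed behavior matches the full-size defaults: genus
accuracy 100%, species accuracy ~70% with all errors within-genus, a
high-res vs integer genus-accuracy gap under 2 percentage points, and
confidence AUCs of 0.63–0.76 against similarity AUCs near 0.47 on the
noisy configuration (3/3 measures improved). Statistical property tests
use fixed seeds; monotonicity sweeps on generator parameters compare
accuracies with a slack of 0.08, the scale of binomial sampling noise at
~100 queries.

## Known limitations

- The denoiser's behavior on signal-rich centroid lists (see above) makes
  preprocessing intentionally harsh; pass `PreprocessParams(snr=...)` to
  relax it. It is the right tool only when low-intensity content is
  expendable for identification.
- Open-set identification (rejecting cells whose taxon is absent from the
  database) is out of scope; every query is assigned its best hit.
- One-to-one matching ignores the possibility that one broad reference
  peak legitimately explains two query centroids.
- The exact Eu/iEu formulations in the wider literature vary; the forms
  here are normative for this package and all evaluation logic depends
  only on their [0,1]/identity/disjoint contract.
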