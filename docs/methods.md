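# Methods

This note documents the statistical procedures, the synthetic data model,
the numerical conventions, and the open design choices made in `asapml`.

## Preprocessing model

An ASAP-MS acquisition is one continuous scan stream (one scan per 0.9 s by
default) covering a leading background window and, nominally, five
sample-insertion windows.  Processing assumes:

- the acquisition *starts* with the probe absent, so the leading scans
  define the background total-ion-count (TIC) level;
- probe insertion raises the TIC sharply and roughly plateau-like;
- peak positions are only trusted to unit mass, so every scan is binned to
  integer m/z before any cross-scan arithmetic.

**Segmentation.** The baseline TIC is the median over the leading
background scans (the first `min_window_scans` scans seed the estimate). A
scan is *high* when its TIC is at least `rise_factor` (default 5) times
this baseline; every maximal run of at least `min_window_scans` (default 5)
consecutive high scans is a sample window, and shorter runs are discarded
as transients.  The median is used rather than the mean so isolated noise
scans cannot inflate the baseline.  A stream whose first scan is already
high has no identifiable background and is rejected.

**Binning.** Bin k covers [k − 0.5, k + 0.5): round-half-up.  Peaks outside
the configured range (default m/z 11–1000, 990 bins) are dropped and their
total intensity reported, so intensity is conserved up to the reported
drop.

**Background subtraction.** Elementwise subtraction of the background-window
mean spectrum from each sample-window mean spectrum, with negative
differences clipped to zero.  Clipping is required because the χ² feature
ranking downstream is defined for nonnegative features; the clipped mass is
reported so the distortion is auditable.

**Normalisation and averaging.** Each background-corrected replicate is
scaled to unit area; the replicates are then averaged arithmetically.  The
mean of unit-area vectors already has unit area, so the average is
deliberately *not* re-normalised — this fixes the pipeline order
unambiguously.  Replicate spread is summarised by the per-bin population
standard deviation (N divisor), the same convention used for within-window
scan statistics.

## Classification tasks and cohort construction

Eight clinical variables become binary tasks: mortality and heart-failure
diagnosis are plain yes/no labels; MVO splits at exactly zero (no
obstruction vs any obstruction); IMR, ischemic time, peak troponin and
creatinine split strictly below/above literature thresholds (40, 6 h, 50,
75); thrombus score splits 1–3 vs 4–5.  Two conventions are fixed here
because strict inequalities leave gaps:

- a continuous value exactly on a threshold is assigned to class 0 ("low")
  and counted in a boundary report;
- thrombus score 0 belongs to neither range and is treated as missing for
  that task, with a count.

No imputation is performed anywhere; missing labels are dropped before any
balancing.  Balanced datasets keep every minority-class sample and
undersample the majority class at random to the same count, so a classifier
cannot profit from guessing the majority.  Extreme-patient datasets take
the n smallest and n largest non-missing values (n = 20 or 30); ties are
broken by stable row order so the subsets are reproducible.  Mortality and
heart-failure diagnosis have no extreme variant (they are categorical), and
the grid runner rejects such requests at validation.

**Demographic augmentation.** Nine variables (age, weight, height, BMI,
BSA, smoking status, hypertension, diabetes, previous cardiological
history) can be appended as extra feature columns.  Patient sex is
deliberately excluded (too few female patients in the emulated cohort for
it to be anything but a shortcut).  Continuous variables are rescaled
linearly from their observed [min, max] onto [0, m], binary ones onto
{0, m}, where m is the median of all positive spectral intensities — this
puts them on the intensity scale so they cannot dominate distance-based
models.  Both m and the per-variable ranges are refitted on the training
rows of every partition, never on test rows.  Patients missing any
requested variable are dropped up front and counted.  Appended columns
carry a reserved `demo_` prefix and are excluded from m/z-peak selection
and from consensus reporting.

## Feature reduction

All three methods are fitted per partition on training rows only.

**Pearson gate.** Per bin, the Pearson correlation between intensity and
the 0/1 label (the point-biserial coefficient) with its exact two-sided
t-transform P-value; bins with P < α (default 0.05) are kept.  No
multiple-testing correction is applied by default — the plain gate is the
procedure being modelled — but a Benjamini–Hochberg variant is available
behind a flag.  Constant bins have undefined correlation, get P = 1, and
are never selected.  A Shapiro–Wilk normality fraction is reported on
request as a diagnostic of the parametric assumption; it gates nothing.

**Overlap integrals.** Per bin, both groups' intensities are histogrammed
on shared edges and normalised to unit sum; the overlap integral is the sum
of pointwise minima — 1 for indistinguishable groups, 0 for disjoint
support.  Edges span the pooled min–max with ⌈√n_pooled⌉ equal-width cells
(at least 5): symmetric in the groups, scale-adaptive, and trivial to
recompute by hand.  A degenerate pooled range (all values equal) counts as
full overlap.  The k = 40 smallest integrals are selected.

**χ² ranking.** The frequency-style χ² classification statistic on the
nonnegative intensities (per-class intensity sums against the marginal
expectation), via scikit-learn; the k = 40 largest statistics are selected.
This is the conventional reading of "χ² feature ranking" for continuous
nonnegative features; a quantile-binned contingency variant was considered
and rejected as a second arbitrary discretisation.

Ties at any selection cut are broken by ascending bin label, everywhere,
for determinism.

**Consensus.** A bin is a consensus feature when, for each of the three
methods separately, it is selected in strictly more than 75% of that
method's training partitions.  Consensus is counted per data partition;
the three methods are evaluated on shared splits so their partition counts
match.

## Evaluation

Datasets are repeatedly split 80:20 within each class
(floor(0.8 · n_class) to training), 200 times by default, each split a pure
function of a per-partition seed derived from the base seed by a counter —
any single partition is replayable.  Five classifier families are exposed
through a registry with pinned, overridable hyperparameters: KNN (k = 5,
Euclidean), SVM (RBF, C = 1, scaled γ), LDA (default SVD solver), Gaussian
naive Bayes, random forest (100 trees, seeded).  Accuracy and Cohen's κ are
computed from the test-set confusion counts; κ uses the marginal-product
expected agreement.  Partitions with an undefined κ (both marginals
degenerate) or an empty feature selection are excluded from the means and
counted, never imputed.  Summaries report mean ± population SD over valid
partitions, the small-sample significance gate (κ ≥ 0.6 for totals ≤ 50,
κ ≥ 0.5 for totals ≤ 60, else a configurable default of 0), and the
agreement band, with boundary κ values assigned to the lower band.

A practical observation encoded in the tests: unregularised LDA on 990
bins with ~40 training samples is unstable across cohort draws — the same
data that a selected-feature LDA, SVM or KNN classifies almost perfectly
can score poorly with full-spectrum LDA.  This is the expected behaviour of
a singular within-class covariance, and it is one reason feature reduction
is part of the design.

## Synthetic data model

The generator emulates the *structure* the analysis relies on, not plasma
chemistry:

- **Clinical table.** Continuous variables are log-normal with medians
  near the task thresholds (so both classes are populated) and per-variable
  missing fractions echoing the uneven availability of clinical follow-up
  data; MVO is additionally zero-inflated (55% exact zeros) because most
  treated patients show no residual obstruction; thrombus score is ordinal
  0–5; binary variables are Bernoulli at configurable prevalence
  (mortality 8.7%, heart failure 11%, male sex 82%, ...).  Every variable
  is masked missing independently.
- **Spectra.** A smooth strictly positive baseline profile over the 990
  bins; class-1 patients of the target task have their mean intensity
  multiplied by `effect_size` (default 3) at the planted bins (default six:
  114, 129, 156, 197, 387, 532).  Per-patient biological variation is
  multiplicative log-normal with CV `biological_cv` (default 0.2) — the
  instrument characterisation constrains only the replicate CV, so the
  biological level is a package choice: large enough that inter-patient
  spread is not purely measurement noise, small enough that a 3× planted
  effect remains recoverable, as any plausible planted-biomarker study
  design requires.  Replicate noise is multiplicative log-normal with CV
  `noise_cv` (default 0.3, under the < 0.4 protocol bound); replicates are
  unit-area normalised and averaged exactly as the preprocessing module
  would.  Patients with a missing target label receive baseline spectra.
- **Raw acquisitions.** Scan streams at the 0.9 s cadence: a leading
  background window, then five sample windows separated by background gaps;
  sample scans superimpose the area-scaled sample spectrum on the
  background at 10× the background TIC, with per-scan log-normal noise
  (CV 0.05) and sub-bin m/z jitter.  Ground-truth window boundaries travel
  with the simulated stream so segmentation is testable without manual
  annotation.

What the generator does *not* model — ion chemistry, adducts and fragments,
instrument drift, batch effects, correlated metabolite modules, label noise
— bounds what passing tests show: they validate the statistical machinery
(leakage-free selection, calibration of the null, recovery of planted
effects at realistic noise), not performance on real plasma.

## Numerical conventions and edge cases

- Unit-area spectra sum to 1 within 1e−9; binning conserves intensity to
  1e−9 up to the reported dropped mass; the zero-noise
  simulate → process round trip agrees to better than 1e−6.
- All randomness flows through `numpy.random.default_rng` seeds; per-
  partition seeds derive from `SeedSequence([base_seed, counter])` and stay
  below 2³¹.
- Population (N-divisor) standard deviations throughout; a single-partition
  summary has SD 0 by convention and is flagged.
- Quartiles in the box-plot summaries use linear interpolation
  (`numpy.percentile` default); whiskers end at the farthest point within
  1.5 × IQR of the box.
- The permuted-label null pools partitions over many fresh permutations
  (40 × 5 by default in the acceptance script) because a single permutation
  retains chance correlation with a planted effect and would bias the
  chance-level estimate.
- The mzML reader/writer is a minimal, self-contained implementation
  (MS1 scans, 32/64-bit float arrays, zlib or no compression) on lxml;
  CSV writers use 17-significant-digit formatting and readers round-trip
  parsing, so all plain-text round trips are value-exact.

## Known limitations

- The χ² statistic treats intensities as frequencies; its null distribution
  on continuous unit-area features is not χ²-distributed, which is why it
  is used only as a ranking, never as a test.
- Grid resumability is keyed by a content hash of the cell settings and
  input data; editing code between runs does not invalidate the cache —
  pass `force=True` after algorithmic changes.
- The CLI's `simulate` plants an effect for a single target task; cohorts
  with simultaneous effects on several tasks must be composed through the
  library API.
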