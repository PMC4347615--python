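# Methods

## Model and assumptions

The package treats protein subcellular localization as flat multi-class
classification of fixed-length feature vectors derived from one PSSM per
protein. Two assumptions underlie the features: (i) the PSSM rows are (after
normalization) probability distributions over the 20 amino acids, so column
means form a composition and argmax per row is well defined; (ii) a
physicochemical attribute is informative through its distribution along the
chain, which the segmented sums and lagged products summarize from both
termini. Multi-location proteins are handled by duplication: one sample per
annotated location, identical feature rows, distinct labels. Accuracy
Q = 100·C/N counts each such sample once, so the denominators match the
expanded sample counts rather than the distinct-protein counts.

## Substitution probabilities

PSI-BLAST ASCII PSSMs carry two numeric blocks. The default `prob_source`
uses the weighted-percentage block divided by 100 and row-renormalized
(all-zero rows, which PSI-BLAST emits for positions with no aligned
neighbours, become uniform 1/20). The alternative `sigmoid_logodds` applies
the logistic function to the log-odds block before renormalizing; it is
offered because parts of the literature normalize log-odds instead, and the
choice is recorded in output metadata so matrices from different settings
are never silently mixed. The percentage route is the default because those
values are the probability-like quantity in the file.

## Segmentation choices

* **Boundary mode.** The d% segment boundary is `length_fraction` by
  default: the first max(1, ⌊d/100·L⌋) residues. An alternative
  `mass_fraction` mode, placing the boundary where the cumulative attribute
  value reaches d% of the total attribute mass, is implemented because the
  two readings of a segment's extent (residue count vs. attribute mass) are
  both defensible; the mode is carried in feature metadata. Both modes are
  oracle-tested.
* **OSD statistic.** Segment features are raw sums of normalized attribute
  values (the global feature alone is a mean). A per-length-normalized
  variant (`normalize_osd_by_length`) converts sums to densities; it is off
  by default because the raw sum preserves segment-length information that
  the boundary percent alone does not carry once lengths vary.
* **Short segments.** An OSA lag that reaches past its segment (D_k − i ≤ 0)
  contributes 0 rather than NaN, keeping the vector length fixed at
  (2·7 + 1)·DF for every protein with L ≥ 2. PSSM-AC, by contrast, refuses
  proteins with L ≤ DF outright: a zero-padded auto-covariance would be
  indistinguishable from genuinely zero covariance, so short proteins are a
  named error the caller must resolve.
* **Right-side features** are computed on the reversed sequence, which makes
  the reflection symmetry (right block of a sequence = left block of its
  reversal) exact and testable.
* **Scale normalization** is per-scale min-max over the 20 published values,
  making the attribute sequence invariant to affine rescalings of the
  published table and guaranteeing the [0, 1] range the segment sums assume.
  A z-score-then-clip variant (±3 SD mapped to [0, 1]) is available.
  Normalization is never per-corpus, so feature values do not depend on
  which other proteins are present.

## Rotation Forest

The ensemble follows the canonical construction: per tree, a random disjoint
partition of the N features into ⌈N/3⌉ subsets; per subset, a random
non-empty set of classes, a 75% bootstrap of their rows, and PCA loadings of
that sub-matrix as the subset's orthonormal column block; blocks assemble
into a sparse N×M rotation (M ≤ N; eigenvalues ≤ 1e-12 are treated as zero
and dropped; a zero-variance subset contributes an identity block). The
base learner is a CART decision tree (scikit-learn), unpruned by default,
with an `entropy` criterion flag for closer fidelity to information-gain
splitting of C4.5-family trees. Ensemble size defaults to 100. Member
randomness derives from `numpy.random.SeedSequence(seed).spawn`, so
fit + predict is a pure function of (X, y, config). Vote ties resolve to the
lowest class index in the sorted class list.

## Cross-validation

Folds are assigned to protein groups, not samples: groups are shuffled,
then placed largest-first onto the currently smallest fold. This keeps
duplicated multi-location samples on one side of every train/test boundary
(preventing self-leakage through their identical feature rows) while fold
sizes stay within 1 for all-singleton data. Folds are random rather than
stratified, with stratification deliberately out of the default path; empty
per-location accuracies are reported as missing, not 0, so a location with
no test samples is distinguishable from one classified entirely wrongly.

The paired t-test utility computes the t statistic on the differences
directly and takes the p-value from the t distribution (scipy); all-zero
differences are a degenerate error rather than p = NaN.

## Synthetic corpora

The fixture generator emulates the structure of PSSM benchmark corpora
without any biology: class c's base composition is softmax(s·z_c) with z_c a
fixed standard-normal 20-vector and s the `class_signal`; each protein's
PSSM rows are Dirichlet(concentration·base) draws; lengths are uniform in
`length_range`. Defaults (50 samples/class, L ∈ [50, 200], concentration 20,
signal 0.5) give a corpus that the full pipeline separates essentially
perfectly, while signal 0 gives chance-level accuracy — the two calibration
points the test suite checks (a binomial test against chance at α = 0.01 for
the null, ≥ 95% 10-fold accuracy for the separable corpus). An imbalanced
8-class preset (56/12/41/13/4/2/2/18) exercises per-location reporting with
tiny classes. What the generator does **not** emulate: homology between
proteins, positional conservation structure, biologically plausible
transition patterns, or any relationship between a class and real cellular
compartments. Passing tests therefore demonstrate that the machinery is
correct and that composition signal propagates through all four feature
groups — not that any particular accuracy is attainable on real corpora,
which additionally depends on the PSSM database and search settings.

## Problem sizes and numerics

The test suite and acceptance script run on corpora of 40–200 samples with
ensembles of 25–100 trees — sizes chosen so a full run completes in a few
minutes on one core while still exercising 401-feature vectors and 10-fold
splits at the defaults. Feature computations are validated against naive
brute-force reimplementations (math.fsum loops) to 1e-12 on random inputs
with lengths up to 500. Feature matrices are written with `%.17g` and read
with round-trip float parsing, so a rebuild from the same corpus and
configuration is byte-identical; a short configuration hash is embedded in
CSV and report metadata for provenance.

## Known limitations

* The CART base learner is not a faithful C4.5/J48 reimplementation
  (pruning, missing-value handling and gain-ratio details differ).
* Only the ASCII PSSM dialect is parsed — no binary checkpoints, no XML.
* One attribute per feature matrix by design; multi-attribute concatenation
  is a thin extension the caller can do by column-binding matrices.
* Per-location accuracy on very small classes (a handful of samples) is
  inherently noisy; the reporting keeps such classes visible but cannot make
  them statistically meaningful.
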