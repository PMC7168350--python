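# Methods

## Problem and model

The task is binary classification of 41-bp DNA windows (alphabet
A, C, G, T, N; a C fixed at the center, 1-based position 21) into 4mC
and non-4mC. The model is a score-fusion ensemble: six sequence
encodings, one random forest per encoding, and a convex combination of
the six positive-class probabilities with weights fitted on out-of-fold
cross-validation scores. Nothing in the architecture is specific to
41 bp; the window length `w` is a parameter everywhere, with dimensions
derived from it (one-hot `5w`, dinucleotide-binary `4(w−1)`, EIIP `w`).

## Encodings and their conventions

Where a construction admits more than one reading, the convention used
here is fixed and documented so feature indices are stable across runs:

- **Kmer** counts are normalized to frequencies, count/(w−k+1), so
  features are length-independent and bounded in [0, 1]; each k-block
  over the full 5-letter alphabet then sums to exactly 1.
- **Canonical ordering** is lexicographic over A, C, G, N, T for k-mers
  and ordered pairs. The one-hot channel order is A, T, G, C, N.
- **KSNC** spacing `d` counts intervening bases: the pair is
  (seq[p], seq[p+d+1]) and the normalizer w−d−1 is the number of valid
  positions, which is what forces this reading.
- **DBE** uses the 2-bit base code A=00, T=01, C=10, G=11 — the unique
  assignment consistent with the four published example codes
  (AT→0001, AA→0000, GG→1111, AC→0010). N-containing pairs are 0000,
  making the 16 standard codes bijective and N windows all-zero.
- **EIIP** values: A 0.1260, C 0.1340, G 0.0806, T 0.1335, N 0.
- **DPC** feature (pair, property) = pair frequency among the w−1
  overlapping dinucleotides × property value. The 15-property table is
  a curated stand-in: the identity of the original property set is cited
  to prior publications without being listed, so the bundled table
  (`data/dinucleotide_properties.tsv`) assembles 15 standard
  conformational and thermodynamic dinucleotide parameters (step
  geometry: twist, tilt, roll, shift, slide, rise; stacking energy;
  nearest-neighbor enthalpy, entropy and free energy; melting
  temperature; propeller twist; protein-induced deformability;
  bendability; duplex disruption energy), min–max normalized to [0, 1]
  over the 16 standard pairs. The table is injectable
  (`PropertyTable`), so an alternative convention (e.g. positional
  averaging, different property sets) can be swapped in without code
  changes.

## Feature selection

Features are ranked per encoding by the two-sided Wilcoxon rank-sum
(Mann–Whitney) p-value between classes, ascending, ties broken by
original index. The p-value uses the normal approximation with tie
correction (adequate at ≥20 samples per class; the test suite checks it
against exact enumeration at small n). Constant features get p = 1 by
convention and sink to the bottom. No multiple-testing correction is
applied: the p-values rank features, they are not inferential.

The retained dimensionality k is chosen by sweeping a grid (default:
steps of 10 up to the scheme dimension, which places the reference
optima 160/80/110 on the grid) and scoring each k by mean 10-fold CV
AUC of a random forest, with the ranking recomputed inside each
training fold so selection never sees held-out data. The final feature
set is recomputed on the full training data at the winning k; ties
favor the smallest k. Default retained dimensionalities are Kmer 160,
KSNC 80, DPC 110, with MBE, DBE and EIIP keeping all features (their
selected versions do not beat the full-dimension control).

## Classifier and fusion

Forests default to 500 trees, √p features per split, unlimited depth —
the defaults of the classic randomForest implementation. The classifier
slot is pluggable (anything with `fit`/`predict_proba`), but only the
random forest ships. All stochastic steps (fold assignment, bootstrap)
derive from one user-visible seed.

Fusion weights live on the probability simplex discretized at grid step
0.05 (inferred from the published weight profile, all multiples of
0.05). The search enumerates all compositions (≈53k points for six
schemes) exactly rather than using a heuristic optimizer; AUC per grid
point is computed via the rank-sum identity, vectorized in chunks.
Weights are fitted on out-of-fold CV scores, not resubstitution scores,
to avoid overfitting the fusion; ties break toward fewer nonzero
weights, then the lexicographically smallest vector, so the search is
fully deterministic. Because every vertex is on the grid, the fused
out-of-fold AUC can never be below the best single encoding.

## Evaluation

MCC, accuracy, sensitivity and specificity follow the standard
confusion-matrix formulas; a sample is called positive at score ≥
threshold (≥, not >, so threshold 1.0 is reachable). MCC is defined as
0 when any denominator factor vanishes. AUC is the trapezoid area under
the threshold-sweep ROC, identical to the Mann–Whitney statistic with
half-credit ties (the suite verifies the equivalence by exhaustive pair
enumeration). Specificity control picks the smallest threshold whose
specificity reaches the target, then reports sensitivity there; an
unreachable target raises with the achievable maximum. Model
comparisons use a paired two-tailed t-test across CV folds — the only
repeated measurements available — with p = 1 by convention for
identical fold vectors. This paired-over-folds reading is an
interpretation choice, documented as such.

## Synthetic benchmark generator

The generator emulates the statistical structure of real 4mC
benchmarks: position-specific C enrichment and A depletion in the
positive class. Negatives draw each non-center base i.i.d. from a
background distribution (default uniform, n_rate = 0 — the simplest
exchangeable null; a genome-like background or N substitution can be
configured). Positives are identical except at a chosen informative
position set, where mass `effect` moves from A to C (clipped at zero,
renormalized). The center is always C.

What it does not emulate: genome-wide composition, dinucleotide
dependency within windows, redundancy between windows, and
sequencing-quality filtering. Passing the planted-signal tests
therefore shows that the pipeline recovers position-specific
compositional signal at realistic sample sizes — not that it attains
any particular accuracy on real mouse data, for which the original
benchmark would be required.

Study conditions used by the tests and the acceptance script: 500
windows per class for calibration runs (null: effect 0, fused CV AUC
expected in [0.45, 0.55]; planted: effect 0.3 at 10 flanking positions,
fused CV AUC ≥ 0.85), and a 906+906 benchmark split 746/746 + 160/160
for the end-to-end run, mirroring the reference dataset geometry. The
calibration runs use 150-tree forests — forest size is a free
hyperparameter and AUC is flat in it well below 500 trees at these
sample sizes — while the end-to-end run keeps the 500-tree default.

## Numerical and degenerate-input choices

- Validation is strict by default (wrong length, non-ACGTN characters,
  non-C center are errors naming the record); a lenient mode skips bad
  records with a warning. Characters outside the alphabet are never
  silently mapped to N.
- The train/test splitter takes an absolute per-class test count, not a
  fraction, so printed counts reproduce exactly; it is stratified,
  disjoint and exhaustive for every seed.
- Sequences are used as given; no reverse-complement augmentation.
- Prediction tables print scores with 4 decimals; round-tripping
  reproduces scores to that precision.
- Empty datasets, single-class labels, out-of-range k or dmax, and
  off-simplex weights all raise immediately with specific messages.

## Known limitations

- The DPC property table is a documented stand-in (see above); results
  depending on specific property identities should swap in their own
  table.
- The Wilcoxon p-values are asymptotic; at fewer than ~10 samples per
  class the ranking is still sensible but the p-values are approximate.
- The simplex grid search scales exponentially in the number of
  schemes; at step 0.05 it is exact and fast for six schemes, but a
  finer step or many more schemes would need a different strategy.
- Synthetic benchmarks bound what the tests can certify about real
  genomic data (see generator section).
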