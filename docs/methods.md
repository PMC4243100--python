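# Methods

## The selection model

RESI treats a feature's predictive power as a distribution over instances
rather than a scalar. On a single feature axis, each instance's
*neighbourhood purity* is the fraction of its k nearest neighbours (distance
|x_v − x_u|, the instance itself excluded) sharing its class label; purity is
always a multiple of 1/k. An instance is clear-discerned when purity exceeds
µ strictly and blur-discerned otherwise. Redundancy between features is the
REMI ratio: the fraction of the *candidate's* blur set also blurred on an
already-selected feature. The merit of a candidate is its absolute
unequal-variance two-sample t-statistic minus the mean REMI to the selected
set; selection is greedy forward search after an ε-filter on |t|.

Assumptions worth keeping in mind:

* **Binary labels only.** The t-statistic and the blur bookkeeping are
  two-class constructs; multi-class data is rejected at the door.
* **REMI's penalty is bounded by 1** while |t| is unbounded. Redundancy can
  therefore only reorder features whose relevance differs by less than one
  merit unit. This is intrinsic to the merit's additive form.
* **Purity is metric, not ordinal.** Neighbourhoods depend on actual
  distances on the feature axis, so purity is invariant under positive
  affine maps of a feature but *not* under arbitrary strictly monotone
  transforms (a transform that stretches one side of a value can hand an
  instance a different neighbour). The property tests assert the affine
  invariance, which is the one that actually holds.

## Numerical and tie-break choices

* Clear/blur comparison `count/k <= µ` is made in exact rational arithmetic
  on the binary value of the float µ supplied, so boundary purities can
  never flip with rounding; with k = 3 and µ = 0.66, purity 2/3 is clear.
  Note that µ = 2/3 passed as a double is strictly below the rational 2/3.
* REMI with an empty candidate blur set (0/0) is defined as 0: a feature
  that clear-discerns every instance neither needs nor causes a penalty.
* The candidate is the *first* REMI argument: the penalty is normalised by
  the candidate's own blur count. The reversed normalisation would ask how
  much of the selected feature's failure set the candidate covers; the
  implemented direction asks how much of the candidate's failure set is
  already covered, which is the form used throughout.
* Variances (t-statistic, fold standardization) use the n−1 sample
  convention. Zero-denominator t is 0 for equal means and signed infinity
  (maximal relevance) otherwise.
* All argmax ties break to the lowest feature index. In the greedy
  mutual-information loop, merits that agree to 1e-9 are treated as tied
  before that rule applies, because mathematically equal criteria reached
  through different floating-point paths (e.g. mIMR vs JMI) can differ by an
  ulp.
* Purity profiles and blur masks are computed once per surviving feature and
  reused across the whole greedy loop; the loop itself is a boolean
  matrix-vector product per step. Selecting 80 of 2,000 features at n = 60
  takes a fraction of a second on one CPU.

## Comparator criteria

MIFS, mRMR, MIFS-U, mIMR/JMI and CMIM/IF are implemented as their standard
merit functions over plug-in mutual information (base 2) of MDL-discretized
features; CFS is the canonical subset merit k·r̄_cf / √(k + k(k−1)·r̄_ff)
with symmetrical uncertainty as the correlation. β for MIFS/MIFS-U has no
default and must be supplied. The equivalences CMIM ≡ IF (chain rule),
JMI ≡ mIMR (per-step constant offset) and mRMR ≡ MIFS with β = 1/(p−1) are
asserted numerically in the tests rather than assumed.

Fayyad–Irani discretization accepts a boundary only when its information
gain exceeds (log2(n−1) + Δ)/n with the usual three-way coding term Δ; on
cohorts of a few dozen samples this is deliberately conservative, and a
feature with no accepted cut is treated as carrying no information about the
label. Discretization is always fit on training data only; test values are
coded by thresholding against the fitted cut points.

## Evaluation protocol

Stratified 10-fold cross-validation repeated 10 times (fold partitions
shared by all selectors and classifiers within a repetition). Inside each
fold: standardize on the training split (zero-SD features map to zeros),
fit the selector on the training split only, truncate its ranking at each
requested dimension, train each classifier on the selected columns, score
balanced accuracy on the test split. The positive class is always the
minority class. The default classifier registry holds linear SVM (C = 1), a
degree-2 polynomial-kernel SVM (the common non-linear choice when the
degree is otherwise unspecified), 3-NN, logistic regression, Gaussian naive
Bayes and an entropy-split decision tree.

Method comparisons use a paired two-sided t-test per (dataset, classifier)
cell. The pairing unit is the 10 repetition means by default — fold-level
scores within a repetition are not independent, and pairing on repetition
means keeps the test's nominal level honest; fold-level pairing is available
by flag (and is used when only one repetition exists). A dimension can be
fixed, or the sweep is averaged within each pairing unit. Verdicts conserve
counts: wins + ties + losses equals the number of cells compared.

## The synthetic generator

The generator emulates the small-n / large-m expression regime: by default
60 instances with a 20/40 class split (matching the imbalance of typical
small tumour cohorts), two relevant features, one exact duplicate, one
complementary pair, and 200 irrelevant features.

* **Relevant** features are class-conditional Gaussians shifted by
  ±effect_size/2 (default 2 SD — a strong but realistic marker), empirically
  standardized within class so the planted sample effect size is *exact*.
  Every planted informative feature therefore carries an identical |t|, and
  the order in which a selector takes them is decided purely by redundancy
  structure — the property the generator exists to probe. Because the
  redundancy penalty is bounded by 1, plantings whose sample |t| values
  scatter by more than a merit unit would conflate relevance noise with
  redundancy handling.
* **Duplicates** are exact or noisy copies of a relevant source; an exact
  copy shares its source's blur set, so its REMI to the source is 1 whenever
  the source blurs at least one instance.
* **Complementary pairs** split the cohort into two class-balanced halves;
  each member separates the classes cleanly (separation 3×effect_size,
  cluster SD separation/40) on its half and is mid-scale noise
  (SD separation/12) on the other, then is within-class standardized like
  the relevant features. The clean-half margin makes those instances
  clear-discerned with near certainty, so the two members' blur sets are
  disjoint and REMI between them is 0 — the construction realises the
  "fully complementary" end of the measure by instance bookkeeping, which
  value-similarity measures cannot see.
* **Irrelevant** features are raw standard normals, so their |t| follows the
  two-sample null (about 5% beyond |t| = 2).

What the generator does **not** model: probe/batch effects, heavy tails,
correlated noise blocks, dropout. Passing the recovery tests shows the
algorithm orders planted redundancy structure correctly under clean Gaussian
noise; it does not certify behaviour under real microarray artefacts.

## Data handling

Delimited matrices load in either orientation (always stated explicitly,
never guessed). Missing cells (empty or "NA") are imputed with the feature
mean over non-missing entries at load time — before any cross-validation
split, which leaks a vanishing amount of information through the imputed
means; fold-internal imputation would require keeping missingness masks
through the harness and is not implemented. Values survive a write/load
round trip bit-identically (floats are written at full precision and parsed
with correctly-rounded conversion).

## Problem sizes in the test suite

The suite and the acceptance script run everything at desk scale: oracle
cross-checks on ≤ 30×10 matrices, recovery over 50 generator seeds at
60×205, calibration of the win/tie/loss verdict on 2,000 simulated null
pairs, and a single 60×2000 timing run. These sizes make every property
checkable in seconds while staying inside the regime the method targets
(n ≪ m).

## Known limitations

* Strictly binary classification; no multi-class extension.
* The ε filter applies to |t| on the data as given; ε = 0.1 tacitly assumes
  roughly standardized expression values.
* No merit-threshold default for early stopping (`min_merit` is off unless
  set); the dimension bound is the operative stop.
* The CFS merit is provided as a scoring function for subsets in the same
  greedy harness; best-first subset search is out of scope.
* Win/tie/loss tables on the published fourteen-cohort benchmark are not
  reproduced here — they require the external datasets; the procedure that
  would produce them is implemented and tested on synthetic data.
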