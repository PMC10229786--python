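# Methods

## Problem and model

Resting-state fMRI cohorts are small relative to the dimensionality of the
features they yield: a 116-region parcellation produces 6,670 pairwise
Pearson correlations per subject, while clinical cohorts often have tens of
subjects per class. `stdac` expands the training set with two augmentation
rules that exploit structure specific to ROI-level BOLD time series, then
fuses the two resulting classifiers.

A subject is a matrix X in R^(t x m) (t time points, m ROIs), z-scored per
column. The functional brain network (FBN) is the m x m sample Pearson
correlation matrix of the columns; the classifier feature vector is its
upper triangle (m(m-1)/2 entries, no feature selection, no Fisher transform,
no sparsification).

### Spatial augmentation

Spatially adjacent regions carry similar signals, so replacing each node's
series with the mean over a constrained nearest-neighbor set produces a
plausible new subject. The neighbor set C_i of node i contains i itself plus
at most k other nodes, each strictly closer to i than any excluded node and
strictly inside a radius r*D, where D is the largest inter-centroid distance
in the atlas:

    |C_i| <= k + 1,    d(i,s) < d(i,j) for s in C_i, j not in C_i,
    d(i,s) < r*D, 0 < r < 1.

The updated column is y_i = mean(C_i), computed from the *original* columns
for every node (no sequential update). A degree-g spatial augmentation emits
one sample per k = 1..g; k is the only free parameter that differentiates
the samples. Self-inclusion in C_i is what makes |C_i| <= k+1 coherent and
gives the exact identity at k = 0. Distance ties break by ascending node
index so output is deterministic. Default r = 0.5; the radius is a cap, not
a target, so moderate changes matter only for sparse atlases. Augmented
samples are not re-z-scored: Pearson correlation is invariant to per-column
affine rescaling, so renormalization would change nothing downstream.

### Temporal augmentation

An augmented sample keeps l of the t time points, drawn uniformly *without
replacement* and possibly non-contiguous, the same index set applied to all
ROIs jointly (independent per-ROI slicing would destroy the inter-regional
alignment that correlation measures). Rows are kept in ascending original
order; correlation is row-permutation invariant, so the order is purely
cosmetic. This is a random-subset analogue of jackknife resampling: the mean
of subsample correlation matrices approaches the full-sample matrix, so each
draw is an unbiased-ish, distinct training sample. Defaults: l = ceil(0.7 t)
fixed across draws, floor l_min = ceil(0.5 t) to keep draws from becoming
too sparse, degree 100. An option draws l uniformly in [l_min, l] per
replicate instead. Each draw's stream derives from
SeedSequence([master_seed, subject_index, replicate_index]), so sample sets
are byte-reproducible and independent of generation order.

### Fusion

Each branch classifier emits a per-class probability vector for a test
subject's *original* FBN features. The fused feature is

    omega = f(s_spatial s_temporal^T)

flattened row-major (spatial index major) and normalized by f, which
subtracts the mean and divides by the standard deviation of the c^2 entries
(per sample, not per batch, preserving test-time independence; a
zero-variance product yields the zero vector with a log note rather than an
error). The outer product is rank-1 and preserves every pairwise interaction
of branch scores, unlike concatenation. A third classifier maps omega to the
final label.

Probabilities (not margins) are used for all classifier kinds because the
product needs both vectors on a shared nonnegative scale. The fusion
classifier is trained on the fused scores the two branches assign to the
original (unaugmented) training subjects — mirroring the test-time contract;
pairing arbitrary spatial with temporal augmented samples has no principled
definition.

### Branch training sets

Branch classifiers (and the single-branch SDA/TDA schemes) are trained on
the augmented samples only; original subjects enter training solely through
the fusion stage and serve as the test-time inputs. This follows the scheme
description (train on augmented, test on original) and keeps the two
branches' training sets disjoint in construction.

## Classifiers

Three kinds, selected by name with seeds fixed by config:

- `svm` — linear-kernel SVM (liblinear) with Platt-style sigmoid calibration
  (3-fold) for probability outputs; one-vs-rest for multiclass. The linear
  formulation scales to the 100x-augmented training sets (thousands of
  samples x thousands of edge features) where a kernel SMO solver would not.
- `rf` — 500-tree random forest.
- `ann` — one-hidden-layer (100 unit) feed-forward network.

Defaults are deliberately plain; no hyperparameter search is performed
(nested CV is out of scope).

## Cross-validation protocol

Stratified k-fold (default 10). Stratification is used because per-class
counts in realistic cohorts are small enough that unstratified folds can
lose a class from a training fold entirely. Augmentation happens strictly
inside each training fold; before any model is fitted, every training
sample's provenance (source subject id) is checked against the test fold and
a violation raises `LeakageError`. Metrics: Accuracy (%), per-class
Precision and Recall (%), and macro Precision (the aggregation of a single
"Precision" number over classes is ambiguous, so both are reported). ROC and
trapezoidal AUC are produced for binary tasks only, from pooled test-fold
scores with the lexicographically second class as positive. Within one run
the SDA classifier is the spatial branch and the TDA classifier the temporal
branch (identical data, kind and seed), so each branch is fitted once per
fold and shared across schemes.

## Interpretation

Edge importances per classifier kind: mean absolute linear coefficients
(SVM, averaged over calibration folds and one-vs-rest rows), Gini impurity
importances (RF), input-layer absolute weights summed over hidden units
(ANN). Importance vectors from several trained models (e.g. the per-fold
models, or the two branches) are averaged, min-max normalized to [0, 1], and
ranked; ties break by ascending edge index. An ROI's weight is the sum of
its incident normalized edge weights, so sum(roi_weights) is exactly twice
the edge-weight total. Exports include BrainNet-Viewer `.node`/`.edge`
files.

## Synthetic cohorts

Pearson correlation is the analysis target, so second-order structure is the
sufficient statistic to emulate: subject rows are i.i.d. draws from
N(0, Sigma_class), plus white noise (sd 0.25 by default — mild measurement
noise that shrinks correlations by ~6%), then z-scored per column. The
background correlation is rho^|i-j| with rho = 0.3 (smooth, always positive
definite); group effects are additive deltas on chosen edges, with a
Cholesky positive-definiteness check before any sampling. Geometry is a
jittered cubic lattice (10 mm step, 10% jitter), giving realistic
nearest-neighbor structure without a real template.

Defaults mirror a typical ROI-level cohort: t = 137 time points, 20 subjects
per class, two classes, and five planted edges with deltas 0.4-0.6; m = 30
regions keeps the default profile fast (m = 116 matches the AAL template and
works, just slower). What this generator does *not* emulate: hemodynamic
autocorrelation, non-Gaussian BOLD artifacts, site/scanner effects, and
subject-level covariance heterogeneity within a class. Passing tests
therefore establish the pipeline's correctness and calibration, not
clinical-grade performance on real rs-fMRI.

With these planted effect sizes the synthetic task is strongly separable
(baseline classifiers can reach ceiling), so the augmentation-benefit check
is directional — fusion must never fall below the original scheme or below
the weaker branch — rather than a claim of a specific accuracy margin.

## Numerical choices and edge cases

- Correlations are clipped to [-1, 1] and diagonals forced to exactly 1.
- A constant ROI column is always fatal (load, z-score, and FBN stages all
  name the offending node); a Pearson estimate needs >= 3 time points.
- Fold, temporal-draw and classifier seeds all derive from one master seed
  via SeedSequence, recorded in every result object.
- Problem sizes in the test suite and acceptance script are scaled to
  desk-top runs: the scheme-comparison harnesses use 5-20 master seeds of
  the default cohort; the law-of-large-numbers check uses one noise-free
  subject at t = 10,000.

## Known limitations

- The fusion stage assumes both branches were trained on the same label set;
  class orders are checked and mismatches are fatal.
- Multiclass ROC is out of scope (binary only).
- Anatomically informed (non-Euclidean) neighborhoods and regularized FBN
  estimators (graphical lasso, partial correlation) are out of scope.
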