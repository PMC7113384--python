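# Methods

This note documents the models and procedures `afpscan` implements, the
parameters that matter, the numerical choices, and what the synthetic study
does and does not demonstrate.

## The evolutionary encoding

A PSI-BLAST PSSM assigns each position of a query protein a 20-vector of
log-odds substitution scores: entry *Z* at position *i* measures how often
the query residue at *i* is replaced by residue *Z* among related sequences,
relative to chance. The encoding sums all rows sharing the same query
residue *X* into a 20 × 20 matrix and flattens it row-major over the
canonical PSI-BLAST residue order (A R N D C Q E G H I L K M F P S T W Y V),
giving 400 features labelled "X-Z" with flat index 20·pos(X) + pos(Z).

Properties that follow directly: the encoding is position-free (permuting
positions changes nothing) and additive over sequence segments. Feature
values are raw sums, so longer proteins produce larger-magnitude vectors.
We deliberately do not normalize by length — the features are occurrence
totals, and scale is handled once by the classifier's standardizer — but
`encode_profile(..., normalize_by_length=True)` is available for
experimentation.

Only the signed log-odds block of the PSSM file is used by default. The
sign is what carries the conservation reading (negative X–Z = replacement
rarer than chance = X conserved), which is the interpretation the whole
pipeline rests on. The percentage block can be selected with
`read_pssm(..., block="percent")` but is not part of the standard workflow.

## MWMOTE

AFP data sets are strongly imbalanced (roughly 1:19 before filtering), and
an SVM trained on the raw data concentrates on the majority class. MWMOTE
augments the minority class with synthetic samples that are (a) weighted
toward the decision border and (b) confined to observed minority clusters:

1. Minority points whose k₁ = 5 nearest neighbors (among all points)
   contain no minority point are treated as noise and excluded.
2. The borderline-majority set is the union of the k₂ = 3 nearest majority
   neighbors of each remaining minority point.
3. The informative-minority set is the union of the k₃ = ⌊n_min/2⌋ nearest
   minority neighbors of each borderline-majority point.
4. Each informative sample x is weighted by
   Σ_y Cf(y,x) · Df(y,x) over borderline-majority points y, with closeness
   factor Cf = min(1/d̄, Cf_th) · (CMAX/Cf_th), d̄ the Euclidean distance
   divided by the feature dimension, Cf_th = 5, CMAX = 2, and density
   factor Df(y,x) = Cf(y,x)/Σ_x' Cf(y,x'). Weights normalize to selection
   probabilities.
5. Minority points are clustered by average-linkage agglomeration cut at
   Cp = 3 times the mean nearest-minority-neighbor distance. Each synthetic
   sample is x + α(y − x) with x drawn by its selection probability, y
   uniform from x's cluster and α ~ U(0,1), so synthetics never leave the
   convex hull of a cluster; a singleton cluster reproduces x itself.

Degenerate inputs degrade gracefully: if the noise filter removes every
minority point, sampling falls back to uniform over the minority class with
a logged warning rather than an exception.

The number of synthetics is ⌈r · n_majority⌉ − n_minority for target ratio
r, default r = 0.78 — the training-set balance the pipeline aims for. All
neighborhood constants are configurable; the defaults follow the method's
original description, since the choice is not determined by anything in the
data. Distances are computed on raw features; an imbalance-aware scaling of
the feature space is left to the caller.

## Ensemble mRMR and incremental selection

Features are discretized into 3 states split at μ − σ and μ + σ (constant
features collapse to one state), and scored by plug-in mutual information
in nats. Ranking is greedy mRMR with the difference criterion: the first
pick maximizes MI(f; label); each later pick maximizes MI(f; label) minus
the mean MI with the already-selected features. Scores within 1e-9 of the
step maximum are treated as tied and resolved toward the lower feature
index, so last-bit summation noise cannot reorder genuinely equal scores.
The quotient (MIQ) criterion is not implemented; the difference form is the
common default and the one our tests oracle against.

The consensus ranking aggregates 20 stratified bootstrap resamples
(rows drawn with replacement within each class) by mean rank position,
Borda style, with features absent from a resample's top-K charged rank
K + 1. The ensemble makes the ranking robust to individual samples at the
cost of determinism only through the seed.

Incremental selection trains an SVM on the top-k features for k = 1, 2, …
and records five-fold CV metrics on the training table and metrics on the
independent test partition. The retained model is the one *preceding* the
first strict decrease of the monitored test metric (default AUC); a plateau
does not stop the search, and if no decrease occurs up to K_max the full
K_max-feature model is kept and logged. A stricter mode requires a
simultaneous decrease in AUC, ACC and SN before stopping. K_max defaults
to 200; the synthetic studies in the tests and the acceptance script use
K_max = 15, which is past the point where the planted signal saturates.

## Classifier and metrics

The classifier is an RBF-kernel SVM on features standardized with
training-partition statistics only. Hyperparameters are chosen by mean
five-fold CV AUC over a grid (full grid: C ∈ 2⁻⁵…2⁹, γ ∈ 2⁻¹⁵…2³ at
octave-of-four steps; a coarse 3 × 3 `fast_grid` serves the inner loops of
incremental selection), with ties resolved toward smaller C then smaller γ.
No class weighting is applied by default — imbalance is handled by MWMOTE.
Models serialize to JSON (scaler statistics, hyperparameters, support
vectors, dual coefficients, intercept) and a deserialized model reproduces
decision values exactly.

Metrics: SN = TP/(TP+FN), SP = TN/(TN+FP), ACC = (TP+TN)/N, MCC by its
closed form with the value defined as 0 when any marginal is empty, and AUC
by pair counting with tied score pairs worth ½, computed through the
Mann–Whitney rank statistic (exactly equal to exhaustive pair counting).
AUC is reported as NaN when only one class is present.

## Two cross-validation modes

Oversampling before cross-validation leaks information: synthetic rows
interpolated from the whole training set appear in CV training folds while
their parents sit in the validation fold. The pipeline therefore has two
modes. `paper-faithful` oversamples the training partition once and runs CV
on the balanced table — the protocol matching the original study design and
the default for reproducing it. `leakage-safe` (the pipeline default) ranks
features on the raw training partition and applies MWMOTE inside each CV
training fold only. In both modes the independent test partition is split
off before any oversampling, never contains synthetic rows, and the final
model for test evaluation is trained on the balanced training partition, so
test-set metrics are computed identically; only the CV estimates differ.

## PCA contributions

PCA runs on standardized features by default (the selected substitution
features have heterogeneous scales). Components are ordered by decreasing
variance and sign-fixed so each component's largest-magnitude loading is
positive. The contribution of feature i to component j is
r²ᵢⱼ / Σᵢ r²ᵢⱼ with rᵢⱼ the sample Pearson correlation between the raw
feature values and the component scores — computed from the data, not read
off the loadings, so the statistic is identical under covariance- or
correlation-matrix PCA and invariant to component sign flips. Columns sum
to 1; a component uncorrelated with every feature yields an undefined
(NaN) column. With p equally correlated features every contribution is 1/p,
the reference value for judging dominance.

## The synthetic study

The generator draws sequences uniformly over the 20 residues (lengths
uniform in 50–300 by default), background scores integer-uniform in
[−5, 5], and shifts the Z-column score of rows carrying residue X by −δ for
positives and +δ for negatives at each planted (X, Z) pair, plus Gaussian
noise (σ = `noise_sd`) rounded back to integers so fixtures remain valid
PSSMs. The default seven planted pairs are C-A, W-M, G-A, R-S, R-R plus
the conservative extras E-D and K-Q. The sign convention encodes
conservation: a depressed X→Z score in positives means X resists
replacement in the positive class. The default study conditions are
n_pos = 200, n_neg = 800, δ = 8, noise σ = 2 — an imbalance of 1:4 and a
per-feature separation of several within-class standard deviations after
aggregation over ~length/20 positions per residue.

A shortcut generator (`simulate_feature_table`) emits 400-column tables
directly — planted columns are Gaussians at ∓δ/2 with σ = `noise_sd`,
everything else standard normal — for tests that do not need the encoding
step.

What passing the synthetic study shows: every stage's contracts hold, the
ranking recovers planted signal through the full encode→balance→rank chain,
and the pipeline is deterministic and leak-free by construction. What it
does not show: performance on real proteins. Real PSSMs have positional
autocorrelation, alignment-depth effects, compositional biases correlated
with length and taxon, and class boundaries far less clean than a planted
δ = 8 shift; published benchmark figures on real AFP data cannot be
inferred from, or compared against, the synthetic metrics here.

## Numerical choices and limitations

- Mutual information uses the plug-in estimator with no bias correction;
  rankings, not absolute MI values, are the consumed quantity.
- mRMR tie tolerance 1e-9 (above); SVM grid ties resolve to the smaller
  (C, γ); stratified splits give the floor share to training and the
  remainder to test.
- All stage seeds derive from the single pipeline seed by fixed affine
  offsets modulo 2³¹, so a manifest reproduces a run bit-for-bit
  (artifact checksums are recorded in the manifest).
- FASTA/PSSM pairing is by file basename; a residue mismatch between the
  two sources is an error, while a missing PSSM (an upstream profile-search
  failure) skips the sequence with a logged warning.
- The package does not run PSI-BLAST, does not handle XML or binary
  checkpoint PSSM formats, and implements no oversamplers other than
  MWMOTE and no feature-selection families other than ensemble mRMR.
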