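# Methods

`acrstack` predicts whether a protein sequence is an anti-CRISPR protein
(Acr): a phage-encoded inhibitor of a CRISPR-Cas immune system. Known Acrs
are short (roughly 50-350 residues) and share little sequence similarity
with one another, which defeats homology search and motivates a
feature-based classifier. The package implements the full chain: feature
encoding, feature selection, ensemble classification, score averaging, and
cross-validated evaluation, plus a synthetic corpus generator so the whole
chain is testable without external data or pretrained weights.

## Feature encodings

Every protein is a sequence `S = s_1 … s_L` over the 20 canonical residues.
Non-canonical symbols (B, J, O, U, X, Z, `*`) are stripped with a warning
before encoding: the composition formulas below are defined only on the
canonical alphabet.

**AAC (20 dims).** Amino-acid composition, `p_i = c_i / L` with `c_i` the
count of residue `i`. Sums to 1 by construction.

**PAAC (20 + λ dims, default 23).** Pseudo-amino-acid composition adds λ
sequence-order coupling factors to the composition. With three per-residue
property scales — hydrophobicity (Tanford-style consensus), hydrophilicity
(Hopp-Woods), and side-chain mass — each standardized to zero mean and unit
(population) variance over the 20 residues, the pair correlation is

    Θ(a, b) = (1/3) Σ_q (H_q(b) − H_q(a))²

and the rank-j coupling factor is

    θ_j = (1/(L−j)) Σ_{i=1..L−j} Θ(s_i, s_{i+j}),   j = 1..λ.

The output is `[f_1..f_20, ω θ_1..ω θ_λ] / (Σf + ω Σθ)`, so the whole
vector sums to 1. Defaults λ = 3 (giving the conventional 23-dim vector for
this problem) and ω = 0.05 (the common weighting of standard PAAC
extractors). λ must be smaller than the shortest sequence.

**PSSM-AC (20·G dims, default 200).** From an L×20 position-specific
scoring matrix `P` (PSI-BLAST `-out_ascii_pssm` log-odds, column order
A R N D C Q E G H I L K M F P S T V W Y), the per-column autocovariance at
lag g is

    AC(j, g) = (1/(L−g)) Σ_{i=1..L−g} (P_{i,j} − P̄_j)(P_{i+g,j} − P̄_j)

with `P̄_j` the column mean over all L rows and g = 1..G (G = 10). Output
order is residue-major, lag-minor. Because columns are mean-centered the
encoding is invariant to adding a constant to a column; raw integer
log-odds are used by default, with an optional elementwise sigmoid
(`sigmoid=True`) for users matching toolchains that rescale first.

**RPSSM (110 dims).** The 20 PSSM columns are merged into 10
physicochemical groups — {FYW}, {ML}, {IV}, {ATS}, {NH}, {QED}, {RK}, {C},
{G}, {P} — by column averaging (the reduced PSSM `r`). Two statistics are
taken: per-column population variances `E_j = (1/L) Σ (r_{i,j} − r̄_j)²`
and adjacent-row cross terms
`E_{j,t} = (1/(L−1)) Σ_{i=1..L−1} (r_{i,j} − r_{i+1,t})² / 2` for all
j,t = 1..10. Output order `[E_{1,1} … E_{10,10}, E_1 … E_10]`. All entries
are sums of squares, hence ≥ 0; L ≥ 2 is required.

**SSA (D dims, default 121).** Given a per-residue embedding matrix
(one row `x_i` per position), the pooled feature is the column mean. The
soft-sequence-alignment similarity between two embeddings `P1 (L1×D)` and
`P2 (L2×D)` uses L1 distances `d_ij = ‖x_i − y_j‖₁`:

    δ = row-softmax(−d),  ε = column-softmax(−d),  α = δ + ε − δε,
    score = −(1/A) Σ α_ij d_ij,  A = Σ α_ij.

The score is ≤ 0, equals 0 only for perfectly matching single pairs, and is
symmetric in its two inputs (transposition swaps δ and ε). Softmaxes are
computed with max-subtraction for numerical stability.

The package does not ship pretrained language-model weights; embeddings are
supplied as files, or produced by `SequenceProjectionEmbedder`, a
deterministic per-residue embedder (seeded random projection of one-hot
residues followed by a moving-average positional smoothing, window 5). It
is a structural stand-in that exercises the SSA code path, not a learned
model; its outputs carry composition information but no learned semantics.

## Feature selection

Greedy minimum-redundancy maximum-relevance ranking under the MID
(difference) criterion. Continuous features are discretized into 10
equal-width bins (constant columns collapse to one bin and get zero
relevance); mutual information is estimated from the discrete contingency
tables; the binary label is used as-is. Step 1 picks the feature with
maximal I(f; y); step k+1 maximizes `I(f; y) − mean_{s∈selected} I(f; s)`.
Ties break toward the lower column index, making the ranking deterministic
and giving the greedy prefix property (the k'-prefix of a k-ranking equals
the k'-ranking). The default policy (`select_features`) applies mRMR only
when a matrix exceeds 200 columns, mirroring the study design in which
encoders at ≤ 200 dims pass through unreduced — so all five encoders here
pass through by default, and the selector exists for larger encodings.

## Classifiers and ensembles

The eight base learners are an RBF SVM, k-nearest neighbours, a multilayer
perceptron (two hidden layers, 64 and 32 units, at most 1000 iterations),
logistic regression, random forest, XGBoost (defaults except learning rate
0.1), LightGBM (defaults), and a histogram gradient-boosted tree ensemble
(scikit-learn's `HistGradientBoostingClassifier`, defaults). The SVM gets
probabilistic outputs through Platt-style sigmoid calibration
(`CalibratedClassifierCV`, 5-fold), which score averaging and AUC require.

Hyperparameter search (`tune=True`) follows the conventional spaces: C and
γ over {2⁻⁶ … 2⁶} for the SVM, k over {1 … max(√FeaNum, FeaNum/2)} for KNN,
and tree count over the same bound with mtry ∈ {1, 6, 11, 16} for the
random forest, scored by 5-fold CV accuracy with ties resolved toward the
smallest parameter values. Integer grids are stepped to at most 30 points
(`full_grid=True` restores the exhaustive grid). Ensemble trainers default
to `tune=False` with fixed mid-grid settings (C = 1, γ = "scale", k = 5,
100 trees, √FeaNum features): nesting a full grid search inside the
out-of-fold stacking construction inside outer cross-validation multiplies
fit counts by several hundred for marginal gain on the feature sizes used
here, and the search remains available as a switch.

Combiners:

* **Hard voting** — majority of the 8 members' hard votes; the reported
  score is the mean member probability, which also resolves 4-4 ties
  (mean ≥ 0.5 → positive).
* **Stacking** — meta-features are the members' out-of-fold positive-class
  probabilities from a stratified, seeded 5-fold split, so the meta-learner
  (logistic regression for "sta_lr", gradient boosting for "sta_gbc") never
  sees a member probability produced by a model trained on that sample;
  members are refitted on the full data for deployment. Requires ≥ 10
  samples per class.
* **Feature averaging** — one stacking-LR sub-model per feature block; the
  composite score is the arithmetic mean of the block scores. The final
  composite predictor uses the PSSM-AC, RPSSM and SSA blocks; labels use a
  0.5 threshold.

All randomness (fold shuffling, member seeds) derives from a single seed
argument; refitting with the same seed reproduces scores bit-identically.

## Evaluation

Sensitivity, specificity, precision, accuracy, F-score and Matthews
correlation are computed directly from confusion counts; any degenerate
denominator yields 0 and the metric name is recorded in the result's
`degenerate` set (so an all-negative predictor reports MCC 0, flagged,
rather than NaN). AUC uses midrank tie handling (equal to the Mann-Whitney
pair statistic) and AUPRC the precision-recall step integration.
Cross-validation is stratified with shuffled, seeded folds and reports
per-fold metrics with mean and population standard deviation (ddof = 0) —
a presentation choice, stated here because either convention is defensible.
If k exceeds the minority class count, stratification is impossible and the
harness errors, except for the k = n leave-one-out boundary where
stratification is vacuous and single-sample folds simply flag their
rank-based metrics as degenerate.

## Synthetic corpus generator

`simulate_dataset` emulates the *shape* of a curated Acr corpus — two
classes with a 412/412 default split, lengths uniform on [50, 350], one
PSSM and one L×121 embedding per protein — and injects a class signal of
strength `effect` visible to all three composite feature branches:

* positive-class sequences up-weight residues F, Y, W, M, L
  (softmax weights with log-boost 0.15·effect);
* PSSM noise is drawn uniformly from the integers [−5, 9] (a typical
  log-odds range, keeping ASCII files format-valid); positives add, on the
  five signal-residue columns, a constant shift `round(effect)` (moves the
  reduced-PSSM adjacent-row cross terms) plus an integer-rounded sinusoid
  of amplitude 1.5·effect and period 20 positions (adds variance and lag
  autocovariance, which the shift-invariant autocovariance encoder sees);
* embeddings are the deterministic sequence projection plus N(0, 0.1²)
  noise, with +0.05·effect on the first ten dimensions for positives.

At `effect = 0` the class distributions are identical (exchangeable), and
everything is reproducible byte-for-byte from the seed. What the generator
deliberately does **not** emulate: homology structure within and between
classes, redundancy filtering, real PSSM column correlations, database
composition of the negative set, or learned embedding semantics. Passing
tests on this corpus therefore demonstrate that the pipeline recovers an
injected separable signal and is leakage-free and deterministic — not that
any particular accuracy carries over to real Acr corpora.

The default evaluation scale for parameter-recovery runs is 200 proteins
per class with `effect = 2.0`: large enough for stable stratified 5-fold
stacking, small enough for routine re-runs on one CPU.

## Numerical choices and edge cases

* PSSM parsing retains only the 20 log-odds columns; rows are 0-based
  internally, 1-based in files, and malformed rows report their line
  number. Exactly 42 numeric fields must follow the residue letter.
* Feature tables round-trip through TSV at 12 significant digits
  (differences < 1e-9); embeddings at 17 (exact for float64).
* mRMR tie-break: lowest column index; argmax over the criterion vector.
* Composite blocks with duplicated column names (e.g. the same matrix used
  twice) are qualified with block names on concatenation.
* Model bundles embed a format-version string; loading a mismatched
  version fails loudly rather than guessing.

## Known limitations

* The SSA path is only as informative as the supplied embeddings; the
  built-in projection embedder is deterministic scaffolding, not a
  pretrained model.
* mRMR's equal-width 10-bin MI estimator is the classical choice but is
  sensitive to outliers in a column's range; no quotient (MIQ) criterion is
  provided.
* The KNN/RF search-space bound max(√FeaNum, FeaNum/2) grows linearly in
  feature count and is stepped to ≤ 30 grid points by default.
* Hard-voting tie resolution and the 0.5 label threshold are conventions;
  both are documented rather than derived.
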