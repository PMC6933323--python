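# Methods

## Model

`lnrlink` treats link prediction on a lncRNA–miRNA network as matrix
self-representation. The known binary network `LMN` (ln×mn) and two
entity-similarity matrices `LSM` (ln×ln), `MSM` (mn×mn) are assembled into
the symmetric bipartite matrix

    M = [ LSM   LMN ; LMNᵀ  MSM ]  ∈ R^{N×N},  N = ln + mn.

Each column (equivalently row) of `M` is approximated as a linear combination
of all columns with weight matrix `C`, penalized in Frobenius norm:

    Q(C) = α‖M − MC‖²_F + ‖C‖²_F.

Setting ∂Q/∂C = 0 gives the unique minimizer

    C* = α(αMᵀM + I)⁻¹ MᵀM,     S = MC*.

Because `αMᵀM + I` is symmetric positive definite for every α > 0, `C*` is
computed by Cholesky factorization and triangular solves; the residual of the
linear system is verified against a tolerance (default 1e-8, relative to the
right-hand side's Frobenius norm) and an explicit inverse is never formed.
With `MᵀM = VΛVᵀ`, `C* = V diag(αλᵢ/(1+αλᵢ)) Vᵀ`: every eigenvalue of `C*`
lies in [0, 1), so the map `M → S` is a spectral shrinkage. For symmetric `M`
both `C*` and `S` are symmetric; the prediction matrix is the average of the
lncRNA×miRNA cross block of `S` and the transpose of the miRNA×lncRNA block,
which agree analytically and differ only by floating-point round-off.

Assumptions worth stating explicitly:

* the diagonal of `C` is left unconstrained — a node may participate in its
  own reconstruction; the ridge penalty keeps this bounded;
* predictions are **not** invariant to rescaling `M` (replacing `M` by `cM`
  rescales `MᵀM` by `c²` and therefore changes the shrinkage); this is the
  practical reason similarity inputs are normalized into a fixed range
  before model assembly;
* score *rankings* are invariant to positive rescaling of the scores
  themselves. In particular, as α → 0, `C* ≈ αMᵀM` and `S ≈ αM(MᵀM)`: the
  scores all shrink toward zero, but their ranking converges to that of
  `M(MᵀM)`, a two-step neighbourhood count that is itself an informative
  predictor. A vanishing α therefore does **not** degrade ROC-AUC toward
  0.5 — only the score magnitudes collapse. Conversely for full-rank `M` and
  α → ∞, `S → M`.

## Similarities

* **Expression**: Pearson correlation between per-condition profiles. Raw
  correlations (possibly negative) are kept by default; a clamp-to-zero mode
  exists. Zero-variance profiles have undefined correlation: their
  off-diagonal entries are set to 0 with a warning, the diagonal to 1.
* **Function**: `|Ra ∩ Rb| / √(|Ra|·|Rb|)` (Ochiai/cosine), chosen so that
  self-similarity is exactly 1 and values lie in [0, 1]; a plain-product
  denominator is available behind a flag. Empty-set entities score 0 against
  everything, diagonal 1.
* **Sequence**: Needleman–Wunsch global alignment with affine gaps via
  Biopython's `PairwiseAligner` (match 2, mismatch 0, gap open −0.5, gap
  extend −0.1 by default; a gap of length L costs open + (L−1)·extend; RNA is
  canonicalized to the DNA alphabet before alignment). Raw scores are then
  normalized: each column is divided by its maximum (columns with
  non-positive maxima are left at zero with a warning) and the strict upper
  triangle is overwritten by the transpose of the strict lower triangle.
  Since a self-alignment never scores below any cross-alignment in the same
  column under these parameters, the diagonal becomes 1 and off-diagonal
  entries lie in [0, 1].
* **Assembly**: entities of the interaction network that lack side data get
  identity-like rows (self-similarity 1, 0 elsewhere), so partial coverage
  degrades gracefully instead of failing. Side-data entities outside the
  network universe participate in the computation (they can set column
  maxima in the sequence normalization) and are dropped afterwards.

## Cross-validation protocol

Positive pairs are partitioned uniformly at random into k near-equal folds
(sizes differ by ≤1). For each fold, its positives are zeroed in the training
network, the model is refit, and the held-out positives (label 1) are ranked
against **all** pairs that are 0 in the full known network (label 0);
training positives are never scored. An option subsamples the negative class
per repetition for speed. AUC is the rank-statistic (Mann–Whitney) area with
midrank tie handling, computed per fold and pooled per repetition (the
pooled set concatenates each fold's held-out positives with that fold's
negative scores, so each negative pair contributes once per fold). The
headline statistic is the mean ± sample standard deviation (ddof = 1) of the
pooled per-repetition AUCs; the per-fold matrix is retained. One master seed
spawns per-repetition child seeds (recorded in the result), so a (config,
seed) pair reproduces the whole experiment bit-for-bit. The α sweep reuses
one seed across the grid so fold assignments are identical and only the
hyper-parameter varies.

The single-layer ablation replaces both similarity blocks with identity
matrices, preserving the problem size and unit self-similarity while removing
all side information; comparing it with the full bipartite model quantifies
the value of the side data.

## Synthetic data generator

The generator plants a latent group structure shared by the network and all
side data: groups are assigned uniformly; edges are Bernoulli(p_in) within
groups and Bernoulli(p_out) between; expression profiles are group centroids
(standard normal per condition) plus N(0, noise_sd²) noise; annotation sets
mix terms from a disjoint per-group pool (fraction 0.8) with a shared global
pool; sequences are uniform nucleotide backgrounds with a fixed per-group
motif implanted at a random position.

Defaults: 80 lncRNAs × 40 miRNAs, 4 groups, p_in = 0.3, p_out = 0.02
(expected density 9%), 20 expression conditions with noise_sd = 0.5, 8 terms
per entity from pools of 30 (group) + 40 (global), sequences of length 120
with 15-nt motifs. Sequence lengths are kept modest so the O(n²) alignment
stage stays in seconds; the motif-to-background ratio is deliberately weak,
and because random sequences of equal length already align with high scores,
sequence similarity is the weakest side channel in this benchmark — a
realistic property, not a defect. The generator emulates *structure*, not
biology: real expression is non-Gaussian and tissue-dependent, real
annotation vocabularies are hierarchical, and real RNA sequences have
composition biases and length distributions this model ignores. Passing
tests on planted data show the pipeline recovers the signal it assumes;
they do not certify performance on any real resource.

A null configuration (p_in = p_out, side data uncorrelated with edges) gives
mean CV AUC ≈ 0.5, with a small negative bias (≈0.45–0.50 at small n): a
held-out edge's removal lowers its own row/column degree in the training
network, slightly depressing its score relative to untouched negatives. The
effect shrinks as density and size grow.

## Numerical choices and degenerate inputs

* Linear solve: Cholesky (`scipy.linalg.cho_factor/cho_solve`); residual
  checked, hard failure if it exceeds tolerance.
* Prediction block: mean of the two cross blocks of `S` (identical up to
  round-off for symmetric `M`).
* Ties in prediction tables are broken lexicographically by (lncRNA id,
  miRNA id) for reproducible output files.
* Floating-point I/O uses `%.17g` on write and round-trip parsing on read,
  so every file format is a lossless inverse pair.
* Interaction edge lists cannot represent isolated entities; dataset bundles
  therefore also store the labelled 0/1 matrix layout, which round-trips
  exactly. Duplicate edges are collapsed on read with a logged count.
* Fold split requires k ≤ number of positives; AUC requires both classes
  present; α must be strictly positive — all hard errors.

## Problem sizes

Default test and reproduction runs use the 80×40 planted dataset (N = 120
nodes, ~290 positives), 5 cross-validation repetitions, and 3 repetitions per
grid point in the α sweep. At this size a full repeated-CV battery completes
in seconds on one core while leaving the statistical conclusions (signal
recovery, fold-count trend, ablation ordering) stable across seeds.

## Known limitations

* The closed form densifies `MᵀM`; networks beyond ~10⁴ nodes would need an
  iterative or low-rank solver, which is out of scope.
* The model tolerates negative Pearson similarities, but their effect is a
  signed contribution in the reconstruction, not a principled repulsion.
* AUC against all unknown pairs treats unobserved interactions as negatives;
  truly positive but undiscovered pairs deflate the measured AUC.
* The α sweep's granularity (0.002) bounds how precisely the optimum is
  located; on planted data the AUC surface is nearly flat across the grid,
  so the arg-max is seed-sensitive.
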