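# lnrlink

Link prediction for lncRNA–miRNA interaction networks by **linear neighbour
representation**: a closed-form, ridge-penalized self-representation model on
a similarity-augmented bipartite matrix.

## The problem

Long non-coding RNAs (lncRNAs) and microRNAs (miRNAs) regulate each other in
competing-endogenous-RNA (ceRNA) networks, but experimentally confirmed
lncRNA–miRNA interactions (e.g. from CLIP-seq) cover only a small fraction of
the candidate pairs. `lnrlink` ranks the unobserved pairs of a known binary
interaction network `LMN ∈ {0,1}^{ln×mn}`, optionally informed by per-entity
side information — expression profiles, functional-annotation term sets, or
nucleotide sequences — under the working assumption that functionally similar
lncRNAs tend to interact with functionally similar miRNAs.

## The model

Side information enters through two square similarity matrices: `LSM` for
lncRNAs and `MSM` for miRNAs, built from

* Pearson correlation of expression profiles (values in [−1, 1]),
* annotation-set overlap `|Ra ∩ Rb| / √(|Ra|·|Rb|)` (Ochiai coefficient),
* Needleman–Wunsch global-alignment scores with affine gap penalties
  (match 2, mismatch 0, gap open −0.5, gap extend −0.1 by default), followed
  by a column-maximum normalization and lower-triangle symmetrization.

These combine with the network into one symmetric bipartite matrix

```
M = [ LSM   LMN ]
    [ LMNᵀ  MSM ]
```

Each node's row of `M` is then modelled as a linear combination of all rows,
with weights `C` minimizing the ridge objective

```
Q(C) = α‖M − MC‖²_F + ‖C‖²_F ,        α > 0
```

whose unique optimum is the closed form

```
C* = α(αMᵀM + I)⁻¹ MᵀM ,       S = MC* .
```

The lncRNA×miRNA cross block of the score matrix `S` holds the prediction
scores. The single hyper-parameter `α` (default 0.018) controls shrinkage:
eigenvalues of `C*` are `αλ/(1+αλ)` for eigenvalues `λ` of `MᵀM`, so they
always lie in [0, 1). The linear system is symmetric positive definite and is
solved by Cholesky factorization, never by explicit inversion.

The package also provides repeated k-fold cross-validation with ROC-AUC
scoring (held-out positives ranked against all pairs that are 0 in the full
network), a "single-layer" ablation that replaces both similarity blocks with
identity matrices, an α-sensitivity sweep, and a planted-partition synthetic
data generator that produces networks and correlated side data with known
group structure.

## Worked example

```python
import lnrlink as L

ds = L.generate_dataset(L.PlantedModelConfig(seed=7))   # 80 lncRNAs x 40 miRNAs
lsm = L.pcc_similarity(ds.lnc_profiles)                 # expression similarity
msm = L.pcc_similarity(ds.mirna_profiles)

res = L.LinearNeighborModel(ds.lmn, lsm, msm).fit(alpha=0.018)
print(res.summary(top=3))

cv = L.cross_validate(lsm, msm, ds.lmn, L.CVConfig(k=5, repetitions=5, seed=11))
print(cv.summary())
```

prints

```
Linear neighbour representation link prediction
================================================
lncRNAs: 80   miRNAs: 40
known interactions: 288 (density 0.0900)
alpha: 0.018
weight-matrix spectrum: [-0.0000, 0.9543]

top 3 novel candidate interactions:
lncRNA_id miRNA_id    score  known_flag  rank
  LNC0007  MIR0030 0.474783           0    73
  LNC0065  MIR0039 0.442256           0   103
  LNC0047  MIR0023 0.434620           0   117

5-fold CV, 5 repetitions (bipartite, alpha=0.018): AUC 0.7984 +/- 0.0017 (best 0.8009)
```

The summary lists the highest-scoring pairs *not* in the training network —
the model's novel candidates — and the weight-matrix spectrum confirms the
shrinkage bound. The cross-validation line reports the pooled per-repetition
AUC (mean ± sample standard deviation over repetitions, plus the best
repetition): held-out interactions are ranked far above chance.

The same steps are available from the shell:

```bash
lnrlink simulate --out data/ --seed 7
lnrlink similarity --kind expression --input data/lnc_expression.tsv \
        --interactions data/interactions.tsv --side lnc --out data/lsm.tsv
lnrlink cv --interactions data/interactions.tsv --lnc-similarity data/lsm.tsv \
        --k 5 --reps 5 --seed 11 --out cv_report.tsv
```

Every CLI run writes a JSON manifest (config, input SHA-256 digests, seed,
version) alongside its output.

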