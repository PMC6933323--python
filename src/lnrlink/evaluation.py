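"""Cross-validated evaluation of the link predictor.

Known interactions are split into k near-equal folds; each fold in turn is
masked from the training network, the model is refit, and the masked
positives are ranked against candidate pairs that are 0 in the *full* known
network.  Ranking quality is measured by ROC-AUC.  The whole procedure is
repeated with fresh random fold assignments to average out split noise.

Two AUC aggregations are computed: a per-fold AUC, and a pooled AUC per
repetition that concatenates every fold's test scores (each fold's held-out
positives together with that fold's scores for the negative pairs).  The
pooled per-repetition AUC is the headline statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .model import (
    DEFAULT_ALPHA,
    InteractionMatrix,
    LinearNeighborModel,
    ModelConfig,
)
from .similarity import SimilarityMatrix

__all__ = [
    "FoldAssignment",
    "CVConfig",
    "CVResult",
    "AlphaSweepResult",
    "split_folds",
    "mask_fold",
    "roc_auc",
    "cross_validate",
    "alpha_sweep",
    "default_alpha_grid",
]


@dataclass
class FoldAssignment:
    """Random partition of the positive pairs into k near-equal folds."""

    positive_pairs: np.ndarray  # (n, 2) of (lnc index, mirna index)
    fold_of_pair: np.ndarray  # (n,) ints in [0, k)
    k: int
    seed: int

    def pairs_in_fold(self, fold: int) -> np.ndarray:
        return self.positive_pairs[self.fold_of_pair == fold]


@dataclass(frozen=True)
class CVConfig:
    """k-fold CV settings; ``mode`` selects the full bipartite model or the
    single-layer (no side information) ablation."""

    k: int = 5
    repetitions: int = 20
    seed: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)
    mode: str = "bipartite"
    max_negatives: int | None = None  # subsample the negative class for speed
    collect_roc: bool = False

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.mode not in ("bipartite", "single_layer"):
            raise ValueError("mode must be 'bipartite' or 'single_layer'")


@dataclass
class CVResult:
    """Per-fold and pooled AUCs of a repeated k-fold cross-validation."""

    fold_aucs: np.ndarray  # (repetitions, k)
    pooled_aucs: np.ndarray  # (repetitions,)
    mean_auc: float
    std_auc: float
    best_auc: float
    rep_seeds: np.ndarray
    config: CVConfig
    roc_curves: list[tuple[np.ndarray, np.ndarray]] | None = None

    def to_frame(self) -> pd.DataFrame:
        reps, k = self.fold_aucs.shape
        return pd.DataFrame(
            {
                "repetition": np.repeat(np.arange(reps), k),
                "fold": np.tile(np.arange(k), reps),
                "auc": self.fold_aucs.ravel(),
            }
        )

    def summary(self) -> str:
        return (
            f"{self.config.k}-fold CV, {self.config.repetitions} repetitions "
            f"({self.config.mode}, alpha={self.config.model.alpha:g}): "
            f"AUC {self.mean_auc:.4f} +/- {self.std_auc:.4f} "
            f"(best {self.best_auc:.4f})"
        )


@dataclass
class AlphaSweepResult:
    """One CVResult per alpha, with shared fold seeds across alphas."""

    alphas: list[float]
    results: list[CVResult]

    @property
    def best_alpha(self) -> float:
        return self.alphas[int(np.argmax([r.mean_auc for r in self.results]))]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alpha": self.alphas,
                "mean_auc": [r.mean_auc for r in self.results],
                "std_auc": [r.std_auc for r in self.results],
                "best_auc": [r.best_auc for r in self.results],
            }
        )


def split_folds(lmn: InteractionMatrix, k: int, seed: int) -> FoldAssignment:
    """Uniform random partition of the positive pairs into k folds whose
    sizes differ by at most one; deterministic given ``seed``."""
    pairs = lmn.positive_pairs()
    n = len(pairs)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} positive pairs")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % k
    return FoldAssignment(pairs, folds, k, seed)


def mask_fold(lmn: InteractionMatrix, fa: FoldAssignment, fold: int) -> InteractionMatrix:
    """Copy of the network with the held-out fold's positives zeroed."""
    if not 0 <= fold < fa.k:
        raise ValueError(f"fold {fold} out of range [0, {fa.k})")
    masked = lmn.copy()
    held = fa.pairs_in_fold(fold)
    masked.values[held[:, 0], held[:, 1]] = 0
    return masked


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-statistic (Mann-Whitney) ROC-AUC with midrank tie handling."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute AUC")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _rep_seeds(seed: int, repetitions: int) -> np.ndarray:
    # one master seed spawns per-repetition child seeds (< 2^31), recorded
    # in the result for provenance
    return (np.random.SeedSequence(seed).generate_state(repetitions) % (2**31)).astype(
        np.int64
    )


def cross_validate(
    lsm: SimilarityMatrix | None,
    msm: SimilarityMatrix | None,
    lmn: InteractionMatrix,
    config: CVConfig,
) -> CVResult:
    """Repeated k-fold cross-validation of the link predictor.

    For each repetition and fold: mask the fold's positives, refit the model
    on the masked network (with the similarity matrices in ``bipartite`` mode,
    or identity blocks in ``single_layer`` mode), then compute the AUC of the
    masked positives (label 1) against all pairs that are 0 in the full known
    network (label 0).  Training positives are never scored.
    """
    if config.mode == "single_layer":
        lsm = msm = None
    neg_idx = np.argwhere(lmn.values == 0)
    if neg_idx.size == 0:
        raise ValueError("network has no negative (zero) pairs to rank against")
    rep_seeds = _rep_seeds(config.seed, config.repetitions)

    fold_aucs = np.empty((config.repetitions, config.k))
    pooled_aucs = np.empty(config.repetitions)
    curves: list[tuple[np.ndarray, np.ndarray]] | None = (
        [] if config.collect_roc else None
    )
    for rep, rep_seed in enumerate(rep_seeds):
        rng = np.random.default_rng(rep_seed)
        fa = split_folds(lmn, config.k, int(rep_seed))
        if config.max_negatives is not None and len(neg_idx) > config.max_negatives:
            sel = rng.choice(len(neg_idx), size=config.max_negatives, replace=False)
            rep_neg = neg_idx[np.sort(sel)]
        else:
            rep_neg = neg_idx
        pooled_scores: list[np.ndarray] = []
        pooled_labels: list[np.ndarray] = []
        for fold in range(config.k):
            masked = mask_fold(lmn, fa, fold)
            model = LinearNeighborModel(masked, lsm, msm)
            res = model.fit(
                alpha=config.model.alpha,
                solver_tolerance=config.model.solver_tolerance,
            )
            scores = res.predictions.scores
            pos = fa.pairs_in_fold(fold)
            pos_scores = scores[pos[:, 0], pos[:, 1]]
            neg_scores = scores[rep_neg[:, 0], rep_neg[:, 1]]
            s = np.concatenate([pos_scores, neg_scores])
            y = np.concatenate(
                [np.ones(len(pos_scores)), np.zeros(len(neg_scores))]
            )
            fold_aucs[rep, fold] = roc_auc(s, y)
            pooled_scores.append(s)
            pooled_labels.append(y)
        s_all = np.concatenate(pooled_scores)
        y_all = np.concatenate(pooled_labels)
        pooled_aucs[rep] = roc_auc(s_all, y_all)
        if curves is not None:
            fpr, tpr, _ = roc_curve(y_all, s_all)
            curves.append((fpr, tpr))

    return CVResult(
        fold_aucs=fold_aucs,
        pooled_aucs=pooled_aucs,
        mean_auc=float(pooled_aucs.mean()),
        std_auc=float(pooled_aucs.std(ddof=1)) if config.repetitions > 1 else 0.0,
        best_auc=float(pooled_aucs.max()),
        rep_seeds=rep_seeds,
        config=config,
        roc_curves=curves,
    )


def default_alpha_grid() -> np.ndarray:
    """The standard sensitivity grid: 0.006 to 0.040 in steps of 0.002."""
    return np.round(np.arange(0.006, 0.0401, 0.002), 6)


def alpha_sweep(
    lsm: SimilarityMatrix | None,
    msm: SimilarityMatrix | None,
    lmn: InteractionMatrix,
    alphas: Sequence[float],
    cv: CVConfig,
) -> AlphaSweepResult:
    """One cross-validation per alpha.  Fold seeds are shared across alphas
    (same ``cv.seed``) so the sweep isolates the hyper-parameter."""
    alphas = [float(a) for a in alphas]
    if not alphas:
        raise ValueError("alphas must be non-empty")
    if any(a <= 0 for a in alphas):
        raise ValueError("alphas must be positive")
    if any(b <= a for a, b in zip(alphas, alphas[1:])):
        raise ValueError("alphas must be strictly increasing")
    results = []
    for a in alphas:
        cfg = CVConfig(
            k=cv.k,
            repetitions=cv.repetitions,
            seed=cv.seed,
            model=ModelConfig(alpha=a, solver_tolerance=cv.model.solver_tolerance),
            mode=cv.mode,
            max_negatives=cv.max_negatives,
            collect_roc=cv.collect_roc,
        )
        results.append(cross_validate(lsm, msm, lmn, cfg))
    return AlphaSweepResult(alphas, results)
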