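"""Linear neighbour representation model for bipartite link prediction.

The method scores candidate lncRNA-miRNA interactions from a symmetric
bipartite matrix

    M = [[LSM, LMN],
         [LMN', MSM]]

where LSM and MSM are lncRNA and miRNA similarity matrices and LMN is the
known binary interaction network.  Each node's row of M is modelled as a
linear combination of all rows (a self-expressive / linear neighbour
representation), with ridge-penalized weights C chosen to minimize

    Q(C) = alpha * ||M - M C||_F^2 + ||C||_F^2 .

Setting the gradient to zero gives the closed-form optimum

    C* = alpha * (alpha M'M + I)^{-1} M'M ,

and the score matrix is S = M C*.  The lncRNA x miRNA cross block of S holds
the prediction scores.  The only hyper-parameter is alpha > 0, which trades
reconstruction fidelity against shrinkage; alpha -> 0 collapses all scores to
zero while large alpha makes S approach M for full-rank M.

The module follows the statsmodels convention: build a
:class:`LinearNeighborModel` from data, call :meth:`~LinearNeighborModel.fit`
to obtain a :class:`LinearNeighborResults` carrying the weight matrix, score
matrix, predictions and a ``summary()``.  Thin functional wrappers
(:func:`predict`, :func:`predict_single_layer`, ...) expose the same steps
individually.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .similarity import SimilarityMatrix, _check_unique

__all__ = [
    "InteractionMatrix",
    "BlockLayout",
    "BipartiteMatrix",
    "ModelConfig",
    "WeightMatrix",
    "ScoreMatrix",
    "PredictionMatrix",
    "LinearNeighborModel",
    "LinearNeighborResults",
    "build_bipartite",
    "solve_weights",
    "score_matrix",
    "extract_predictions",
    "predict",
    "predict_single_layer",
]

DEFAULT_ALPHA = 0.018  # empirically best-performing balance parameter


@dataclass
class InteractionMatrix:
    """Known binary lncRNA x miRNA interaction network."""

    lnc_ids: list[str]
    mirna_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.lnc_ids), len(self.mirna_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.lnc_ids)} lncRNAs x {len(self.mirna_ids)} miRNAs"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("interaction matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8)
        _check_unique(self.lnc_ids, "lncRNA")
        _check_unique(self.mirna_ids, "miRNA")

    @property
    def n_positives(self) -> int:
        return int(self.values.sum())

    @property
    def density(self) -> float:
        return self.n_positives / self.values.size

    def positive_pairs(self) -> np.ndarray:
        """(n_positives, 2) array of (lnc index, mirna index)."""
        return np.argwhere(self.values == 1)

    def copy(self) -> "InteractionMatrix":
        return InteractionMatrix(
            list(self.lnc_ids), list(self.mirna_ids), self.values.copy()
        )


@dataclass(frozen=True)
class BlockLayout:
    """Index bookkeeping for the four blocks of the bipartite matrix."""

    n_lnc: int
    n_mirna: int

    @property
    def n_nodes(self) -> int:
        return self.n_lnc + self.n_mirna

    @property
    def lnc(self) -> slice:
        return slice(0, self.n_lnc)

    @property
    def mirna(self) -> slice:
        return slice(self.n_lnc, self.n_lnc + self.n_mirna)


@dataclass
class BipartiteMatrix:
    """Symmetric (ln+mn) x (ln+mn) matrix combining LSM, MSM and LMN."""

    node_ids: list[str]
    values: np.ndarray
    block_layout: BlockLayout

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.block_layout.n_nodes
        if self.values.shape != (n, n) or len(self.node_ids) != n:
            raise ValueError("bipartite matrix shape inconsistent with layout")
        if np.abs(self.values - self.values.T).max() > 1e-12:
            raise ValueError("bipartite matrix must be symmetric")


@dataclass(frozen=True)
class ModelConfig:
    """alpha balances reconstruction vs shrinkage; must be > 0."""

    alpha: float = DEFAULT_ALPHA
    solver_tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if not self.solver_tolerance > 0:
            raise ValueError("solver_tolerance must be > 0")


@dataclass
class WeightMatrix:
    """The self-representation weight matrix C*; entry (k, j) is the
    contribution of node k to the reconstruction of node j."""

    values: np.ndarray


@dataclass
class ScoreMatrix:
    """S = M C*; symmetric (to solver tolerance) when M is symmetric."""

    node_ids: list[str]
    values: np.ndarray


@dataclass
class PredictionMatrix:
    """lncRNA x miRNA block of the score matrix: the prediction scores."""

    lnc_ids: list[str]
    mirna_ids: list[str]
    scores: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.lnc_ids, columns=self.mirna_ids)


def build_bipartite(
    lsm: SimilarityMatrix, msm: SimilarityMatrix, lmn: InteractionMatrix
) -> BipartiteMatrix:
    """Assemble M with LSM top-left, LMN (ln x mn) top-right, LMN' bottom-left
    and MSM bottom-right.  Ids of the similarity matrices must equal the
    interaction matrix's ids in order."""
    if list(lsm.entity_ids) != list(lmn.lnc_ids):
        raise ValueError("lncRNA similarity ids do not match interaction lnc_ids in order")
    if list(msm.entity_ids) != list(lmn.mirna_ids):
        raise ValueError("miRNA similarity ids do not match interaction mirna_ids in order")
    ln, mn = len(lmn.lnc_ids), len(lmn.mirna_ids)
    A = lmn.values.astype(float)
    M = np.block([[lsm.values, A], [A.T, msm.values]])
    return BipartiteMatrix(
        list(lmn.lnc_ids) + list(lmn.mirna_ids), M, BlockLayout(ln, mn)
    )


def solve_weights(m: BipartiteMatrix, config: ModelConfig) -> WeightMatrix:
    """Closed-form ridge solution C* = alpha (alpha M'M + I)^{-1} M'M.

    The system matrix alpha*M'M + I is symmetric positive definite for every
    alpha > 0, so a Cholesky solve always succeeds; the residual of the linear
    system is checked against ``config.solver_tolerance`` (relative to the
    right-hand side's Frobenius norm).
    """
    M = m.values
    if not np.isfinite(M).all():
        raise ValueError("bipartite matrix contains non-finite entries")
    gram = M.T @ M
    rhs = config.alpha * gram
    system = rhs + np.eye(M.shape[0])
    c_factor = cho_factor(system)
    C = cho_solve(c_factor, rhs)
    resid = np.linalg.norm(system @ C - rhs, "fro")
    scale = max(1.0, np.linalg.norm(rhs, "fro"))
    if resid > config.solver_tolerance * scale:
        raise ArithmeticError(
            f"linear solve residual {resid:g} exceeds tolerance "
            f"{config.solver_tolerance:g} x {scale:g}"
        )
    return WeightMatrix(C)


def score_matrix(m: BipartiteMatrix, c: WeightMatrix) -> ScoreMatrix:
    """S = M C*, i.e. s_ij = sum_k m_ik c_kj: each node's score vector is the
    linear summation of its neighbours' contributions."""
    if m.values.shape[1] != c.values.shape[0]:
        raise ValueError("non-conformable bipartite and weight matrices")
    return ScoreMatrix(list(m.node_ids), m.values @ c.values)


def extract_predictions(s: ScoreMatrix, layout: BlockLayout) -> PredictionMatrix:
    """Extract the lncRNA x miRNA prediction block of S.

    The top-right block and the transpose of the bottom-left block agree
    analytically (S is symmetric when M is); their average absorbs
    floating-point asymmetry.
    """
    if s.values.shape != (layout.n_nodes, layout.n_nodes):
        raise ValueError("score matrix shape inconsistent with layout")
    top_right = s.values[layout.lnc, layout.mirna]
    bottom_left = s.values[layout.mirna, layout.lnc]
    scores = (top_right + bottom_left.T) / 2.0
    return PredictionMatrix(
        list(s.node_ids[layout.lnc]), list(s.node_ids[layout.mirna]), scores
    )


class LinearNeighborModel:
    """Linear neighbour representation link predictor.

    Parameters
    ----------
    interactions
        Known binary interaction network (the LMN block).
    lnc_similarity, mirna_similarity
        Similarity matrices for the two node classes, aligned (same ids, same
        order) with the interaction matrix.  ``None`` substitutes an identity
        matrix, removing that side's information; with both ``None`` the model
        is the "single-layer" ablation that sees only the network itself.
    """

    def __init__(
        self,
        interactions: InteractionMatrix,
        lnc_similarity: SimilarityMatrix | None = None,
        mirna_similarity: SimilarityMatrix | None = None,
    ) -> None:
        if lnc_similarity is None:
            lnc_similarity = SimilarityMatrix.identity(interactions.lnc_ids)
        if mirna_similarity is None:
            mirna_similarity = SimilarityMatrix.identity(interactions.mirna_ids)
        self.interactions = interactions
        self.lnc_similarity = lnc_similarity
        self.mirna_similarity = mirna_similarity
        self.bipartite = build_bipartite(lnc_similarity, mirna_similarity, interactions)

    @classmethod
    def from_frames(
        cls,
        interactions: pd.DataFrame,
        lnc_similarity: pd.DataFrame | None = None,
        mirna_similarity: pd.DataFrame | None = None,
    ) -> "LinearNeighborModel":
        """Build from pandas objects: a binary interaction DataFrame (lncRNA
        index, miRNA columns) and optional labelled square similarity frames
        (reindexed to the interaction ids)."""
        lmn = InteractionMatrix(
            [str(i) for i in interactions.index],
            [str(c) for c in interactions.columns],
            interactions.to_numpy(),
        )
        lsm = msm = None
        if lnc_similarity is not None:
            lsm = SimilarityMatrix(
                [str(i) for i in lnc_similarity.index], lnc_similarity.to_numpy()
            ).reindex(lmn.lnc_ids)
        if mirna_similarity is not None:
            msm = SimilarityMatrix(
                [str(i) for i in mirna_similarity.index], mirna_similarity.to_numpy()
            ).reindex(lmn.mirna_ids)
        return cls(lmn, lsm, msm)

    def fit(
        self, alpha: float = DEFAULT_ALPHA, solver_tolerance: float = 1e-8
    ) -> "LinearNeighborResults":
        config = ModelConfig(alpha=alpha, solver_tolerance=solver_tolerance)
        weights = solve_weights(self.bipartite, config)
        scores = score_matrix(self.bipartite, weights)
        preds = extract_predictions(scores, self.bipartite.block_layout)
        return LinearNeighborResults(self, config, weights, scores, preds)


class LinearNeighborResults:
    """Fit results: weight matrix C*, score matrix S and prediction block."""

    def __init__(
        self,
        model: LinearNeighborModel,
        config: ModelConfig,
        weights: WeightMatrix,
        scores: ScoreMatrix,
        predictions: PredictionMatrix,
    ) -> None:
        self.model = model
        self.config = config
        self.alpha = config.alpha
        self.weights = weights
        self.scores = scores
        self.predictions = predictions

    def prediction_table(self) -> pd.DataFrame:
        """Long-format ranking of all candidate pairs, best first.

        Columns: lncRNA_id, miRNA_id, score, known_flag (1 if the pair is in
        the training network), rank (1 = highest score).
        """
        lmn = self.model.interactions
        pm = self.predictions
        ln, mn = len(pm.lnc_ids), len(pm.mirna_ids)
        li, mi = np.meshgrid(np.arange(ln), np.arange(mn), indexing="ij")
        df = pd.DataFrame(
            {
                "lncRNA_id": np.asarray(pm.lnc_ids, dtype=object)[li.ravel()],
                "miRNA_id": np.asarray(pm.mirna_ids, dtype=object)[mi.ravel()],
                "score": pm.scores.ravel(),
                "known_flag": lmn.values.ravel().astype(int),
            }
        )
        df = df.sort_values(
            ["score", "lncRNA_id", "miRNA_id"], ascending=[False, True, True]
        ).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        return df

    def summary(self, top: int = 10) -> str:
        """Human-readable fit summary with the top novel predictions."""
        lmn = self.model.interactions
        eigs = np.linalg.eigvalsh((self.weights.values + self.weights.values.T) / 2)
        table = self.prediction_table()
        novel = table[table["known_flag"] == 0].head(top)
        lines = [
            "Linear neighbour representation link prediction",
            "=" * 48,
            f"lncRNAs: {len(lmn.lnc_ids)}   miRNAs: {len(lmn.mirna_ids)}",
            f"known interactions: {lmn.n_positives} (density {lmn.density:.4f})",
            f"alpha: {self.alpha:g}",
            f"weight-matrix spectrum: [{eigs.min():.4f}, {eigs.max():.4f}]",
            "",
            f"top {len(novel)} novel candidate interactions:",
            novel.to_string(index=False),
        ]
        return "\n".join(lines)


def predict(
    lsm: SimilarityMatrix,
    msm: SimilarityMatrix,
    lmn: InteractionMatrix,
    config: ModelConfig | None = None,
) -> PredictionMatrix:
    """End-to-end: assemble M, solve C*, score, extract the cross block."""
    config = config or ModelConfig()
    return (
        LinearNeighborModel(lmn, lsm, msm)
        .fit(alpha=config.alpha, solver_tolerance=config.solver_tolerance)
        .predictions
    )


def predict_single_layer(
    lmn: InteractionMatrix, config: ModelConfig | None = None
) -> PredictionMatrix:
    """Ablation without side information: identity matrices replace the
    similarity blocks, so only the network itself informs the scores."""
    config = config or ModelConfig()
    return (
        LinearNeighborModel(lmn)
        .fit(alpha=config.alpha, solver_tolerance=config.solver_tolerance)
        .predictions
    )
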