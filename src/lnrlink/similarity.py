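"""Entity-entity similarity matrices from expression, annotation and sequence data.

Three similarity notions are supported, matching the three kinds of side
information typically available for non-coding RNAs:

* expression similarity — Pearson correlation of per-condition expression
  profiles (values in [-1, 1]);
* functional similarity — normalized overlap of annotation-term sets,
  ``|Ra ∩ Rb| / sqrt(|Ra|·|Rb|)`` (the Ochiai coefficient, values in [0, 1]);
* sequence similarity — global (Needleman-Wunsch) alignment score with affine
  gap penalties, followed by a column-max normalization and lower-triangle
  symmetrization that maps scores into [0, 1].

All constructors return a :class:`SimilarityMatrix` whose rows/columns are
aligned to an explicit ordered id list, so matrices from different sources can
be conformed to a common entity universe with :func:`assemble_similarity`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import Align

__all__ = [
    "ExpressionProfileSet",
    "AnnotationSetCollection",
    "SequenceSet",
    "AlignmentScoring",
    "SimilarityMatrix",
    "pcc_similarity",
    "functional_similarity",
    "sequence_similarity_raw",
    "normalize_columns_and_symmetrize",
    "assemble_similarity",
]

_NUCLEOTIDES = frozenset("ACGTN")


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dupes = sorted({i for i in ids if i in seen or seen.add(i)})
        raise ValueError(f"duplicate {what} ids: {dupes[:5]}")


@dataclass
class ExpressionProfileSet:
    """Per-entity expression profiles over a shared set of conditions.

    One row per entity, one column per condition (tissue / cell line).
    At least two conditions are required because Pearson correlation is
    undefined on single-point profiles.
    """

    entity_ids: list[str]
    profiles: np.ndarray
    condition_ids: list[str]

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.ndim != 2:
            raise ValueError("profiles must be a 2-D matrix")
        n, p = self.profiles.shape
        if n != len(self.entity_ids):
            raise ValueError(
                f"{len(self.entity_ids)} entity ids but {n} profile rows"
            )
        if p != len(self.condition_ids):
            raise ValueError(
                f"{len(self.condition_ids)} condition ids but {p} profile columns"
            )
        if p < 2:
            raise ValueError("at least 2 conditions are required")
        _check_unique(self.entity_ids, "entity")
        if not np.isfinite(self.profiles).all():
            bad = np.argwhere(~np.isfinite(self.profiles))[0]
            raise ValueError(
                f"non-finite expression value at entity {self.entity_ids[bad[0]]!r}, "
                f"condition {self.condition_ids[bad[1]]!r}"
            )


@dataclass
class AnnotationSetCollection:
    """A finite set of annotation terms per entity; empty sets are allowed."""

    entity_ids: list[str]
    term_sets: list[frozenset[str]]

    def __post_init__(self) -> None:
        if len(self.entity_ids) != len(self.term_sets):
            raise ValueError("one term set per entity id is required")
        _check_unique(self.entity_ids, "entity")
        self.term_sets = [frozenset(s) for s in self.term_sets]


@dataclass
class SequenceSet:
    """Nucleotide sequences, canonicalized to uppercase DNA (U -> T).

    The alphabet after canonicalization must be a subset of {A, C, G, T, N}.
    """

    entity_ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.entity_ids) != len(self.sequences):
            raise ValueError("one sequence per entity id is required")
        _check_unique(self.entity_ids, "entity")
        canon = []
        for eid, seq in zip(self.entity_ids, self.sequences):
            s = seq.upper().replace("U", "T")
            if not s:
                raise ValueError(f"empty sequence for entity {eid!r}")
            bad = set(s) - _NUCLEOTIDES
            if bad:
                raise ValueError(
                    f"non-nucleotide characters {sorted(bad)} in sequence {eid!r}"
                )
            canon.append(s)
        self.sequences = canon


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap global alignment parameters.

    ``gap_open`` is charged at the first position of a gap, ``gap_extend`` at
    each additional gapped position, so a gap of length L scores
    ``gap_open + (L-1)·gap_extend``.
    """

    match_score: float = 2.0
    mismatch_score: float = 0.0
    gap_open: float = -0.5
    gap_extend: float = -0.1

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if not self.match_score > self.mismatch_score:
            raise ValueError("match_score must exceed mismatch_score")


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix aligned to an ordered id list."""

    entity_ids: list[str]
    values: np.ndarray
    kind: str = "custom"

    _SYMMETRY_TOL = 1e-12

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match {n} entity ids"
            )
        _check_unique(self.entity_ids, "entity")
        asym = np.abs(self.values - self.values.T).max() if n else 0.0
        if asym > self._SYMMETRY_TOL:
            raise ValueError(f"similarity matrix is asymmetric (max |A-A'| = {asym:g})")

    @classmethod
    def identity(cls, entity_ids: Sequence[str], kind: str = "custom") -> "SimilarityMatrix":
        return cls(list(entity_ids), np.eye(len(entity_ids)), kind=kind)

    def reindex(self, entity_ids: Sequence[str]) -> "SimilarityMatrix":
        """Subset/reorder to ``entity_ids`` (all must be present)."""
        pos = {e: i for i, e in enumerate(self.entity_ids)}
        try:
            idx = np.array([pos[e] for e in entity_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"entity {exc.args[0]!r} not in similarity matrix") from None
        return SimilarityMatrix(
            list(entity_ids), self.values[np.ix_(idx, idx)], kind=self.kind
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.entity_ids, columns=self.entity_ids)


def pcc_similarity(profiles: ExpressionProfileSet) -> SimilarityMatrix:
    """Pearson-correlation similarity of expression profiles.

    Entities whose profile has zero variance across conditions have undefined
    correlations; their off-diagonal similarities are set to 0 (with a warning)
    and the diagonal to 1.
    """
    X = profiles.profiles
    sd = X.std(axis=1)
    degenerate = sd <= 0
    if degenerate.any():
        names = [profiles.entity_ids[i] for i in np.flatnonzero(degenerate)]
        warnings.warn(
            f"zero-variance expression profiles for {names[:5]}"
            f"{'...' if len(names) > 5 else ''}; their similarities are set to 0",
            UserWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr = np.atleast_2d(corr)
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return SimilarityMatrix(list(profiles.entity_ids), corr, kind="expression")


def functional_similarity(
    annotations: AnnotationSetCollection, denominator: str = "sqrt"
) -> SimilarityMatrix:
    """Annotation-set overlap similarity.

    With ``denominator="sqrt"`` (default) this is the Ochiai/cosine
    coefficient ``|Ra ∩ Rb| / sqrt(|Ra|·|Rb|)``, which is 1 for identical
    non-empty sets and lies in [0, 1].  ``denominator="product"`` divides by
    the plain product ``|Ra|·|Rb|`` instead.  Pairs where either set is empty
    score 0; the diagonal is always 1.
    """
    if denominator not in ("sqrt", "product"):
        raise ValueError("denominator must be 'sqrt' or 'product'")
    sets = annotations.term_sets
    n = len(sets)
    sizes = np.array([len(s) for s in sets], dtype=float)
    vals = np.zeros((n, n))
    for i in range(n):
        if sizes[i] == 0:
            continue
        for j in range(i + 1, n):
            if sizes[j] == 0:
                continue
            inter = len(sets[i] & sets[j])
            if inter:
                denom = sizes[i] * sizes[j]
                if denominator == "sqrt":
                    denom = np.sqrt(denom)
                vals[i, j] = vals[j, i] = inter / denom
    np.fill_diagonal(vals, 1.0)
    return SimilarityMatrix(list(annotations.entity_ids), vals, kind="function")


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match_score
    aligner.mismatch_score = scoring.mismatch_score
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def sequence_similarity_raw(
    seqs: SequenceSet, scoring: AlignmentScoring | None = None
) -> SimilarityMatrix:
    """Raw pairwise Needleman-Wunsch global-alignment scores.

    The score matrix is symmetric by construction (each unordered pair is
    aligned once) but NOT yet range-normalized; follow with
    :func:`normalize_columns_and_symmetrize` before feeding it to the model.
    """
    scoring = scoring or AlignmentScoring()
    aligner = _make_aligner(scoring)
    n = len(seqs.entity_ids)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            vals[i, j] = vals[j, i] = aligner.score(seqs.sequences[i], seqs.sequences[j])
    return SimilarityMatrix(list(seqs.entity_ids), vals, kind="sequence")


def normalize_columns_and_symmetrize(raw: SimilarityMatrix) -> SimilarityMatrix:
    """Two-step normalization of a raw (e.g. alignment-score) matrix.

    Step 1 divides every column by its maximum; columns whose maximum is not
    strictly positive are left as zeros with a warning.  Step 2 restores
    symmetry by overwriting the strict upper triangle with the transpose of
    the strict lower triangle (the lower triangle and diagonal of the
    column-normalized matrix are authoritative).  For nonnegative input the
    result lies in [0, 1].
    """
    vals = raw.values.copy()
    colmax = vals.max(axis=0)
    bad = colmax <= 0
    if bad.any():
        names = [raw.entity_ids[i] for i in np.flatnonzero(bad)]
        warnings.warn(
            f"columns with non-positive maxima left as zeros: {names[:5]}",
            UserWarning,
            stacklevel=2,
        )
        vals[:, bad] = 0.0
    good = ~bad
    vals[:, good] = vals[:, good] / colmax[good]
    out = np.tril(vals) + np.tril(vals, -1).T
    return SimilarityMatrix(list(raw.entity_ids), out, kind=raw.kind)


def assemble_similarity(
    side_info,
    universe_ids: Sequence[str],
    kind: str,
    *,
    scoring: AlignmentScoring | None = None,
    denominator: str = "sqrt",
    clamp_negative: bool = False,
) -> SimilarityMatrix:
    """Build a similarity matrix over an explicit id universe.

    ``side_info`` may cover only part of ``universe_ids`` (side data rarely
    exist for every entity in an interaction network); uncovered entities get
    off-diagonal similarity 0 and diagonal 1.  Entities in ``side_info`` but
    outside the universe are computed with (they influence e.g. the column
    maxima of the sequence normalization) and then dropped.

    kind ``"expression"`` routes through :func:`pcc_similarity`,
    ``"function"`` through :func:`functional_similarity`, ``"sequence"``
    through :func:`sequence_similarity_raw` +
    :func:`normalize_columns_and_symmetrize`.  ``clamp_negative`` zeroes
    negative Pearson correlations (off by default: raw correlations are kept).
    """
    universe_ids = list(universe_ids)
    _check_unique(universe_ids, "universe")
    if kind == "expression":
        sim = pcc_similarity(side_info)
        if clamp_negative:
            sim = SimilarityMatrix(
                sim.entity_ids, np.maximum(sim.values, 0.0), kind=sim.kind
            )
    elif kind == "function":
        sim = functional_similarity(side_info, denominator=denominator)
    elif kind == "sequence":
        sim = normalize_columns_and_symmetrize(
            sequence_similarity_raw(side_info, scoring)
        )
    else:
        raise ValueError(f"unknown similarity kind {kind!r}")

    pos = {e: i for i, e in enumerate(sim.entity_ids)}
    upos = {e: i for i, e in enumerate(universe_ids)}
    covered = [e for e in universe_ids if e in pos]
    out = np.eye(len(universe_ids))
    if covered:
        u_idx = np.array([upos[e] for e in covered], dtype=int)
        s_idx = np.array([pos[e] for e in covered], dtype=int)
        out[np.ix_(u_idx, u_idx)] = sim.values[np.ix_(s_idx, s_idx)]
    return SimilarityMatrix(universe_ids, out, kind=kind)
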