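"""Readers and writers for all interchange formats.

Tab-separated tables are the primary dialect; comma-separated input is
auto-detected.  Floating-point writers use a round-tripping representation
(``%.17g``) so write -> read is lossless.

Formats
-------
interactions   two-column edge list (lncRNA_id, miRNA_id), optional header;
               duplicate pairs are collapsed with a logged count.  A labelled
               rectangular matrix layout (``fmt="matrix"``) is also supported
               and is lossless for networks with isolated entities.
expression     delimited table, first column entity id, header of condition
               ids, real cells; missing values are rejected with coordinates.
annotations    two-column table (entity_id, term), one pair per line.
sequences      FASTA; the record id up to the first whitespace is the entity
               id; RNA and lowercase input are canonicalized (U->T, upper).
similarity     square delimited table with identical row/column id headers;
               symmetry is enforced to 1e-8 on read.
predictions    long table (lncRNA_id, miRNA_id, score, known_flag, rank).
cv report      long table (repetition, fold, auc) with a summary block in
               '#'-prefixed header lines.
manifest       JSON snapshot of a run: config, input digests, seeds, version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .evaluation import CVResult
from .model import InteractionMatrix, LinearNeighborResults, PredictionMatrix
from .similarity import (
    AnnotationSetCollection,
    ExpressionProfileSet,
    SequenceSet,
    SimilarityMatrix,
)

logger = logging.getLogger("lnrlink")

__all__ = [
    "read_interactions",
    "write_interactions",
    "read_expression",
    "write_expression",
    "read_annotations",
    "write_annotations",
    "read_fasta",
    "write_fasta",
    "read_similarity",
    "write_similarity",
    "write_predictions",
    "write_cv_report",
    "RunManifest",
    "write_dataset",
    "read_dataset",
]

_FLOAT_FMT = "%.17g"


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


# ---------------------------------------------------------------- interactions


def read_interactions(path) -> InteractionMatrix:
    """Read a known-interaction network.

    Edge-list input: two columns (lncRNA id, miRNA id); a first line
    mentioning 'lncRNA'/'miRNA' is treated as a header.  Ids are ordered by
    first appearance and duplicate pairs are collapsed to one (the number of
    duplicates is logged).  Input with >2 columns is parsed as a labelled
    matrix (id header row, id first column, 0/1 cells).
    """
    path = Path(path)
    sep = _detect_sep(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    rows = [ln for ln in lines if ln.strip()]
    if not rows:
        raise ValueError(f"{path}: empty interaction file")
    first_fields = rows[0].split(sep)
    if len(first_fields) > 2:
        return _read_interactions_matrix(path, sep)

    start = 0
    low = rows[0].lower()
    if "lnc" in low or "mir" in low:
        start = 1
    lnc_ids: list[str] = []
    mirna_ids: list[str] = []
    lnc_pos: dict[str, int] = {}
    mirna_pos: dict[str, int] = {}
    pairs: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    dupes = 0
    for lineno, row in enumerate(rows[start:], start=start + 1):
        fields = [f.strip() for f in row.split(sep)]
        if len(fields) != 2 or not all(fields):
            raise ValueError(f"{path}:{lineno}: malformed row {row!r}")
        l, m = fields
        if l not in lnc_pos:
            lnc_pos[l] = len(lnc_ids)
            lnc_ids.append(l)
        if m not in mirna_pos:
            mirna_pos[m] = len(mirna_ids)
            mirna_ids.append(m)
        key = (lnc_pos[l], mirna_pos[m])
        if key in seen:
            dupes += 1
            continue
        seen.add(key)
        pairs.append(key)
    if not pairs:
        raise ValueError(f"{path}: no interaction pairs found")
    if dupes:
        logger.info("%s: collapsed %d duplicate pairs (%d unique kept)",
                    path, dupes, len(pairs))
    values = np.zeros((len(lnc_ids), len(mirna_ids)), dtype=np.int8)
    idx = np.array(pairs)
    values[idx[:, 0], idx[:, 1]] = 1
    return InteractionMatrix(lnc_ids, mirna_ids, values)


def _read_interactions_matrix(path: Path, sep: str) -> InteractionMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0)
    vals = df.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{path}: matrix-form interactions must be 0/1")
    return InteractionMatrix(
        [str(i) for i in df.index], [str(c) for c in df.columns], vals
    )


def write_interactions(path, lmn: InteractionMatrix, fmt: str = "edges") -> None:
    """Write an interaction network.

    ``fmt="edges"`` emits a two-column edge list sorted by internal indices
    (entities with no interactions are necessarily dropped; re-reading orders
    ids by first appearance).  ``fmt="matrix"`` emits the labelled 0/1 grid,
    which round-trips exactly, including isolated entities and id order.
    """
    path = Path(path)
    if fmt == "edges":
        with open(path, "w") as fh:
            fh.write("lncRNA_id\tmiRNA_id\n")
            for i, j in lmn.positive_pairs():
                fh.write(f"{lmn.lnc_ids[i]}\t{lmn.mirna_ids[j]}\n")
    elif fmt == "matrix":
        df = pd.DataFrame(lmn.values, index=lmn.lnc_ids, columns=lmn.mirna_ids)
        df.to_csv(path, sep="\t", index_label="id")
    else:
        raise ValueError("fmt must be 'edges' or 'matrix'")


# ----------------------------------------------------------------- expression


def read_expression(path) -> ExpressionProfileSet:
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0,
                     float_precision="round_trip")
    bad = df.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: missing/non-numeric value at entity {df.index[r]!r}, "
            f"condition {df.columns[c]!r}"
        )
    try:
        vals = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric expression cell ({exc})") from None
    return ExpressionProfileSet(
        [str(i) for i in df.index], vals, [str(c) for c in df.columns]
    )


def write_expression(path, profiles: ExpressionProfileSet) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(profiles.condition_ids) + "\n")
        for eid, row in zip(profiles.entity_ids, profiles.profiles):
            fh.write(eid + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------- annotations


def read_annotations(path) -> AnnotationSetCollection:
    """Two-column (entity_id, term) table; entities ordered by first
    appearance.  A line with an entity id and an empty second field declares
    an entity with no annotations."""
    path = Path(path)
    sep = _detect_sep(path)
    ids: list[str] = []
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if lineno == 1 and line.lower().lstrip().startswith(("entity", "id")):
                continue
            fields = [f.strip() for f in line.rstrip("\n").split(sep)]
            if len(fields) != 2 or not fields[0]:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
            eid, term = fields
            if eid not in terms:
                terms[eid] = set()
                ids.append(eid)
            if term:
                terms[eid].add(term)
    if not ids:
        raise ValueError(f"{path}: empty annotation file")
    return AnnotationSetCollection(ids, [frozenset(terms[e]) for e in ids])


def write_annotations(path, annotations: AnnotationSetCollection) -> None:
    with open(path, "w") as fh:
        fh.write("entity_id\tterm\n")
        for eid, ts in zip(annotations.entity_ids, annotations.term_sets):
            if not ts:
                fh.write(f"{eid}\t\n")
            for t in sorted(ts):
                fh.write(f"{eid}\t{t}\n")


# ------------------------------------------------------------------ sequences


def read_fasta(path) -> SequenceSet:
    """FASTA reader; the record id (token before the first whitespace) is the
    entity id; sequences are canonicalized by the SequenceSet constructor."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return SequenceSet([r.id for r in records], [str(r.seq) for r in records])


def write_fasta(path, seqs: SequenceSet) -> None:
    records = [
        SeqRecord(Seq(s), id=e, description="")
        for e, s in zip(seqs.entity_ids, seqs.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


# ----------------------------------------------------------------- similarity


def read_similarity(path, kind: str = "custom") -> SimilarityMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0,
                     float_precision="round_trip")
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if row_ids != col_ids:
        raise ValueError(f"{path}: row and column ids differ")
    vals = df.to_numpy(dtype=float)
    if vals.size and np.abs(vals - vals.T).max() > 1e-8:
        raise ValueError(f"{path}: similarity matrix is not symmetric (tol 1e-8)")
    vals = (vals + vals.T) / 2.0
    return SimilarityMatrix(row_ids, vals, kind=kind)


def write_similarity(path, sim: SimilarityMatrix) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(sim.entity_ids) + "\n")
        for eid, row in zip(sim.entity_ids, sim.values):
            fh.write(eid + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------- results & reports


def write_predictions(path, results: LinearNeighborResults | pd.DataFrame) -> None:
    """Long-format prediction table sorted by descending score."""
    table = (
        results if isinstance(results, pd.DataFrame) else results.prediction_table()
    )
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_prediction_matrix(path, pm: PredictionMatrix) -> None:
    """Optional square-layout output mirroring the similarity format."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(pm.mirna_ids) + "\n")
        for eid, row in zip(pm.lnc_ids, pm.scores):
            fh.write(eid + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def write_cv_report(path, result: CVResult) -> None:
    """Per-fold AUC table preceded by a '#'-commented summary block."""
    with open(path, "w") as fh:
        fh.write(f"# mean_auc\t{_fmt(result.mean_auc)}\n")
        fh.write(f"# std_auc\t{_fmt(result.std_auc)}\n")
        fh.write(f"# best_auc\t{_fmt(result.best_auc)}\n")
        fh.write(f"# k\t{result.config.k}\n")
        fh.write(f"# repetitions\t{result.config.repetitions}\n")
        fh.write(f"# mode\t{result.config.mode}\n")
        fh.write(f"# alpha\t{_fmt(result.config.model.alpha)}\n")
        fh.write(f"# seed\t{result.config.seed}\n")
        fh.write("# pooled_auc_per_repetition\t"
                 + "\t".join(_fmt(a) for a in result.pooled_aucs) + "\n")
        fh.write("repetition\tfold\tauc\n")
        for (rep, fold), auc in np.ndenumerate(result.fold_aucs):
            fh.write(f"{rep}\t{fold}\t{_fmt(auc)}\n")


def write_roc_curves(path, result: CVResult) -> None:
    """Pooled ROC polylines, one block per repetition (rep, fpr, tpr)."""
    if result.roc_curves is None:
        raise ValueError("CV was run without collect_roc=True")
    with open(path, "w") as fh:
        fh.write("repetition\tfpr\ttpr\n")
        for rep, (fpr, tpr) in enumerate(result.roc_curves):
            for x, y in zip(fpr, tpr):
                fh.write(f"{rep}\t{_fmt(x)}\t{_fmt(y)}\n")


# -------------------------------------------------------------------- manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record emitted by every CLI run: the exact
    configuration, SHA-256 digests of the inputs, seeds and package version
    suffice to re-execute the run bit-for-bit."""

    command: str
    config: dict
    inputs: dict[str, str]
    seed: int | None
    version: str
    timestamp: str

    @classmethod
    def create(cls, command: str, config: Mapping, input_paths: Mapping,
               seed: int | None) -> "RunManifest":
        from . import __version__

        digests = {
            name: _sha256(Path(p)) for name, p in input_paths.items() if p is not None
        }
        return cls(
            command=command,
            config=dict(config),
            inputs=digests,
            seed=seed,
            version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


# ------------------------------------------------------------ dataset bundles


def write_dataset(dataset, out_dir) -> dict[str, Path]:
    """Write a synthetic dataset as the full standard file set.

    Interactions are stored in the lossless matrix layout plus a conventional
    edge list; a ground-truth group-label table accompanies them.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "interactions": out / "interactions.tsv",
        "interactions_edges": out / "interactions_edges.tsv",
        "lnc_expression": out / "lnc_expression.tsv",
        "mirna_expression": out / "mirna_expression.tsv",
        "lnc_annotations": out / "lnc_annotations.tsv",
        "mirna_annotations": out / "mirna_annotations.tsv",
        "lnc_sequences": out / "lnc_sequences.fasta",
        "mirna_sequences": out / "mirna_sequences.fasta",
        "groups": out / "groups.tsv",
    }
    write_interactions(paths["interactions"], dataset.lmn, fmt="matrix")
    write_interactions(paths["interactions_edges"], dataset.lmn, fmt="edges")
    write_expression(paths["lnc_expression"], dataset.lnc_profiles)
    write_expression(paths["mirna_expression"], dataset.mirna_profiles)
    write_annotations(paths["lnc_annotations"], dataset.lnc_annotations)
    write_annotations(paths["mirna_annotations"], dataset.mirna_annotations)
    write_fasta(paths["lnc_sequences"], dataset.lnc_seqs)
    write_fasta(paths["mirna_sequences"], dataset.mirna_seqs)
    with open(paths["groups"], "w") as fh:
        fh.write("entity_id\tgroup\n")
        for eid, g in dataset.group_of_entity.items():
            fh.write(f"{eid}\t{g}\n")
    return paths


def read_dataset(in_dir):
    """Read back the file set written by :func:`write_dataset` (ground-truth
    labels and config are not part of the on-disk data contract)."""
    from .synthetic import SyntheticDataset  # local import to avoid a cycle

    d = Path(in_dir)
    lmn = read_interactions(d / "interactions.tsv")
    groups = pd.read_csv(d / "groups.tsv", sep="\t", index_col=0)["group"]
    return SyntheticDataset(
        config=None,
        lmn=lmn,
        lnc_groups=groups.loc[lmn.lnc_ids].to_numpy(),
        mirna_groups=groups.loc[lmn.mirna_ids].to_numpy(),
        lnc_profiles=read_expression(d / "lnc_expression.tsv"),
        mirna_profiles=read_expression(d / "mirna_expression.tsv"),
        lnc_annotations=read_annotations(d / "lnc_annotations.tsv"),
        mirna_annotations=read_annotations(d / "mirna_annotations.tsv"),
        lnc_seqs=read_fasta(d / "lnc_sequences.fasta"),
        mirna_seqs=read_fasta(d / "mirna_sequences.fasta"),
    )
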