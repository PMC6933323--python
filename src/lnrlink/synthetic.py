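"""Planted-structure synthetic datasets for end-to-end testing.

The generator emulates the statistical shape of a curated lncRNA-miRNA
interaction resource: a sparse binary bipartite network (a few percent
density) whose edges are driven by latent functional groups, plus three kinds
of side information — expression profiles, annotation-term sets and
nucleotide sequences — whose pairwise similarities correlate with the same
groups.  That correlation is exactly the working assumption of the link
predictor ("entities with similar function tend to share interaction
partners"), so recovering held-out edges on these datasets exercises every
stage of the pipeline with known ground truth.

Mechanisms, all driven by one seed:

* interactions — planted-partition model: each lncRNA and miRNA is assigned a
  group uniformly at random; an edge is drawn Bernoulli(p_in) for same-group
  pairs and Bernoulli(p_out) otherwise;
* expression — each group has a Gaussian centroid profile; entity profiles
  are the centroid plus iid Gaussian noise;
* annotations — each group owns a disjoint term pool; entities draw a fixed
  number of terms, mostly (``group_term_fraction``) from their group pool and
  the rest from a shared global pool;
* sequences — iid uniform nucleotide background with a fixed per-group motif
  implanted at a random position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .model import InteractionMatrix
from .similarity import (
    AnnotationSetCollection,
    ExpressionProfileSet,
    SequenceSet,
)

__all__ = [
    "PlantedModelConfig",
    "SyntheticDataset",
    "generate_planted_interactions",
    "generate_expression_profiles",
    "generate_annotations",
    "generate_sequences",
    "generate_dataset",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedModelConfig:
    """Defaults give an 80 x 40 network with ~2-3% background density and a
    clear planted-group signal in both the network and the side data."""

    n_lnc: int = 80
    n_mirna: int = 40
    n_groups: int = 4
    p_in: float = 0.3
    p_out: float = 0.02
    n_conditions: int = 20
    noise_sd: float = 0.5
    terms_per_entity: int = 8
    pool_per_group: int = 30
    global_pool: int = 40
    group_term_fraction: float = 0.8
    seq_length: int = 120
    motif_length: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_out <= self.p_in <= 1):
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if self.n_groups > min(self.n_lnc, self.n_mirna):
            raise ValueError("n_groups must not exceed min(n_lnc, n_mirna)")
        for name in ("n_lnc", "n_mirna", "n_groups", "n_conditions", "seq_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.group_term_fraction <= 1:
            raise ValueError("group_term_fraction must be in [0, 1]")
        if not 0 <= self.motif_length <= self.seq_length:
            raise ValueError("motif_length must be in [0, seq_length]")


@dataclass
class SyntheticDataset:
    """All components share consistent entity ids; reproducible from the
    config seed."""

    config: PlantedModelConfig
    lmn: InteractionMatrix
    lnc_groups: np.ndarray
    mirna_groups: np.ndarray
    lnc_profiles: ExpressionProfileSet
    mirna_profiles: ExpressionProfileSet
    lnc_annotations: AnnotationSetCollection
    mirna_annotations: AnnotationSetCollection
    lnc_seqs: SequenceSet
    mirna_seqs: SequenceSet

    @property
    def group_of_entity(self) -> dict[str, int]:
        out = dict(zip(self.lmn.lnc_ids, self.lnc_groups.tolist()))
        out.update(zip(self.lmn.mirna_ids, self.mirna_groups.tolist()))
        return out


def _entity_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1:04d}" for i in range(n)]


def generate_planted_interactions(
    config: PlantedModelConfig, rng: np.random.Generator | None = None
) -> tuple[InteractionMatrix, np.ndarray, np.ndarray]:
    """Planted-partition bipartite network plus ground-truth group labels.

    If the first draw yields an empty network it is redrawn once; a second
    empty draw raises (the configuration is then too sparse to be usable).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    for attempt in range(2):
        lnc_groups = rng.integers(config.n_groups, size=config.n_lnc)
        mirna_groups = rng.integers(config.n_groups, size=config.n_mirna)
        same = lnc_groups[:, None] == mirna_groups[None, :]
        prob = np.where(same, config.p_in, config.p_out)
        values = (rng.random((config.n_lnc, config.n_mirna)) < prob).astype(np.int8)
        if values.any():
            lmn = InteractionMatrix(
                _entity_ids("LNC", config.n_lnc),
                _entity_ids("MIR", config.n_mirna),
                values,
            )
            return lmn, lnc_groups, mirna_groups
    raise RuntimeError("planted network was empty twice; increase p_in/p_out")


def generate_expression_profiles(
    groups: np.ndarray,
    config: PlantedModelConfig,
    rng: np.random.Generator | None = None,
    prefix: str = "LNC",
) -> ExpressionProfileSet:
    """Group centroid (standard normal per condition) plus Gaussian noise of
    scale ``noise_sd``; within-group Pearson similarity therefore exceeds
    between-group similarity in expectation."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    centroids = rng.standard_normal((config.n_groups, config.n_conditions))
    profiles = centroids[groups] + config.noise_sd * rng.standard_normal(
        (len(groups), config.n_conditions)
    )
    return ExpressionProfileSet(
        _entity_ids(prefix, len(groups)),
        profiles,
        [f"cond{i + 1:02d}" for i in range(config.n_conditions)],
    )


def generate_annotations(
    groups: np.ndarray,
    config: PlantedModelConfig,
    rng: np.random.Generator | None = None,
    prefix: str = "LNC",
) -> AnnotationSetCollection:
    """Each entity draws ``terms_per_entity`` distinct terms, a
    ``group_term_fraction`` share from its group's disjoint pool and the rest
    from a shared global pool."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_group_terms = int(round(config.group_term_fraction * config.terms_per_entity))
    n_global_terms = config.terms_per_entity - n_group_terms
    if n_group_terms > config.pool_per_group:
        raise ValueError("terms_per_entity exceeds the per-group term pool")
    if n_global_terms > config.global_pool:
        raise ValueError("terms_per_entity exceeds the global term pool")
    group_pools = [
        [f"G{g}_T{t:03d}" for t in range(config.pool_per_group)]
        for g in range(config.n_groups)
    ]
    global_pool = [f"GLOBAL_T{t:03d}" for t in range(config.global_pool)]
    term_sets = []
    for g in groups:
        picked = list(
            rng.choice(group_pools[g], size=n_group_terms, replace=False)
        ) + list(rng.choice(global_pool, size=n_global_terms, replace=False))
        term_sets.append(frozenset(str(t) for t in picked))
    return AnnotationSetCollection(_entity_ids(prefix, len(groups)), term_sets)


def generate_sequences(
    groups: np.ndarray,
    config: PlantedModelConfig,
    rng: np.random.Generator | None = None,
    prefix: str = "LNC",
) -> SequenceSet:
    """Uniform random background with a fixed group motif implanted at a
    random position, so alignment similarity is higher within groups."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    motifs = [
        "".join(rng.choice(_BASES, size=config.motif_length))
        for _ in range(config.n_groups)
    ]
    seqs = []
    for g in groups:
        s = list(rng.choice(_BASES, size=config.seq_length))
        if config.motif_length:
            start = int(rng.integers(0, config.seq_length - config.motif_length + 1))
            s[start : start + config.motif_length] = motifs[g]
        seqs.append("".join(s))
    return SequenceSet(_entity_ids(prefix, len(groups)), seqs)


def generate_dataset(config: PlantedModelConfig | None = None) -> SyntheticDataset:
    """Compose all four generators under one seed.

    Independent child RNG streams are spawned deterministically from
    ``config.seed``, so any single component can be regenerated without
    replaying the others.
    """
    config = config or PlantedModelConfig()
    children = np.random.SeedSequence(config.seed).spawn(7)
    rng = [np.random.default_rng(c) for c in children]
    lmn, lnc_groups, mirna_groups = generate_planted_interactions(config, rng[0])
    return SyntheticDataset(
        config=config,
        lmn=lmn,
        lnc_groups=lnc_groups,
        mirna_groups=mirna_groups,
        lnc_profiles=generate_expression_profiles(lnc_groups, config, rng[1], "LNC"),
        mirna_profiles=generate_expression_profiles(mirna_groups, config, rng[2], "MIR"),
        lnc_annotations=generate_annotations(lnc_groups, config, rng[3], "LNC"),
        mirna_annotations=generate_annotations(mirna_groups, config, rng[4], "MIR"),
        lnc_seqs=generate_sequences(lnc_groups, config, rng[5], "LNC"),
        mirna_seqs=generate_sequences(mirna_groups, config, rng[6], "MIR"),
    )
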