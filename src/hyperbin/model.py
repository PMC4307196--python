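"""The trained model container and the end-to-end pipeline.

``build_model`` runs the whole training side: feature extraction from
reference sequences, online SOM training on the hyperbolic lattice,
Voronoi partitioning of the training features, and per-rank node
labeling. ``classify_records`` runs the assignment side with the
normalization and corpus statistics frozen into the model at training
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from . import kmers
from .classify import (
    ClassifierConfig,
    Lineage,
    NodeLabels,
    Assignment,
    assign_reads,
    label_all_ranks,
    voronoi_partition,
)
from .errors import ConfigurationError, InvalidParameterError
from .kmers import CorpusTermStats, FeaturizeResult
from .lattice import Lattice, build_lattice
from .som import TrainingConfig, train

__all__ = ["H2SOMModel", "build_model", "classify_records"]

FORMAT_VERSION = 1


@dataclass
class H2SOMModel:
    """A trained, labeled hierarchical hyperbolic SOM.

    Everything needed to classify new reads is frozen in: architecture
    (k, s, r), the lattice geometry, the prototype matrix, the feature
    normalization (plus corpus term statistics when it is tfti), the
    per-rank node label tables, and the default classifier settings.
    """

    k: int
    s: int
    r: int
    normalization: str
    lattice: Lattice
    prototypes: np.ndarray
    node_labels: NodeLabels
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    term_stats: Optional[CorpusTermStats] = None
    format_version: int = FORMAT_VERSION

    def __post_init__(self) -> None:
        if self.normalization == "tfti" and self.term_stats is None:
            raise ConfigurationError(
                "a tfti model must carry its corpus term statistics"
            )
        if self.prototypes.shape != (self.lattice.n_nodes, 4**self.k):
            raise InvalidParameterError(
                "prototype matrix shape must be (n_nodes, 4^k)"
            )


def _featurize_records(
    records: Sequence,
    k: int,
    normalization: str,
    stats: Optional[CorpusTermStats],
) -> FeaturizeResult:
    seqs = [rec.sequence for rec in records]
    return kmers.featurize(seqs, k, normalization, stats=stats)


def build_model(
    records: Sequence,
    lineages: Mapping[str, Lineage],
    k: int = 4,
    s: int = 8,
    r: int = 5,
    normalization: str = "tf",
    training: Optional[TrainingConfig] = None,
    classifier: Optional[ClassifierConfig] = None,
) -> H2SOMModel:
    """Train and label a model from reference sequence records and their
    lineage table.

    Every record id must have a lineage. Records whose sequence cannot be
    featurized (too short or fully ambiguous) are skipped with a report;
    at least one must survive.
    """
    if not (2 <= k <= 8):
        raise InvalidParameterError("k must lie in 2..8")
    training = training if training is not None else TrainingConfig()
    classifier = classifier if classifier is not None else ClassifierConfig()
    missing = [rec.id for rec in records if rec.id not in lineages]
    if missing:
        raise InvalidParameterError(
            f"{len(missing)} reference sequences have no lineage "
            f"(first: {missing[0]!r})"
        )

    stats: Optional[CorpusTermStats] = None
    if normalization == "tfti":
        profiles = [kmers.count_kmers(rec.sequence, k) for rec in records]
        stats = kmers.corpus_term_stats(profiles)
    feats = _featurize_records(records, k, normalization, stats)
    if not feats.vectors:
        raise InvalidParameterError("no reference sequence could be featurized")

    lattice = build_lattice(s, r)
    prototypes = train(feats.vectors, lattice, training)
    cells = voronoi_partition(
        feats.vectors, prototypes, lattice, classifier.beam_width
    )
    kept_lineages = [lineages[records[i].id] for i in feats.indices]
    node_labels = label_all_ranks(
        cells,
        kept_lineages,
        lattice.n_nodes,
        labeling=classifier.labeling,
        alpha=classifier.alpha,
    )
    return H2SOMModel(
        k=k,
        s=s,
        r=r,
        normalization=normalization,
        lattice=lattice,
        prototypes=prototypes,
        node_labels=node_labels,
        classifier=classifier,
        training=training,
        term_stats=stats,
    )


def classify_records(
    records: Sequence,
    model: H2SOMModel,
    config: Optional[ClassifierConfig] = None,
) -> tuple[List[Assignment], List[tuple]]:
    """Classify query records with a trained model; returns the
    assignments and the (index, reason) skip reports of unusable reads.

    Features are computed with the model's frozen normalization; for
    tfti the corpus statistics learned at training time are used and
    never updated by queries.
    """
    feats = _featurize_records(
        records, model.k, model.normalization, model.term_stats
    )
    ids = [records[i].id for i in feats.indices]
    assignments = assign_reads(feats.vectors, model, config, read_ids=ids)
    return assignments, feats.skipped
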