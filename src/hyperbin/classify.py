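"""Taxonomic labeling of trained nodes and classification of query reads.

After training, each node is linked to taxonomy by mapping the labeled
training features onto the grid: the Voronoi cell of a node is the set
of training vectors whose BMU it is, and a labeling function turns each
cell into a taxon per rank — either plain majority voting, or purity
voting which demands that the majority fraction strictly exceed a
threshold alpha and otherwise assigns the rejection class R. Unvisited
nodes are rejected.

Queries are classified per rank by one of three rules: ``nn`` takes the
BMU's label; ``thresh`` additionally rejects when the BMU distance
reaches an empirical threshold beta; ``nbrs`` exploits neighborhood
preservation — when the BMU's two ring siblings agree on a label and lie
comparatively close (d(x,u_{j+1}) + d(x,u_{j-1}) < 3*d(x,u_j)), their
label overrides the BMU's. Rejection propagates downward so the output
lineage never has gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import (
    ConfigurationError,
    InvalidParameterError,
    LineageValidationError,
)
from .kmers import FeatureVector
from .lattice import Lattice
from .som import beam_search_bmu

__all__ = [
    "RANKS",
    "REJECT",
    "Lineage",
    "NodeLabels",
    "ClassifierConfig",
    "Assignment",
    "voronoi_partition",
    "label_majority",
    "label_purity",
    "label_all_ranks",
    "classify_nn",
    "classify_thresh",
    "classify_nbrs",
    "estimate_beta",
    "assign_reads",
]

RANKS: Tuple[str, ...] = ("superkingdom", "phylum", "class", "order")

#: Distinguished rejection label; reserved, never a valid taxon name.
REJECT = "__REJECT__"


@dataclass(frozen=True)
class Lineage:
    """Ranked taxonomic path superkingdom -> phylum -> class -> order;
    lower ranks may be absent but a present rank implies all above it."""

    taxa: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) > len(RANKS):
            raise LineageValidationError(
                f"at most {len(RANKS)} ranks supported, got {len(self.taxa)}"
            )
        if any(t == "" or t is None for t in self.taxa):
            raise LineageValidationError(
                "empty taxon inside a lineage (gap in ranks)"
            )
        if REJECT in self.taxa:
            raise LineageValidationError(f"{REJECT!r} is reserved")

    def get(self, rank: str) -> Optional[str]:
        i = RANKS.index(rank)
        return self.taxa[i] if i < len(self.taxa) else None

    @property
    def depth(self) -> int:
        return len(self.taxa)


@dataclass
class NodeLabels:
    """Per-rank taxon (or REJECT) for every lattice node, plus the
    Voronoi occupancy count per node."""

    labels: Dict[str, List[str]]
    occupancy: np.ndarray

    def for_rank(self, rank: str) -> List[str]:
        return self.labels[rank]


@dataclass
class ClassifierConfig:
    labeling: str = "pur"  # 'maj' | 'pur'
    alpha: float = 0.8
    rule: str = "nn"  # 'nn' | 'thresh' | 'nbrs'
    beta: Optional[float] = None
    beam_width: int = 1

    def __post_init__(self) -> None:
        if self.labeling not in ("maj", "pur"):
            raise ConfigurationError(f"unknown labeling {self.labeling!r}")
        if not (0 < self.alpha <= 1):
            raise ConfigurationError("alpha must lie in (0, 1]")
        if self.rule not in ("nn", "thresh", "nbrs"):
            raise ConfigurationError(f"unknown rule {self.rule!r}")
        if self.rule == "thresh" and self.beta is None:
            raise ConfigurationError(
                "rule 'thresh' requires beta (set it or use estimate_beta)"
            )
        if self.beam_width < 1:
            raise ConfigurationError("beam_width must be >= 1")


@dataclass
class Assignment:
    """Classification outcome of one read."""

    read_id: str
    predictions: Dict[str, str]  # rank -> taxon or REJECT
    node: int
    distance: float

    def lineage_path(self) -> List[str]:
        """Assigned taxa from the top rank down to the first rejection."""
        path = []
        for rank in RANKS:
            taxon = self.predictions[rank]
            if taxon == REJECT:
                break
            path.append(taxon)
        return path


def _features_to_matrix(features: Sequence[Union[FeatureVector, np.ndarray]]):
    rows = [
        f.values if isinstance(f, FeatureVector) else np.asarray(f, dtype=np.float64)
        for f in features
    ]
    return np.array(rows, dtype=np.float64)


def voronoi_partition(
    features: Sequence[Union[FeatureVector, np.ndarray]],
    prototypes: np.ndarray,
    lattice: Lattice,
    beam_width: int = 1,
) -> Dict[int, List[int]]:
    """Map each feature to its (beam-search) BMU; returns node -> member
    feature indices. Nodes may have empty cells and are then absent from
    the mapping."""
    if len(features) == 0:
        raise InvalidParameterError("cannot partition an empty feature set")
    cells: Dict[int, List[int]] = {}
    for i, f in enumerate(features):
        node, _ = beam_search_bmu(f, prototypes, lattice, beam_width)
        cells.setdefault(node, []).append(i)
    return cells


def _vote(
    members: Sequence[int], lineages: Sequence[Lineage], rank: str
) -> Tuple[Optional[str], int]:
    """Majority taxon among cell members carrying the rank (ties to the
    lexicographically smallest taxon) and its vote count."""
    votes: Dict[str, int] = {}
    for i in members:
        taxon = lineages[i].get(rank)
        if taxon is not None:
            votes[taxon] = votes.get(taxon, 0) + 1
    if not votes:
        return None, 0
    winner = min(votes, key=lambda t: (-votes[t], t))
    return winner, votes[winner]


def label_majority(
    cells: Mapping[int, Sequence[int]],
    lineages: Sequence[Lineage],
    rank: str,
    n_nodes: int,
) -> List[str]:
    """Majority-vote label per node at one rank; empty cells get REJECT."""
    labels = [REJECT] * n_nodes
    for node, members in cells.items():
        winner, _ = _vote(members, lineages, rank)
        if winner is not None:
            labels[node] = winner
    return labels


def label_purity(
    cells: Mapping[int, Sequence[int]],
    lineages: Sequence[Lineage],
    rank: str,
    n_nodes: int,
    alpha: float,
) -> List[str]:
    """Purity-vote label per node: the majority taxon if its cell
    fraction strictly exceeds alpha, else REJECT."""
    if not (0 < alpha <= 1):
        raise InvalidParameterError("alpha must lie in (0, 1]")
    labels = [REJECT] * n_nodes
    for node, members in cells.items():
        winner, count = _vote(members, lineages, rank)
        if winner is not None and count / len(members) > alpha:
            labels[node] = winner
    return labels


def label_all_ranks(
    cells: Mapping[int, Sequence[int]],
    lineages: Sequence[Lineage],
    n_nodes: int,
    labeling: str = "pur",
    alpha: float = 0.8,
) -> NodeLabels:
    """Label every node at every rank with one labeling strategy."""
    occupancy = np.zeros(n_nodes, dtype=np.int64)
    for node, members in cells.items():
        occupancy[node] = len(members)
    labels = {}
    for rank in RANKS:
        if labeling == "maj":
            labels[rank] = label_majority(cells, lineages, rank, n_nodes)
        elif labeling == "pur":
            labels[rank] = label_purity(cells, lineages, rank, n_nodes, alpha)
        else:
            raise ConfigurationError(f"unknown labeling {labeling!r}")
    return NodeLabels(labels=labels, occupancy=occupancy)


def _check_labeled(node_labels: Sequence[str], prototypes: np.ndarray) -> None:
    if node_labels is None or len(node_labels) != prototypes.shape[0]:
        raise ConfigurationError("model is not labeled (one label per node needed)")


def classify_nn(
    x: Union[FeatureVector, np.ndarray],
    prototypes: np.ndarray,
    node_labels: Sequence[str],
    lattice: Lattice,
    beam_width: int = 1,
) -> Tuple[str, int, float]:
    """Nearest-neighbor rule: the BMU's label (which may be REJECT)."""
    _check_labeled(node_labels, prototypes)
    node, dist = beam_search_bmu(x, prototypes, lattice, beam_width)
    return node_labels[node], node, dist


def classify_thresh(
    x: Union[FeatureVector, np.ndarray],
    prototypes: np.ndarray,
    node_labels: Sequence[str],
    lattice: Lattice,
    beta: Optional[float],
    beam_width: int = 1,
) -> Tuple[str, int, float]:
    """Distance-threshold rule: nearest-neighbor label when the BMU
    distance stays below beta, REJECT otherwise."""
    if beta is None:
        raise ConfigurationError("rule 'thresh' requires beta")
    if beta <= 0:
        raise InvalidParameterError("beta must be positive")
    label, node, dist = classify_nn(x, prototypes, node_labels, lattice, beam_width)
    if dist < beta:
        return label, node, dist
    return REJECT, node, dist


def classify_nbrs(
    x: Union[FeatureVector, np.ndarray],
    prototypes: np.ndarray,
    node_labels: Sequence[str],
    lattice: Lattice,
    beam_width: int = 1,
) -> Tuple[str, int, float]:
    """Neighborhood-smoothing rule: if the BMU's two ring siblings agree
    on a label and d(x,u_{j+1}) + d(x,u_{j-1}) < 3*d(x,u_j), their label
    wins; otherwise fall back to the nearest-neighbor rule."""
    _check_labeled(node_labels, prototypes)
    vec = x.values if isinstance(x, FeatureVector) else np.asarray(x, dtype=np.float64)
    node, dist = beam_search_bmu(vec, prototypes, lattice, beam_width)
    siblings = lattice.nodes[node].ring_siblings
    if siblings is not None:
        prev, nxt = siblings
        d_prev = float(np.linalg.norm(vec - prototypes[prev]))
        d_next = float(np.linalg.norm(vec - prototypes[nxt]))
        if d_next + d_prev < 3 * dist and node_labels[prev] == node_labels[nxt]:
            return node_labels[nxt], node, dist
    return node_labels[node], node, dist


def estimate_beta(
    training_distances: Sequence[float], quantile: float = 0.95
) -> float:
    """Empirical quantile (linear interpolation) of training BMU
    distances, used as the rejection threshold of the thresh rule."""
    if len(training_distances) == 0:
        raise InvalidParameterError("need at least one distance")
    if not (0 < quantile < 1):
        raise InvalidParameterError("quantile must lie strictly in (0, 1)")
    return float(np.quantile(np.asarray(training_distances, dtype=np.float64), quantile))


def assign_reads(
    features: Sequence[Union[FeatureVector, np.ndarray]],
    model,
    config: Optional[ClassifierConfig] = None,
    read_ids: Optional[Sequence[str]] = None,
) -> List[Assignment]:
    """Classify features against a labeled model, independently per rank,
    then propagate rejection downward so output lineages have no gaps.

    ``model`` needs ``prototypes``, ``lattice`` and ``node_labels``
    attributes (and a ``classifier`` default config, used when ``config``
    is None). Pure per-read computation, so ordering and batching cannot
    change results.
    """
    cfg = config if config is not None else model.classifier
    if cfg.rule == "thresh":
        if cfg.beta is None:
            raise ConfigurationError("rule 'thresh' requires beta")
        if cfg.beta <= 0:
            raise InvalidParameterError("beta must be positive")
    if read_ids is None:
        read_ids = [f"q{i}" for i in range(len(features))]
    out: List[Assignment] = []
    for rid, f in zip(read_ids, features):
        vec = (
            f.values if isinstance(f, FeatureVector) else np.asarray(f, dtype=np.float64)
        )
        # the BMU does not depend on the rank; find it once per read
        node, dist = beam_search_bmu(
            vec, model.prototypes, model.lattice, cfg.beam_width
        )
        siblings = model.lattice.nodes[node].ring_siblings
        sibling_close = False
        if cfg.rule == "nbrs" and siblings is not None:
            d_prev = float(np.linalg.norm(vec - model.prototypes[siblings[0]]))
            d_next = float(np.linalg.norm(vec - model.prototypes[siblings[1]]))
            sibling_close = d_next + d_prev < 3 * dist
        predictions: Dict[str, str] = {}
        rejected = False
        for rank in RANKS:
            labels = model.node_labels.for_rank(rank)
            if rejected:
                predictions[rank] = REJECT
                continue
            label = labels[node]
            if cfg.rule == "thresh" and dist >= cfg.beta:
                label = REJECT
            elif cfg.rule == "nbrs" and sibling_close and siblings is not None:
                if labels[siblings[0]] == labels[siblings[1]]:
                    label = labels[siblings[1]]
            predictions[rank] = label
            if label == REJECT:
                rejected = True
        out.append(Assignment(rid, predictions, node, dist))
    return out
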