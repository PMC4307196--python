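"""Seeded synthetic communities with controllable compositional signal.

Each taxon is an order-1 nucleotide Markov chain. Phylum-level base
transition matrices are drawn independently and mixed toward a shared
global matrix by an amount controlled by ``separation``; order-level
matrices are small perturbations of their phylum base. At separation 0
every taxon shares one matrix (no signal at all); as separation grows,
between-phylum compositional distance grows while sibling orders stay
comparatively close, emulating the hierarchical k-mer signal real
genomes carry. Reads are sampled from each chain started at its
stationary distribution, so long reads have dinucleotide frequencies
converging to pi_a * T[a, b].

Read ids are opaque (they encode nothing about the taxon); labels
travel only in the returned lineage mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .classify import Lineage
from .errors import InvalidParameterError
from .io import SequenceRecord

__all__ = ["TaxonModel", "CommunitySpec", "sample_taxa", "generate_reads"]

_ALPHABET = np.frombuffer(b"acgt", dtype=np.uint8)


@dataclass(frozen=True)
class TaxonModel:
    lineage: Lineage
    transition: np.ndarray  # 4x4, rows sum to 1
    initial: np.ndarray  # length 4, sums to 1

    def __post_init__(self) -> None:
        if self.transition.shape != (4, 4) or self.initial.shape != (4,):
            raise InvalidParameterError("transition must be 4x4, initial length 4")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-12):
            raise InvalidParameterError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-12):
            raise InvalidParameterError("initial distribution must sum to 1")


@dataclass(frozen=True)
class CommunitySpec:
    """Study conditions of one synthetic community.

    Defaults describe the standard benchmark community: 12 taxa
    (4 phyla x 3 orders), 420 reads of 1 kb per taxon (~5,000 reads),
    well-separated phyla.
    """

    n_phyla: int = 4
    orders_per_phylum: int = 3
    reads_per_taxon: int = 420
    read_length: int = 1000
    separation: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_phyla, self.orders_per_phylum, self.reads_per_taxon) < 1:
            raise InvalidParameterError("all counts must be positive")
        if self.read_length < 1:
            raise InvalidParameterError("read_length must be positive")
        if self.separation < 0:
            raise InvalidParameterError("separation must be >= 0")


def _stationary(transition: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(transition.T)
    pi = np.real(vecs[:, np.argmax(np.real(vals))])
    pi = np.abs(pi)
    return pi / pi.sum()


def sample_taxa(spec: CommunitySpec) -> List[TaxonModel]:
    """Draw the taxon transition matrices of a community, deterministic
    given the spec seed.

    With w = separation/(1+separation), a phylum matrix is
    (1-w)*G + w*D_p for a shared global matrix G and an independent
    Dirichlet draw D_p; an order matrix perturbs its phylum base with
    the much smaller weight w/(2*(1+separation)). At separation 0 both
    weights vanish and every taxon is exactly G.
    """
    rng = np.random.default_rng(spec.seed)
    global_matrix = rng.dirichlet(np.full(4, 5.0), size=4)
    w_phy = spec.separation / (1.0 + spec.separation)
    w_ord = w_phy / (2.0 * (1.0 + spec.separation))
    taxa: List[TaxonModel] = []
    for p in range(spec.n_phyla):
        d_phy = rng.dirichlet(np.ones(4), size=4)
        base = (1 - w_phy) * global_matrix + w_phy * d_phy
        for o in range(spec.orders_per_phylum):
            d_ord = rng.dirichlet(np.ones(4), size=4)
            transition = (1 - w_ord) * base + w_ord * d_ord
            transition /= transition.sum(axis=1, keepdims=True)
            lineage = Lineage(
                (
                    "Bacteria",
                    f"Phylum_{p:02d}",
                    f"Class_{p:02d}_{o:02d}",
                    f"Order_{p:02d}_{o:02d}",
                )
            )
            taxa.append(TaxonModel(lineage, transition, _stationary(transition)))
    return taxa


def generate_reads(
    taxa: List[TaxonModel], spec: CommunitySpec
) -> Tuple[List[SequenceRecord], Dict[str, Lineage]]:
    """Sample ``reads_per_taxon`` Markov-chain reads per taxon.

    Returns FASTA-ready records (opaque ids, shuffled order) and the
    id -> lineage mapping.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    n = spec.reads_per_taxon
    length = spec.read_length
    sequences: List[str] = []
    taxon_of: List[int] = []
    for ti, taxon in enumerate(taxa):
        cum = np.cumsum(taxon.transition, axis=1)
        states = np.empty((n, length), dtype=np.int64)
        states[:, 0] = rng.choice(4, size=n, p=taxon.initial)
        u = rng.random((n, length))
        for pos in range(1, length):
            states[:, pos] = (
                u[:, pos, None] > cum[states[:, pos - 1]]
            ).sum(axis=1)
        for row in states:
            sequences.append(_ALPHABET[row].tobytes().decode("ascii"))
        taxon_of.extend([ti] * n)
    order = rng.permutation(len(sequences))
    records: List[SequenceRecord] = []
    lineages: Dict[str, Lineage] = {}
    for new_idx, old_idx in enumerate(order):
        rid = f"read_{new_idx:06d}"
        records.append(SequenceRecord(rid, rid, sequences[old_idx]))
        lineages[rid] = taxa[taxon_of[old_idx]].lineage
    return records, lineages
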