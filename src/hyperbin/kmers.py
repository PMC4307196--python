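"""k-mer composition features for DNA sequences.

A sequence of length n over {a,c,g,t} contains n-k+1 overlapping k-mers;
their occurrence counts form a profile of dimension 4^k. Three normalized
variants of the profile are provided:

``tf``
    the profile scaled to unit Euclidean length (term frequency);
``tfti``
    term frequency / term importance — each count is divided by the total
    occurrence of that k-mer across the reference corpus and by the
    sequence's own total, then the vector is scaled to unit length, which
    damps the dominance of globally frequent k-mers;
``oligo``
    an over/under-representation contrast g of observed counts against
    the expectation under an independent single-nucleotide null model
    (g = K/E when over-represented, -E/K when under-represented, 0 when
    the k-mer is absent).

Ambiguous characters (N and other IUPAC codes) invalidate every window
that contains them and are excluded from sequence length and nucleotide
frequencies. Counting is case-insensitive and forward-strand only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import DegenerateInputError, InconsistencyError, InvalidParameterError

__all__ = [
    "KmerProfile",
    "FeatureVector",
    "CorpusTermStats",
    "FeaturizeResult",
    "count_kmers",
    "tf_normalize",
    "corpus_term_stats",
    "tfti_normalize",
    "oligo_features",
    "featurize",
    "kmer_index",
]

NORMALIZATIONS = ("tf", "tfti", "oligo")

# byte value -> nucleotide code (a=0, c=1, g=2, t=3), -1 for anything else
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _ch in enumerate(b"acgt"):
    _CODE[_ch] = _i
    _CODE[_ch - 32] = _i  # upper case


def _encode(sequence: str) -> np.ndarray:
    raw = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    return _CODE[raw]


def kmer_index(kmer: str) -> int:
    """Lexicographic rank of a k-mer (a=0 < c=1 < g=2 < t=3, leftmost most
    significant); the index of its component in profiles and features."""
    codes = _encode(kmer)
    if len(codes) == 0 or (codes < 0).any():
        raise InvalidParameterError(f"not an unambiguous DNA k-mer: {kmer!r}")
    return int(codes @ (4 ** np.arange(len(codes) - 1, -1, -1)))


@dataclass(frozen=True)
class KmerProfile:
    """Occurrence counts of all 4^k k-mers of one sequence."""

    counts: np.ndarray
    total: int
    seq_length: int
    k: int

    def __post_init__(self) -> None:
        if self.counts.shape != (4**self.k,):
            raise InvalidParameterError(
                f"profile for k={self.k} must have 4^k={4**self.k} components, "
                f"got {self.counts.shape}"
            )
        if int(self.counts.sum()) != self.total:
            raise InvalidParameterError("total must equal the sum of counts")


@dataclass(frozen=True)
class FeatureVector:
    """A normalized k-mer feature vector of dimension 4^k."""

    values: np.ndarray
    normalization: str
    k: int


@dataclass(frozen=True)
class CorpusTermStats:
    """Per-k-mer total occurrence counts over a reference corpus."""

    term_totals: np.ndarray
    k: int


@dataclass
class FeaturizeResult:
    """Outcome of featurizing a batch: vectors, the indices of the inputs
    that produced them, and (index, reason) reports for skipped inputs."""

    vectors: list
    indices: list
    skipped: list = field(default_factory=list)


def count_kmers(sequence: str, k: int) -> KmerProfile:
    """Count every overlapping k-mer window made solely of {a,c,g,t}.

    Windows containing any other character contribute nothing;
    ``seq_length`` counts only unambiguous characters.
    """
    if k < 1:
        raise InvalidParameterError(f"k must be >= 1, got {k}")
    codes = _encode(sequence)
    seq_length = int((codes >= 0).sum())
    dim = 4**k
    if len(codes) < k:
        return KmerProfile(np.zeros(dim, dtype=np.int64), 0, seq_length, k)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1)
    ranks = windows[valid] @ powers
    counts = np.bincount(ranks, minlength=dim).astype(np.int64)
    return KmerProfile(counts, int(valid.sum()), seq_length, k)


def tf_normalize(profile: KmerProfile) -> FeatureVector:
    """Scale a profile to unit Euclidean length (term-frequency features)."""
    if profile.total == 0:
        raise DegenerateInputError("cannot normalize an all-zero k-mer profile")
    counts = profile.counts.astype(np.float64)
    return FeatureVector(counts / np.linalg.norm(counts), "tf", profile.k)


def corpus_term_stats(profiles: Sequence[KmerProfile]) -> CorpusTermStats:
    """Sum k-mer counts over a reference corpus of profiles."""
    if len(profiles) == 0:
        raise InvalidParameterError("corpus statistics need at least one profile")
    k = profiles[0].k
    if any(p.k != k for p in profiles):
        raise InvalidParameterError("all profiles must share the same k")
    totals = np.zeros(4**k, dtype=np.int64)
    for p in profiles:
        totals += p.counts
    return CorpusTermStats(totals, k)


def tfti_normalize(profile: KmerProfile, stats: CorpusTermStats) -> FeatureVector:
    """Corpus-weighted features: component j is t_j^(seq) / (t_j * t^(seq))
    where t_j is the corpus-wide total of k-mer j and t^(seq) the sequence
    total; components with zero count stay exactly zero. The weighted
    vector is then scaled to unit length.
    """
    if profile.k != stats.k:
        raise InvalidParameterError("profile and corpus statistics disagree on k")
    if profile.total == 0:
        raise DegenerateInputError("cannot normalize an all-zero k-mer profile")
    observed = profile.counts > 0
    if (observed & (stats.term_totals == 0)).any():
        raise InconsistencyError(
            "profile contains k-mers absent from the corpus statistics"
        )
    values = np.zeros_like(profile.counts, dtype=np.float64)
    values[observed] = profile.counts[observed] / (
        stats.term_totals[observed].astype(np.float64) * profile.total
    )
    return FeatureVector(values / np.linalg.norm(values), "tfti", profile.k)


def oligo_features(
    sequence: str, k: int, unit_normalize: bool = False
) -> FeatureVector:
    """Over/under-representation contrast of each k-mer against an
    independent-nucleotide null model.

    With K_j the observed count and E_j = L * prod_l p(kappa_{j,l}) the
    expected count (p estimated from the single-nucleotide composition of
    the L unambiguous characters), the contrast is 0 if K_j = 0, K_j/E_j
    if K_j > E_j, and -E_j/K_j otherwise. The vector is not length-
    normalized by default.
    """
    if k < 1:
        raise InvalidParameterError(f"k must be >= 1, got {k}")
    profile = count_kmers(sequence, k)
    if profile.seq_length < k:
        raise DegenerateInputError(
            f"need at least k={k} unambiguous characters, "
            f"got {profile.seq_length}"
        )
    codes = _encode(sequence)
    p = np.bincount(codes[codes >= 0], minlength=4) / profile.seq_length
    digits = (np.arange(4**k)[:, None] // 4 ** np.arange(k - 1, -1, -1)) % 4
    expected = profile.seq_length * np.prod(p[digits], axis=1)
    observed = profile.counts.astype(np.float64)
    g = np.zeros(4**k, dtype=np.float64)
    present = observed > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        over = present & (observed > expected)
        under = present & ~over
        g[over] = observed[over] / expected[over]
        g[under] = -expected[under] / observed[under]
    if unit_normalize:
        norm = np.linalg.norm(g)
        if norm > 0:
            g = g / norm
    return FeatureVector(g, "oligo", k)


def featurize(
    sequences: Iterable[str],
    k: int,
    normalization: str,
    stats: Optional[CorpusTermStats] = None,
    oligo_unit_normalize: bool = False,
) -> FeaturizeResult:
    """Apply the selected normalization to each sequence.

    Sequences that fail the preconditions of their normalization (too
    short, all-ambiguous) are reported in ``skipped`` and do not abort
    the batch.
    """
    if normalization not in NORMALIZATIONS:
        raise InvalidParameterError(
            f"normalization must be one of {NORMALIZATIONS}, got {normalization!r}"
        )
    if normalization == "tfti" and stats is None:
        raise InvalidParameterError("tfti normalization requires corpus statistics")
    result = FeaturizeResult(vectors=[], indices=[])
    for i, seq in enumerate(sequences):
        try:
            if normalization == "oligo":
                vec = oligo_features(seq, k, unit_normalize=oligo_unit_normalize)
            else:
                profile = count_kmers(seq, k)
                if normalization == "tf":
                    vec = tf_normalize(profile)
                else:
                    vec = tfti_normalize(profile, stats)
        except DegenerateInputError as exc:
            result.skipped.append((i, str(exc)))
            continue
        result.vectors.append(vec)
        result.indices.append(i)
    return result
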