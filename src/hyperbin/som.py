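"""Online training of the hierarchical hyperbolic SOM and beam-search
best-matching-unit lookup.

Training follows the classical online SOM rule — present one feature
vector, find its best matching unit (BMU), pull every prototype toward
the vector with a strength given by the neighborhood kernel evaluated on
the grid distance to the BMU — except that the grid lives in the
Poincaré disk, so the kernel argument is the Möbius-invariant delta and
the kernel itself is exp(-arctan(delta)/sigma^2).

Because the grid grows exponentially with the ring count, the BMU is not
found by exhaustive search but by a beam search down the hierarchy: start
at the center, evaluate its children, keep the w best, evaluate their
children, and so on; the winner on the last ring approximates the global
BMU while touching at most s + w*(s-3)*(r-1) prototypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple, Union

import numpy as np

from .errors import InvalidParameterError
from .kmers import FeatureVector
from .lattice import Lattice, neighborhood_kernel

__all__ = ["TrainingConfig", "init_prototypes", "beam_search_bmu", "train"]


@dataclass
class TrainingConfig:
    """Hyperparameters of one training run.

    epsilon and sigma decay exponentially from their start to end values
    over the total number of presentation steps (epochs * n_samples).
    ``neighborhood_modifier`` scales sigma uniformly; ``kernel_cutoff``
    skips prototype updates whose kernel strength falls below it.
    """

    epochs: int = 3
    epsilon_start: float = 0.5
    epsilon_end: float = 0.01
    sigma_start: float = 1.0
    sigma_end: float = 0.1
    neighborhood_modifier: float = 1.0
    beam_width: int = 1
    seed: int = 0
    kernel_cutoff: float = 1e-3
    kernel_form: str = "arctan"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise InvalidParameterError("epochs must be >= 1")
        if not (0 <= self.epsilon_start <= 1) or not (0 <= self.epsilon_end <= 1):
            raise InvalidParameterError("learning rates must lie in [0, 1]")
        if self.epsilon_end > self.epsilon_start:
            raise InvalidParameterError("epsilon_end must not exceed epsilon_start")
        if self.sigma_start <= 0 or self.sigma_end <= 0:
            raise InvalidParameterError("sigma values must be positive")
        if self.sigma_end > self.sigma_start:
            raise InvalidParameterError("sigma_end must not exceed sigma_start")
        if self.neighborhood_modifier <= 0:
            raise InvalidParameterError("neighborhood_modifier must be positive")
        if self.beam_width < 1:
            raise InvalidParameterError("beam_width must be >= 1")
        if not (0 <= self.kernel_cutoff < 1):
            raise InvalidParameterError("kernel_cutoff must lie in [0, 1)")


def _as_matrix(data: Sequence[Union[FeatureVector, np.ndarray]]) -> np.ndarray:
    if len(data) == 0:
        raise InvalidParameterError("training data must be non-empty")
    rows = [d.values if isinstance(d, FeatureVector) else np.asarray(d) for d in data]
    dim = rows[0].shape[0]
    if any(r.shape != (dim,) for r in rows):
        raise InvalidParameterError("all feature vectors must share one dimension")
    return np.array(rows, dtype=np.float64)


def init_prototypes(
    lattice: Lattice,
    data: Sequence[Union[FeatureVector, np.ndarray]],
    seed: int,
) -> np.ndarray:
    """Seeded initialization: the center prototype is the componentwise
    data mean; each child copies its parent plus a perturbation of scale
    1e-3 of the per-component data standard deviation (so identical data
    yields identical prototypes everywhere)."""
    X = _as_matrix(data)
    rng = np.random.default_rng(seed)
    scale = 1e-3 * X.std(axis=0)
    protos = np.empty((lattice.n_nodes, X.shape[1]), dtype=np.float64)
    protos[0] = X.mean(axis=0)
    for node in lattice.nodes[1:]:  # breadth-first: parents precede children
        protos[node.index] = protos[node.parent] + scale * rng.standard_normal(
            X.shape[1]
        )
    return protos


def _beam_descend(
    x: np.ndarray,
    prototypes: np.ndarray,
    lattice: Lattice,
    w: int,
) -> Tuple[int, float, int]:
    """Greedy ring-by-ring descent; returns (best last-ring node,
    its distance, number of prototype evaluations)."""
    evaluated = 0
    beam = [0]
    best_idx, best_dist = 0, float("inf")
    for _ring in range(1, lattice.r + 1):
        candidates: List[int] = []
        for b in beam:
            candidates.extend(lattice.nodes[b].children)
        if not candidates:
            break
        cand = np.array(candidates)
        cand.sort()  # ascending index so stable sort breaks ties low
        dists = np.linalg.norm(prototypes[cand] - x, axis=1)
        evaluated += len(cand)
        order = np.argsort(dists, kind="stable")[:w]
        beam = cand[order].tolist()
        best_idx, best_dist = beam[0], float(dists[order[0]])
    return best_idx, best_dist, evaluated


def beam_search_bmu(
    x: Union[FeatureVector, np.ndarray],
    prototypes: np.ndarray,
    lattice: Lattice,
    w: int = 1,
    return_evaluations: bool = False,
):
    """Approximate the best matching unit of ``x`` by beam search.

    Keeps the ``w`` closest candidates among the children of the current
    beam at every ring; the winner determined on the last ring is
    returned together with its Euclidean distance. Ties go to the lowest
    node index.
    """
    if w < 1:
        raise InvalidParameterError(f"beam width must be >= 1, got {w}")
    vec = x.values if isinstance(x, FeatureVector) else np.asarray(x, dtype=np.float64)
    if vec.shape[0] != prototypes.shape[1]:
        raise InvalidParameterError(
            f"feature dimension {vec.shape[0]} does not match prototypes "
            f"({prototypes.shape[1]})"
        )
    idx, dist, evals = _beam_descend(vec, prototypes, lattice, w)
    if return_evaluations:
        return idx, dist, evals
    return idx, dist


def train(
    data: Sequence[Union[FeatureVector, np.ndarray]],
    lattice: Lattice,
    config: TrainingConfig,
) -> np.ndarray:
    """Train prototypes with the online rule
    u_i <- u_i + eps(t) * h(delta(z_bmu, z_i), sigma(t)) * (x - u_i).

    Each epoch presents a seeded shuffle of the data; eps and sigma decay
    exponentially over the total step count. Deterministic given the
    config seed. Returns the prototype matrix (n_nodes x dim).
    """
    X = _as_matrix(data)
    seeds = np.random.SeedSequence(config.seed).spawn(2)
    protos = init_prototypes(lattice, X, int(seeds[0].generate_state(1)[0] % 2**31))
    rng = np.random.default_rng(seeds[1])
    n = X.shape[0]
    total = config.epochs * n
    positions = lattice.positions
    eps_ratio = (
        config.epsilon_end / config.epsilon_start
        if config.epsilon_start > 0
        else 0.0
    )
    sig_ratio = config.sigma_end / config.sigma_start
    denom = max(total - 1, 1)
    t = 0
    for _epoch in range(config.epochs):
        for i in rng.permutation(n):
            x = X[i]
            bmu, _dist = _beam_descend(x, protos, lattice, config.beam_width)[:2]
            frac = t / denom
            eps = config.epsilon_start * eps_ratio**frac
            sigma = config.sigma_start * sig_ratio**frac
            zb = positions[bmu]
            delta = np.abs((zb - positions) / (1 - np.conj(zb) * positions))
            h = neighborhood_kernel(
                np.clip(delta, 0.0, np.nextafter(1.0, 0.0)),
                sigma * config.neighborhood_modifier,
                form=config.kernel_form,
            )
            mask = h >= config.kernel_cutoff
            if mask.all():
                protos += (eps * h)[:, None] * (x - protos)
            else:
                sel = np.nonzero(mask)[0]
                protos[sel] += (eps * h[sel])[:, None] * (x - protos[sel])
            t += 1
    return protos


def quantization_error(
    data: Sequence[Union[FeatureVector, np.ndarray]],
    prototypes: np.ndarray,
    lattice: Lattice,
    w: int = 1,
) -> float:
    """Mean beam-search BMU distance of the data — the SOM's fit measure."""
    X = _as_matrix(data)
    return float(
        np.mean([_beam_descend(x, prototypes, lattice, w)[1] for x in X])
    )
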