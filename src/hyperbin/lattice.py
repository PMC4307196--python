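"""Hierarchical lattice construction in the Poincaré disk.

The grid of the hierarchical hyperbolic SOM lives in the open unit disk,
the Poincaré model of the hyperbolic plane, whose isometries are Möbius
transformations. A central node spawns a ring of s children at equal
hyperbolic distance d; each of those recursively spawns s-3 children of
its own (its parent and two ring siblings use up the remaining neighbor
slots), so ring m holds s*(s-3)^(m-1) nodes and the grid grows
exponentially with the ring count r.

The edge length d is that of the equilateral {3,s} tessellation,
cosh(d) = cos(2*pi/s) / (1 - cos(2*pi/s)), which requires s >= 7 — for
smaller s the formula degenerates and no hyperbolic tessellation exists.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "LatticeNode",
    "Lattice",
    "mobius_translate",
    "poincare_delta",
    "neighborhood_kernel",
    "build_lattice",
]


# child fans are contracted about the anti-parent direction so that the
# outermost children of adjacent parents (the vertices a true tessellation
# would share) get distinct positions; 1.0 would reproduce the exact
# tessellation directions and collide them
_FAN_CONTRACTION = 0.95


def _check_disk(z: complex, name: str) -> None:
    if abs(z) >= 1.0:
        raise InvalidParameterError(
            f"{name} must lie strictly inside the unit disk, got |{name}|={abs(z)}"
        )


def mobius_translate(z: complex, a: complex) -> complex:
    """Möbius translation of the disk sending 0 to ``a``:
    z -> (z + a) / (1 + conj(a) * z)."""
    _check_disk(z, "z")
    _check_disk(a, "a")
    return (z + a) / (1 + a.conjugate() * z)


def poincare_delta(z1: complex, z2: complex) -> float:
    """Möbius-invariant pseudo-distance |(z1 - z2) / (1 - conj(z1)*z2)|,
    in [0, 1) for points inside the disk."""
    _check_disk(z1, "z1")
    _check_disk(z2, "z2")
    return abs((z1 - z2) / (1 - z1.conjugate() * z2))


def neighborhood_kernel(delta, sigma: float, form: str = "arctan"):
    """Neighborhood strength exp(-arctan(delta) / sigma^2), equal to 1 at
    delta = 0 and strictly decreasing in delta.

    ``form='artanh'`` substitutes the inverse hyperbolic tangent (the
    monotone transform the true hyperbolic distance would use); the
    arctan form is the default.
    """
    if sigma <= 0:
        raise InvalidParameterError(f"sigma must be positive, got {sigma}")
    if form not in ("arctan", "artanh"):
        raise InvalidParameterError(f"unknown kernel form {form!r}")
    d = np.asarray(delta, dtype=np.float64)
    if (d < 0).any() or (d >= 1).any():
        raise InvalidParameterError("delta must lie in [0, 1)")
    warped = np.arctan(d) if form == "arctan" else np.arctanh(d)
    out = np.exp(-warped / sigma**2)
    return float(out) if np.isscalar(delta) or out.ndim == 0 else out


@dataclass
class LatticeNode:
    index: int
    ring: int
    position: complex
    parent: Optional[int]
    children: List[int] = field(default_factory=list)
    ring_siblings: Optional[Tuple[int, int]] = None  # (predecessor, successor)


@dataclass
class Lattice:
    """The full grid: nodes in breadth-first order (center first), the
    spread factor s, ring count r, and the hyperbolic edge length."""

    s: int
    r: int
    nodes: List[LatticeNode]
    edge_length: float

    def __post_init__(self) -> None:
        self._positions = np.array([n.position for n in self.nodes])
        self._rings = np.array([n.ring for n in self.nodes])

    @property
    def positions(self) -> np.ndarray:
        """Complex array of node positions, indexed by node index."""
        return self._positions

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def ring_indices(self, m: int) -> np.ndarray:
        return np.nonzero(self._rings == m)[0]

    @property
    def last_ring(self) -> np.ndarray:
        return self.ring_indices(self.r)


def expected_node_count(s: int, r: int) -> int:
    """1 + s * sum_{m=0}^{r-1} (s-3)^m."""
    return 1 + s * sum((s - 3) ** m for m in range(r))


def build_lattice(s: int, r: int) -> Lattice:
    """Construct the hierarchical grid with spread factor ``s`` and ``r``
    rings.

    The center sits at 0 with s children at Poincaré radius tanh(d/2),
    angles 2*pi*m/s. Every further node is mapped to the origin by a
    Möbius translation, the direction theta_p of its parent's image is
    noted, s-3 children are placed at radius tanh(d/2) in the fan of
    directions theta_p + 2*pi*m/s (m = 2..s-2), and translated back.
    Because the grid is a pure tree (children belong to one parent, not
    shared between parents as in the true {3,s} tessellation), the exact
    tessellation directions would make the outermost children of
    adjacent parents coincide; the fan is therefore contracted by a
    fixed factor 0.95 about the anti-parent direction, which keeps all
    node positions distinct while leaving the combinatorics and every
    parent-child distance unchanged. Ring siblings link consecutive
    same-ring nodes circularly in angular order.
    """
    if s < 7:
        raise InvalidParameterError(
            f"spread factor must be >= 7 for a hyperbolic tessellation, got {s}"
        )
    if r < 1:
        raise InvalidParameterError(f"ring count must be >= 1, got {r}")
    c = math.cos(2 * math.pi / s)
    edge = math.acosh(c / (1 - c))
    rho = math.tanh(edge / 2)

    nodes: List[LatticeNode] = [LatticeNode(0, 0, 0j, None)]
    for m in range(s):
        child = LatticeNode(len(nodes), 1, rho * cmath.exp(2j * math.pi * m / s), 0)
        nodes[0].children.append(child.index)
        nodes.append(child)

    frontier = list(range(1, s + 1))
    for ring in range(2, r + 1):
        next_frontier: List[int] = []
        for idx in frontier:
            node = nodes[idx]
            z = node.position
            # parent direction in the frame where this node sits at the origin
            zp = nodes[node.parent].position
            parent_local = (zp - z) / (1 - z.conjugate() * zp)
            theta_p = cmath.phase(parent_local)
            for m in range(2, s - 1):
                angle = theta_p + math.pi + _FAN_CONTRACTION * (
                    2 * math.pi * m / s - math.pi
                )
                local = rho * cmath.exp(1j * angle)
                child = LatticeNode(
                    len(nodes), ring, mobius_translate(local, z), idx
                )
                node.children.append(child.index)
                nodes.append(child)
                next_frontier.append(child.index)
        frontier = next_frontier

    for ring in range(1, r + 1):
        members = [n.index for n in nodes if n.ring == ring]
        members.sort(key=lambda i: cmath.phase(nodes[i].position))
        n = len(members)
        for pos, idx in enumerate(members):
            nodes[idx].ring_siblings = (
                members[(pos - 1) % n],
                members[(pos + 1) % n],
            )

    lattice = Lattice(s=s, r=r, nodes=nodes, edge_length=edge)
    assert lattice.n_nodes == expected_node_count(s, r)
    return lattice
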