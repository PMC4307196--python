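"""Build the hierarchical grid in the Poincaré disk and inspect its
geometry.

With spread factor s and r rings, the grid holds 1 + s * sum (s-3)^m
nodes; every parent-child pair sits at the same hyperbolic edge length
d with cosh(d) = cos(2*pi/s) / (1 - cos(2*pi/s)). The neighborhood
kernel exp(-arctan(delta)/sigma^2) turns grid distance into update
strength during training.
"""

import hyperbin as hb

for r in (1, 2, 5):
    lat = hb.build_lattice(s=8, r=r)
    print(f"s=8, r={r}: {lat.n_nodes} nodes "
          f"(last ring holds {len(lat.last_ring)})")

lat = hb.build_lattice(8, 2)
print(f"hyperbolic edge length d = {lat.edge_length:.5f}; "
      f"ring-1 Poincaré radius tanh(d/2) = {abs(lat.nodes[1].position):.5f}")

child = lat.nodes[lat.nodes[1].children[0]]
delta = hb.poincare_delta(lat.nodes[1].position, child.position)
print(f"parent-child delta = {delta:.5f} (equal for every edge, "
      "by Möbius invariance)")

for sigma in (1.0, 0.5, 0.2):
    h = hb.neighborhood_kernel(delta, sigma)
    print(f"kernel at that delta, sigma={sigma}: {h:.4f}")
print("(shrinking sigma narrows the neighborhood, localizing updates)")
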