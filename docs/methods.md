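# Methods

This note records the model, its assumptions, the defaults and the
design choices behind `hyperbin`, in the package's own words. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Feature model

A DNA sequence is reduced to the occurrence counts of all 4^k k-mers
(forward strand only; no reverse-complement canonicalization). Counting
is case-insensitive; any character outside {a,c,g,t} (N or other IUPAC
ambiguity codes) invalidates every window containing it and is excluded
from the sequence length and from the single-nucleotide frequencies
used by the oligo contrast. This exclusion rule avoids inventing
pseudo-counts for ambiguous positions. Index order is lexicographic
with a=0 < c=1 < g=2 < t=3, leftmost symbol most significant.

Three normalizations:

- **tf**: counts scaled to unit Euclidean length. Unit scaling removes
  read-length effects and is the shipped default.
- **tfti**: component j is t_j^(S) / (t_j · t^(S)) with t_j the total
  occurrence of k-mer j over the reference corpus; components with zero
  count stay exactly zero; the weighted vector is then scaled to unit
  length to damp the dominance of globally frequent k-mers. At query
  time the corpus statistics frozen into the model at training time are
  used — query reads never update them, since the statistics are
  defined over the reference corpus only.
- **oligo**: the three-case contrast g of observed count K_j against
  E_j = L·∏ p(nucleotide), giving values in {0} ∪ (1, ∞) ∪ (−∞, −1]
  (a tie K_j = E_j falls in the third case, yielding −1). Oligo vectors
  are not length-normalized by default — the contrast scale itself is
  the signal — but a switch exists.

Degenerate inputs (no countable k-mer, or fewer than k unambiguous
characters for oligo) raise a dedicated error; the batch `featurize`
entry point reports and skips them instead of aborting.

Default k = 4 (256 dimensions), configurable 2–8. Larger k can buy
accuracy at a steep cost in dimensionality and speed.

## Grid geometry

The grid is a tree embedded in the Poincaré disk. The hyperbolic edge
length is that of the equilateral {3,s} tessellation,
cosh d = cos(2π/s)/(1 − cos(2π/s)), which requires s ≥ 7. The center
spawns s children (ring 1); every further node spawns s − 3, so that an
interior node has exactly s grid neighbors: one parent, two ring
siblings, s − 3 children. Ring m therefore holds s·(s−3)^(m−1) nodes.

Children are placed by translating the parent to the origin (a Möbius
isometry), fanning the s − 3 children opposite the grandparent
direction at Poincaré radius tanh(d/2), and translating back. The exact
tessellation directions θ_p + 2πm/s (m = 2…s−2) would make the
outermost children of adjacent parents coincide — those are the
vertices a true tessellation shares between cells, while this grid is a
pure tree with exclusive children. The fan is therefore contracted by a
fixed factor 0.95 about the anti-parent direction, which separates all
positions (minimum intra-ring δ ≈ 0.013 for s ∈ {7,8,9}) while leaving
the combinatorics and every parent–child distance untouched. The
geometry only enters the model through the neighborhood kernel, so this
choice is cosmetic for classification behavior.

The neighborhood kernel is exp(−arctan(δ)/σ²) with δ the
Möbius-invariant distance |(z_i − z_j)/(1 − z̄_i z_j)|. The arctan form
is the default; an artanh variant (the monotone transform the true
hyperbolic metric distance would use) is exposed but non-default. Both
are monotone in δ, so they order neighbors identically and differ only
in effective neighborhood width.

## Training

Classical online SOM learning: per presented vector, find the BMU, pull
every node toward the vector with strength ε(t)·h. Defaults: 3 epochs,
ε decaying exponentially 0.5 → 0.01, σ decaying 1.0 → 0.1 over the
total step count, neighborhood modifier 1, kernel cutoff 1e−3 (nodes
with weaker kernel skip the update — purely a compute saver given the
exponential tail). These schedules are conventional SOM choices; the
method is robust to them, and all are configurable. Training uses the
whole lattice from the start rather than growing it ring by ring — the
simpler reading, since beam search already routes updates top-down.

The BMU is approximated by beam search: evaluate the center's s
children, keep the w closest (default w = 1), evaluate their children,
and so on; the winner on the last ring is the BMU. This bounds
evaluations at s + w·(s−3)·(r−1) per query — for the default
architecture, 28 instead of 6,249 distance computations. The winner is
taken from the last ring (an option returns the best node seen along
the whole descent, non-default). Distances are Euclidean in feature
space throughout. Ties break to the lowest node index everywhere, which
makes results exactly reproducible.

Initialization (not part of the original formulation, so chosen here):
center prototype = data mean; each child = its parent plus seeded
Gaussian noise at 1e−3 of the per-component data standard deviation.
The hierarchy thus starts as a gently perturbed copy of the mean and
differentiates during training. Deterministic given the seed; training
is bitwise reproducible for a fixed config, seed and data.

## Labeling and classification

The Voronoi cell of a node is the set of training vectors whose BMU it
is (beam search, so cells live on the last ring). Labeling is per rank
(superkingdom, phylum, class, order), with a rejection class R:

- majority voting: the taxon with the most cell members; ties go to the
  lexicographically smallest taxon; empty cells get R.
- purity voting: the majority taxon only if its fraction of the full
  cell strictly exceeds α (default 0.8), else R. The threshold is
  compared against the fraction Ψ/|V(u_i)| — the only reading under
  which a threshold of 0.8 is meaningful. Cell members whose lineage
  does not reach the rank do not vote; a cell with no voters at a rank
  is rejected there.

Classification rules: `nn` returns the BMU's label; `thresh`
additionally rejects when the BMU distance is ≥ β (no universal default
exists for β — it is distance-scale dependent — so it must be given
explicitly or estimated as an empirical quantile, default 0.95, of
training BMU distances); `nbrs` lets the BMU's two ring siblings
override it when both carry the same label and
d(x,u_{j+1}) + d(x,u_{j−1}) < 3·d(x,u_j) (the center, having no ring
siblings, falls back to `nn`). One model carries label tables for all
ranks; rules are applied per rank and rejection propagates downward so
an output lineage never has gaps. The shipped default configuration is
purity voting at α = 0.8 with the `nn` rule, tf features, k = 4, s = 8,
r = 5.

## Synthetic communities

The generator emulates the one property the method depends on: taxa
with distinct, hierarchically structured k-mer composition. Each taxon
is an order-1 nucleotide Markov chain; order-1 suffices to induce
signal at every k ≥ 2 while keeping one interpretable dial. Phylum base
matrices mix a shared global matrix with independent Dirichlet draws at
weight w = separation/(1+separation); order matrices perturb their
phylum base at the much smaller weight w/(2(1+separation)). At
separation 0 all taxa are identical (no recoverable signal — held-out
accuracy must match the class prior); at the default separation 5.0
phyla are well separated while sibling orders remain close. Reads start
at the chain's stationary distribution, so long-read dinucleotide
frequencies converge to π_a·T[a,b]. Read ids are opaque to prevent
label leakage into tests.

Defaults: 4 phyla × 3 orders × 420 reads of 1,000 nt (≈ 5,000 reads).
What the generator does **not** emulate: sequencing error, read-length
distributions, repeats, GC skew, shared genes/horizontal transfer, and
realistic between-taxon distances. Passing tests therefore demonstrate
that the machinery recovers hierarchical compositional structure when
present, not field accuracy on real metagenomes.

## Persistence

A model serializes to a single HDF5 file: architecture and
hyperparameters as attributes, prototypes as float32 with gzip-9 +
byte-shuffle compression, label tables as per-rank taxon dictionaries
plus integer codes. The lattice is a pure function of (s, r) and is
rebuilt on load. Dataset timestamps are disabled, so identical inputs
and seed produce byte-identical files. The float32 round-trip preserves
label assignments exactly and distances to ~1e−7 relative; the default
architecture serializes to roughly 2 MB, comfortably under the 5 MB
design budget.

## Problem sizes used in the checks

The test suite and acceptance script run at desk scale by choice:
feature checks on ~1,000 random sequences; beam-search oracle checks on
s ∈ {7,8}, r ∈ {2,3} grids with 100 queries; recovery runs on ~2,000
training / ~500 held-out reads with r = 3; the compactness run at the
full default architecture on the ≈5,000-read default community.

## Known limitations

- Assignments always land on last-ring nodes (the beam search's
  definition of BMU), so interior nodes act only as routing and
  neighborhood structure, not as labels.
- Purity voting at high α with closely related taxa rejects
  aggressively at low ranks; this is by construction (rejection is the
  safe answer for unspecific composition), not a defect.
- Forward-strand counting means a model must be trained and queried on
  consistently oriented sequences, or on data where strand is random
  for both reference and query.
- The `thresh` rule's β is scale-dependent and must be calibrated per
  model.
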