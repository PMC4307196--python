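# hyperbin

Rapid taxonomic binning of DNA reads and scaffolds from k-mer
composition, using a hierarchical hyperbolic self-organizing map
(H²SOM) as a compact descriptive model.

## The problem

Metagenomic sequencing returns reads from an unknown mixture of
organisms, and a first question is always *what is in the sample*.
Alignment-based classifiers answer accurately but slowly; composition
methods exploit the fact that k-mer frequency profiles are distinctive
enough to separate taxa down to roughly the rank of order. `hyperbin`
is for users who want an immediate compositional overview of a sample —
a per-read assignment down to order plus a hierarchical composition
summary — from a model small enough (a few MB) to ship, load and query
in seconds.

## The method

Each sequence S is represented by the counts t_j of all 4^k k-mers
(default k = 4, so 256 dimensions). Three normalizations are available:

- **tf** — x = K/‖K‖, the count vector scaled to unit length (default);
- **tfti** — component j is t_j^(S) / (t_j · t^(S)), weighting each
  count by the inverse of that k-mer's total abundance t_j over the
  reference corpus, then scaled to unit length;
- **oligo** — the contrast g(κ_j) of observed count K_j against its
  expectation E_j = |S|·∏_l p(κ_j,l) under an independent
  single-nucleotide null: g = 0 if K_j = 0, K_j/E_j if K_j > E_j, and
  −E_j/K_j otherwise.

The model is a self-organizing map whose grid lives in the Poincaré
disk: a central node spawns s children at hyperbolic edge length d
(cosh d = cos(2π/s)/(1 − cos(2π/s))), and each node recursively spawns
s − 3 children via Möbius translations, giving 1 + s·Σ_{m<r}(s−3)^m
nodes over r rings (defaults s = 8, r = 5: 6,249 nodes). Training is
the classical online rule u_i ← u_i + ε(t)·h·(x − u_i) with the
hyperbolic neighborhood h(i,i′) = exp(−arctan(δ(z_i,z_i′))/σ²(t)),
where δ is the Möbius-invariant distance between grid coordinates.
Because the grid grows exponentially, the best matching unit is found
by a **beam search** descending the hierarchy (at most
s + w·(s−3)·(r−1) distance evaluations instead of thousands), which is
what makes both training and classification fast.

After training, nodes are labeled per rank (superkingdom → order) from
the Voronoi cells of the labeled training data: **majority voting**, or
**purity voting** which keeps the majority taxon only when its cell
fraction strictly exceeds α (default 0.8) and otherwise assigns the
rejection class R ("unspecific"). Queries are classified by
nearest-prototype lookup (`nn`, default), with optional distance
thresholding (`thresh`, reject beyond β) or neighborhood smoothing
(`nbrs`, the BMU's two ring siblings override it when they agree and
lie comparatively close).

## Worked example

`examples/03_train_and_classify.py` simulates a 12-taxon community
(4 phyla × 3 orders, order-1 Markov chains per taxon, 1,200 training
reads of 1 kb), trains an s=8, r=3 model with tf features, and
classifies 300 held-out reads:

```
training community: 1200 reads of 1000 nt from 12 taxa
model: 249 nodes, 4 phylum-labeled (purity voting, alpha=0.8)
held-out reads: 300; rejected at phylum: 0 (0.0%)
phylum accuracy among assigned: 1.000
serialized model: 0.19 MB
Krona composition lines (count, then the taxon path):
  75	Bacteria	Phylum_00
  75	Bacteria	Phylum_01
  75	Bacteria	Phylum_02
  75	Bacteria	Phylum_03
```

Every held-out read lands on a node whose purity-voted phylum label
matches the phylum it was sampled from, and the Krona export recovers
the uniform 4-phylum composition (75 reads each). The other examples
walk through the feature normalizations (`01`), the disk geometry
(`02`), and the same pipeline from the shell via the `hyperbin` CLI
(`04`).

The CLI mirrors the library: `hyperbin simulate`, `hyperbin
build-model`, `hyperbin classify` (writes an assignments TSV and a
Krona-importable composition text), and `hyperbin inspect-model`.

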