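# hoclust — higher-order (graphlet-induced) community detection

Conventional community detection in protein–protein interaction (PPI)
networks groups nodes by edge density alone, ignoring the richer local
connectivity patterns — triangles, 4-cycles, near-cliques — that disease
genes are known to concentrate in.  `hoclust` clusters a network *per
graphlet*: for a chosen small induced subgraph pattern G_k it removes
every edge that participates in no induced occurrence of G_k, restricts
a random walker to the remaining edges, and runs Markov clustering (MCL)
on the resulting transition matrix.  Each graphlet therefore yields its
own partition, revealing modules held together by that specific pattern
that the plain edge-based (G0) clustering misses.

## The method in brief

**Graphlets and edge orbits.**  Graphlets are the connected, induced,
non-isomorphic graphs on 2–5 nodes: G0 (the edge) through G29 (K5), 30
in total.  Each graphlet's edges split into *edge orbits* — automorphism
classes; two edges share an orbit iff some symmetry of the graphlet maps
one to the other.  Sizes 3–5 carry 68 edge orbits (global ids 0–67; the
3- and 4-node graphlets G1–G8 occupy ids 0–11, e.g. the 4-path G3 has
the orbit set O₃ = {2, 3}: outer edges vs middle edge).

**Graphlet-induced transition matrix.**  For a network with adjacency
*A*, per-edge orbit counts (computed by induced-subgraph enumeration)
define the graphlet-specific adjacency

    a_ij^(k) = a_ij  if edge (i,j) has at least one orbit in O_k,  else 0

and the row-stochastic transition matrix p_ij^(k) = a_ij^(k) / Σ_j a_ij^(k),
with p_ii^(k) = 1 for nodes left isolated.  G0 reproduces the original
network, so the G0 clustering is the classic MCL baseline.

**Clustering and post-processing.**  MCL alternates expansion (matrix
squaring) and inflation (elementwise power + renormalisation) until
convergence; the inflation exponent tunes granularity.  Within each raw
cluster only the largest connected component of the induced network is
kept, and clusters below 3 nodes are dropped.  Graphlets whose induced
matrix keeps ≥ 95% of the original edges are flagged *redundant* —
clustering them would just repeat the baseline.

**Evaluation.**  Clusterings are compared with the Adjusted Rand Index
(restricted to clusters of size ≥ 3) and per-cluster transitivity, and
scored against gene-set collections (GMT) with exact hypergeometric
upper-tail p-values under Benjamini–Hochberg control, summarised as gene
set / module coverage and percentages.

## Worked example

Simulate a 12-node network of two triangle-tiled communities joined by
sparse bridge edges that sit in no triangle, then cluster by the
triangle graphlet G2 and by the edge baseline G0:

```sh
hoclust --seed 7 simulate -o net.tsv --truth truth.tsv --gmt sets.gmt
hoclust cluster -i net.tsv -k 2 --inflation 2 -o g2.tsv
#   clusters=2  largest=6
hoclust compare -a g2.tsv -b truth.tsv
#   ARI=1.000000
hoclust enrich -c g2.tsv -g sets.gmt -i net.tsv -o enr.tsv
#   gene_set_coverage=2  gene_set_percentage=1.0000  module_coverage=2  module_percentage=1.0000
```

The G2-induced network drops exactly the bridge edges (they are in no
triangle), so MCL at inflation 2 returns the two planted communities:
two clusters, largest of size 6, in perfect agreement with the planted
truth (ARI = 1).  Both planted gene sets are significantly enriched in
their matching module after BH correction — e.g. the first module
overlaps its 6-gene set completely, hypergeometric p = 1.08e-3, BH-adjusted
p = 2.16e-3 < 0.05 — hence all four coverage figures are maximal.
`hoclust nonredundant -i net.tsv` lists which of the 30 graphlets
survive the redundancy filter on this network, and `hoclust sweep`
tabulates cluster counts across an inflation grid.

The same operations are available as a library
(`hoclust.cluster_graphlet`, `hoclust.enrichment_table`, ...), which the
CLI wraps thinly.

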