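# Methods

This note records the models, conventions and numerical choices behind
`hoclust`, and what the synthetic benchmarks do and do not establish.

## Graphlet catalog

The catalog holds the 30 connected, induced, non-isomorphic graphs on
2–5 nodes (1, 2, 6 and 21 of sizes 2, 3, 4, 5).  It is built at run time
by exhaustive enumeration: all edge subsets on n labelled nodes are
tested for connectivity and deduplicated by a lexicographically minimal
relabelling certificate (brute force over at most 5! = 120
permutations).  Automorphism groups, and from them the edge-orbit
partitions, are likewise found by exhaustive permutation testing —
trivially correct at this size, and cheap (the full catalog builds in
well under a second).

Ordering conventions:

* G0–G8 (sizes 2–4) follow the established numbering of the
  graphlet-counting literature — G0 edge, G1 3-path, G2 triangle,
  G3 4-path, G4 claw, G5 4-cycle, G6 paw, G7 diamond, G8 K4 — embedded
  as an explicit table and cross-checked against the enumeration at
  build time.
* The 21 graphlets on 5 nodes are ordered by (edge count, canonical
  certificate).  Published depictions of the 5-node series are not
  reproducible from first principles, and nothing downstream depends on
  the global numbering of 5-node orbits: edge induction uses only the
  *membership* of each graphlet's orbit set O_k.
* Global orbit ids are assigned consecutively from 0 in graphlet order,
  starting with G1; within a graphlet, orbits are ordered by their
  smallest canonical member edge.  This places the orbits of G1–G8 at
  ids 0–11 and gives the 4-path O₃ = {2, 3} (outer edges before the
  middle edge).

Sizes 3–5 carry 68 edge orbits in total (12 + 56).  The total is
verified in the test suite by an independent Burnside count (number of
orbits = average number of edges fixed by an automorphism).  G0's edge
carries no orbit number; the G0-induced network is the original network
by definition.

## Orbit counting

Per-edge orbit counts come from ESU-style enumeration of connected
induced subgraphs of sizes 3–5: each subgraph is visited exactly once,
classified against the catalog via its adjacency bitmask (memoised —
there are at most 2¹⁰ masks at size 5), and each of its edges increments
the orbit its position maps to under the classification witness.
Counting is purely topological; edge weights are carried through
induction untouched but never influence which edges participate in a
graphlet.  No combinatorial shortcuts or sampling are used; a warning
(not an error) is emitted when the maximum degree makes size-5
enumeration expensive.  The suite checks the counts against brute force
over all node subsets on random graphs of up to 12 nodes.

## Induction, redundancy, clique expansion

`induce_network` zeroes edges with no count in O_k, preserving weights
and the node set.  "< 95% similar" is operationalised as the fraction of
parent edges retained: the induced matrix differs from *A* only by
zeroed entries, so the edge-retention fraction *is* the matrix
similarity, identically for weighted and binarised matrices.  The
comparison is strict (`fraction < threshold` retains the graphlet), so a
graphlet dropping no edge is excluded even at threshold 1.0.  G0 is
always carried as the baseline.

The clique-expansion transform (the comparison approach in which any two
nodes sharing a graphlet occurrence become adjacent) is provided for
graphlets up to 4 nodes only; it densifies rather than sparsifies and is
not part of the main pipeline.

## Markov clustering

Row-stochastic orientation (p_ij = a_ij / Σ_j a_ij) is used throughout;
for the symmetric adjacencies handled here this is the transpose of the
classic column-stochastic formulation and yields the same partitions.
Defaults: expansion power 2, inflation 2.0, self-loop weight 1,
pruning threshold 1e-5, convergence tolerance 1e-8, at most 200
iterations.  All knobs are exposed on `MCLOptions`.

The self-loop is added to the *adjacency* diagonal before normalisation
(the standard MCL regularisation); `TransitionMatrix` carries the
pre-normalisation row masses so `run_mcl` can do this even though it
receives normalised probabilities.  Adding the loop to the normalised
matrix instead would give the diagonal up to half of each row's mass and
fragment clusters — a failure mode caught by the reference-equivalence
tests.  With the self-loop at 0, isolated nodes still receive p_ii = 1
(the walker stays put).

Convergence is declared when the maximum elementwise change after a full
expansion/inflation/prune/renormalise step falls below the tolerance;
non-convergence at the iteration cap warns and extracts from the current
matrix.  Extraction: rows with a non-vanishing diagonal are attractors;
attractors exchanging flow form systems; every other node joins the
system of its first attractor in node order.  This tie-break is the one
place where output can differ from component-based extraction, which
merges systems that share a multi-attractor node; the equivalence tests
against an independently coded dense MCL reconcile exactly this case and
nothing else.  Post-processing keeps, per raw cluster, only the largest
connected component of the induced network (ties broken by smallest
lexicographic node id — the choice of component is not canonical, and
largest-component retention is this package's convention), then drops
clusters under 3 nodes.

All tie-breaks (node order, component choice, attractor assignment) are
deterministic, so identical inputs and options give bitwise identical
clusterings.

## Evaluation layer

* **ARI** is computed by the standard pair-counting contingency formula
  (via scikit-learn) on the intersection of nodes covered by size-≥3
  clusters in both clusterings; a `pad` mode instead takes the union and
  treats uncovered nodes as singletons.  An empty intersection returns
  NaN with a warning.  `min_size=1` recovers the generic-partition ARI.
* **Transitivity** of a cluster is 3 × triangles / connected triples of
  the parent-network subgraph induced on it (0 when no triple exists).
* **Hypergeometric p-values** are exact integer-combinatorial tail sums
  P(X ≥ overlap); they are cross-checked against `scipy.stats.hypergeom`
  in the tests.  **BH adjustment** is the standard step-up procedure
  (statsmodels `fdr_bh`).
* **Enrichment** forms one BH family per clustering × collection (all
  module/set pairs).  The default gene universe is network nodes ∩
  collection genes, with a flag for all network nodes; modules and sets
  are restricted to the universe before sizing.  Significance is
  BH-adjusted p < α, default α = 0.05.
* **Coverage**: gene-set coverage counts sets with ≥ 1 significant
  module; module coverage counts modules significant for ≥ 1 set.  The
  gene-set percentage divides genes in significant sets by all genes in
  the collection's sets; the module percentage divides genes in
  significant modules by genes in all size-≥3 modules (size ≥ 3 is the
  assumed module-size window).

## Synthetic benchmarks

`generate_planted_graphlet_network` plants `n_communities` communities
of `community_size` nodes each.  The default pattern tiles a community
with the *cyclic* triangle tiling (ring plus next-nearest-neighbour
chords): every within-community edge lies in a triangle, and the
community is vertex-transitive and cohesive enough that MCL at inflation
2 returns it whole — the open-chain tiling, by contrast, is split in two
by MCL at the default community size.  A `clique` pattern gives complete
communities for dense-graphlet (K4/K5-style) experiments.

Cross-community bridges appear independently with probability
`p_between` per node pair (default 0.05), and optional background edges
with `p_background` (default 0); both are rejection-sampled so they
never close a triangle.  Consequently the G2-induced network provably
equals the disjoint union of the communities, which is what makes exact
recovery (ARI = 1) a legitimate expectation rather than a tuned outcome.
Defaults are 2 communities of 6 nodes — small enough that the whole
planted pipeline runs in milliseconds, large enough that every cluster
clears the size-3 floor.

`generate_matched_gene_sets` emits one gene set per community, swapping
a `noise` fraction of members for off-community nodes; at noise 0 the
module/set overlap is complete and enrichment is maximal, and the suite
checks that significance decays as noise rises.

What these fixtures do *not* emulate: interactome-scale degree
heterogeneity, weighted confidence scores, annotation incompleteness, or
overlap between gene sets.  Passing the recovery tests shows the
pipeline's machinery is correct end to end, not that real PPI networks
decompose this cleanly; on real data the inflation parameter must be
chosen by sweep (`sweep_inflation`), e.g. so the largest cluster stays
in the hundreds of nodes.

## Problem sizes used in the checks

The structural quantities reported by `scripts/acceptance.py` are exact
(full enumeration over all 30 graphlets).  Randomised checks use fixed
seeds: orbit-count oracle equivalence on 50 random graphs of 5–12 nodes;
MCL reference equivalence on 20 random graphs of 6–14 nodes; planted
recovery across 10 generator seeds; chance-level ARI over 100 seed pairs
of 300-node partitions.  These sizes keep the full suite under ten
seconds while still exercising every code path the larger-scale runs
would.

## Known limitations

* Orbit counting is exhaustive; size-5 counting on hub-heavy networks
  (degrees in the hundreds) becomes expensive.  ORCA-style combinatorial
  speedups are deliberately out of scope.
* MCL on highly symmetric inputs (e.g. large circulants) can converge to
  the identity, yielding only singletons and hence an empty clustering
  after the size filter; this is a property of the algorithm, not a bug.
* No gene-identifier mapping is performed; node ids and gene-set symbols
  must share a namespace.
* Directed graphlets and multi-graphlet consensus clusterings are not
  implemented.
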