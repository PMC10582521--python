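"""Graphlet-induced networks and their random-walk transition matrices.

The G_k-induced network keeps exactly the parent edges that participate
in at least one induced occurrence of graphlet G_k (weights untouched);
all other edges are zeroed.  A row-stochastic transition matrix is then
built by degree normalisation, with p_ii = 1 for nodes left without any
retained incident edge so that a random walker parked there stays put.

Redundancy filtering: a graphlet whose induced adjacency matrix keeps at
least 95% of the parent's edges is essentially the parent network and is
excluded; clustering it would duplicate the baseline G0 clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .catalog import GraphletCatalog
from .network import Network
from .orbits import EdgeOrbitCounts, edges_in_graphlet

__all__ = [
    "InducedNetwork",
    "TransitionMatrix",
    "induce_network",
    "build_transition_matrix",
    "retained_graphlets",
    "clique_expansion_network",
]

log = logging.getLogger(__name__)


@dataclass
class InducedNetwork:
    """The G_k-induced subnetwork of a parent network."""

    graphlet_id: int
    parent: Network
    retained_edges: dict[tuple[str, str], float]
    isolated_nodes: frozenset[str]

    @property
    def n_retained(self) -> int:
        return len(self.retained_edges)

    def retention_fraction(self) -> float:
        """Fraction of parent edges kept — the matrix-similarity score."""
        total = self.parent.n_edges
        return self.n_retained / total if total else 1.0

    def to_network(self) -> Network:
        net = Network(nodes=self.parent.nodes, weighted=self.parent.weighted)
        for (u, v), w in self.retained_edges.items():
            net.add_edge(u, v, w)
        return net


@dataclass
class TransitionMatrix:
    """Row-stochastic random-walk matrix over a fixed node order.

    ``degrees`` holds the pre-normalisation (weighted) row masses so that
    a later self-loop addition can be applied to the underlying adjacency
    rather than to the already-normalised probabilities.
    """

    nodes: list[str]
    matrix: sp.csr_matrix
    degrees: np.ndarray | None = None

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel()


def induce_network(
    network: Network,
    k: int,
    counts: EdgeOrbitCounts,
    catalog: GraphletCatalog,
) -> InducedNetwork:
    """Zero out every edge that sits in no induced occurrence of G_k."""
    kept = edges_in_graphlet(counts, k, catalog)
    retained = {e: network.weight(*e) for e in kept}
    covered = {u for e in kept for u in e}
    isolated = frozenset(u for u in network.nodes if u not in covered)
    return InducedNetwork(
        graphlet_id=k,
        parent=network,
        retained_edges=retained,
        isolated_nodes=isolated,
    )


def build_transition_matrix(
    induced: InducedNetwork,
    use_weights: bool = True,
    self_loop_weight: float = 0.0,
) -> TransitionMatrix:
    """Row-normalise the induced adjacency into transition probabilities.

    ``self_loop_weight`` is added to every diagonal entry *before*
    normalisation (standard MCL regularisation); with it at 0, isolated
    nodes still receive p_ii = 1.
    """
    if self_loop_weight < 0:
        raise ValueError("self_loop_weight must be >= 0")
    nodes = induced.parent.nodes
    idx = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    rows, cols, vals = [], [], []
    for (u, v), w in induced.retained_edges.items():
        if w < 0:
            raise ValueError(f"negative weight on edge ({u!r}, {v!r})")
        val = w if use_weights else 1.0
        rows += [idx[u], idx[v]]
        cols += [idx[v], idx[u]]
        vals += [val, val]
    a = sp.csr_matrix((np.asarray(vals, dtype=float), (rows, cols)), shape=(n, n))
    raw_deg = np.asarray(a.sum(axis=1)).ravel()
    if self_loop_weight > 0:
        a = a + self_loop_weight * sp.identity(n, format="csr")
    deg = np.asarray(a.sum(axis=1)).ravel()
    zero = deg == 0
    if zero.any():
        # walker with nowhere to go stays put: p_ii = 1
        a = a + sp.diags(zero.astype(float), format="csr")
        deg = deg + zero
    p = sp.diags(1.0 / deg) @ a
    return TransitionMatrix(nodes=list(nodes), matrix=sp.csr_matrix(p),
                            degrees=raw_deg + self_loop_weight)


def retained_graphlets(
    network: Network,
    counts: EdgeOrbitCounts,
    catalog: GraphletCatalog,
    threshold: float = 0.95,
) -> list[int]:
    """Graphlet ids whose induced matrix is < ``threshold`` similar to the parent.

    Similarity is the fraction of parent edges retained.  G_k with
    similarity >= threshold drops too few edges to yield a distinct
    clustering and is excluded; G0 is always carried as the baseline.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if network.n_edges == 0:
        raise ValueError("network has no edges")
    kept = [0]
    max_k = max(
        (g.id for g in catalog.graphlets if g.size <= counts.max_size),
        default=0,
    )
    for k in range(1, max_k + 1):
        frac = len(edges_in_graphlet(counts, k, catalog)) / network.n_edges
        log.debug("G%d edge retention fraction: %.4f", k, frac)
        if frac < threshold:
            kept.append(k)
    return kept


def clique_expansion_network(
    network: Network,
    k: int,
    counts: EdgeOrbitCounts,
    catalog: GraphletCatalog,
) -> Network:
    """Comparison transform: connect any two nodes sharing a G_k occurrence.

    Unlike edge induction this may *add* edges absent from the parent,
    producing a denser network; it is limited to graphlets on at most 4
    nodes, where the resulting density stays manageable.
    """
    from .orbits import enumerate_connected_subgraphs

    g = catalog.graphlet(k)
    if g.size > 4:
        raise ValueError("clique expansion is limited to graphlets up to 4 nodes")
    if k == 0:
        return Network.from_edges(
            [(u, v) for u, v, _ in network.edges()], nodes=network.nodes
        )
    out = Network(nodes=network.nodes)
    for subset in enumerate_connected_subgraphs(network, g.size):
        edges = [
            (u, v)
            for i, u in enumerate(subset)
            for v in subset[i + 1:]
            if network.has_edge(u, v)
        ]
        gid, _ = catalog.classify_subgraph(edges)
        if gid != k:
            continue
        for i, u in enumerate(subset):
            for v in subset[i + 1:]:
                if not out.has_edge(u, v):
                    out.add_edge(u, v)
    return out
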