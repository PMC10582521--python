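"""Undirected weighted network container with a stable node order.

Node identifiers are opaque strings (gene symbols, protein ids, ...).
The node order is the order of first appearance, which makes every
downstream matrix, cluster extraction and tie-break deterministic.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = ["Network"]


class Network:
    """Simple undirected graph: no self-loops, no parallel edges, weights > 0."""

    def __init__(self, nodes: Iterable[str] | None = None, weighted: bool = False):
        self._nodes: list[str] = []
        self._index: dict[str, int] = {}
        self._adj: dict[str, dict[str, float]] = {}
        self.weighted = weighted
        if nodes is not None:
            for n in nodes:
                self.add_node(n)

    # -- construction -------------------------------------------------

    def add_node(self, u: str) -> None:
        if u not in self._index:
            self._index[u] = len(self._nodes)
            self._nodes.append(u)
            self._adj[u] = {}

    def add_edge(self, u: str, v: str, weight: float = 1.0) -> None:
        if u == v:
            raise ValueError(f"self-loop on node {u!r} is not allowed")
        if weight <= 0:
            raise ValueError(f"edge ({u!r}, {v!r}) has non-positive weight {weight}")
        self.add_node(u)
        self.add_node(v)
        self._adj[u][v] = float(weight)
        self._adj[v][u] = float(weight)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        nodes: Iterable[str] | None = None,
        weighted: bool = False,
    ) -> "Network":
        net = cls(nodes=nodes, weighted=weighted)
        for e in edges:
            if len(e) == 2:
                net.add_edge(str(e[0]), str(e[1]))
            else:
                net.add_edge(str(e[0]), str(e[1]), float(e[2]))
        return net

    # -- queries ------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return list(self._nodes)

    def index(self, u: str) -> int:
        return self._index[u]

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def has_node(self, u: str) -> bool:
        return u in self._index

    def has_edge(self, u: str, v: str) -> bool:
        return v in self._adj.get(u, ())

    def weight(self, u: str, v: str) -> float:
        return self._adj[u][v]

    def neighbors(self, u: str) -> set[str]:
        return set(self._adj[u])

    def degree(self, u: str) -> int:
        return len(self._adj[u])

    def edge_key(self, u: str, v: str) -> tuple[str, str]:
        """Canonical (u, v) ordering of an edge by node order."""
        return (u, v) if self._index[u] < self._index[v] else (v, u)

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Edges as (u, v, weight), u before v in node order, sorted by node order."""
        for u in self._nodes:
            iu = self._index[u]
            for v, w in self._adj[u].items():
                if self._index[v] > iu:
                    yield u, v, w

    # -- conversions --------------------------------------------------

    def adjacency_matrix(self, use_weights: bool = True) -> sp.csr_matrix:
        n = self.n_nodes
        rows, cols, vals = [], [], []
        for u, v, w in self.edges():
            i, j = self._index[u], self._index[v]
            val = w if use_weights else 1.0
            rows += [i, j]
            cols += [j, i]
            vals += [val, val]
        return sp.csr_matrix(
            (np.asarray(vals), (rows, cols)), shape=(n, n), dtype=float
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self._nodes)
        g.add_weighted_edges_from(self.edges())
        return g

    def __contains__(self, u: str) -> bool:
        return u in self._index

    def __repr__(self) -> str:  # pragma: no cover
        kind = "weighted" if self.weighted else "unweighted"
        return f"<Network {kind}: {self.n_nodes} nodes, {self.n_edges} edges>"
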