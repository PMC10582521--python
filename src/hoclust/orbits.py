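"""Per-edge graphlet orbit counting by induced-subgraph enumeration.

For every edge of a network we count, for each of the 68 edge orbits,
the number of induced graphlet occurrences that place the edge in that
orbit.  Enumeration uses the ESU scheme (each connected induced subgraph
of a given size is visited exactly once); each occurrence is classified
against the catalog and its edges incremented in the matching orbit.
Counting is purely topological: edge weights never enter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .catalog import GraphletCatalog, build_catalog
from .network import Network

__all__ = [
    "EdgeOrbitCounts",
    "enumerate_connected_subgraphs",
    "count_edge_orbits",
    "edges_in_graphlet",
]

log = logging.getLogger(__name__)

N_ORBITS = 68

# degree above which size-5 enumeration starts to hurt; warn, don't fail
_DEGREE_WARN = 150


@dataclass
class EdgeOrbitCounts:
    """Per-edge vector of 68 orbit counts, keyed by canonical (u, v)."""

    counts: dict[tuple[str, str], np.ndarray]
    max_size: int

    def get(self, u: str, v: str, network: Network) -> np.ndarray:
        return self.counts[network.edge_key(u, v)]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"node_u": u, "node_v": v, **{f"o{i}": int(c) for i, c in enumerate(vec)}}
            for (u, v), vec in self.counts.items()
        ]
        cols = ["node_u", "node_v"] + [f"o{i}" for i in range(N_ORBITS)]
        return pd.DataFrame(rows, columns=cols)


def enumerate_connected_subgraphs(network: Network, size: int) -> Iterator[tuple[str, ...]]:
    """Yield every connected induced subgraph on exactly ``size`` nodes once.

    ESU enumeration: grow from each root node using only higher-indexed
    exclusive neighbours, which guarantees each node subset appears once.
    """
    if size < 2 or size > 5:
        raise ValueError(f"subgraph size must be in 2..5, got {size}")
    nodes = network.nodes
    index = network.index
    nbrs = {u: network.neighbors(u) for u in nodes}

    def extend(sub: list[str], extension: set[str], root_idx: int):
        if len(sub) == size:
            yield tuple(sub)
            return
        ext = sorted(extension, key=index)
        while ext:
            w = ext.pop(0)
            sub_nbrs = set().union(*(nbrs[s] for s in sub))
            new_ext = (set(ext) | {
                u for u in nbrs[w]
                if index(u) > root_idx and u not in sub_nbrs and u not in sub
            }) - {w}
            yield from extend(sub + [w], new_ext, root_idx)

    for v in nodes:
        ri = index(v)
        ext0 = {u for u in nbrs[v] if index(u) > ri}
        yield from extend([v], ext0, ri)


def _orbit_map_for_mask(mask: int, n: int, pairs: list[tuple[int, int]],
                        catalog: GraphletCatalog) -> list[tuple[int, int, int]]:
    """For one induced-subgraph shape, map each present position pair to its orbit.

    ``mask`` encodes which of the ``pairs`` (position pairs over the sorted
    node tuple) are edges.  Returns [(i, j, global_orbit_id), ...].
    """
    edges = [pairs[b] for b in range(len(pairs)) if mask >> b & 1]
    gid, witness = catalog.classify_subgraph(edges)
    out = []
    for i, j in edges:
        canon_edge = (witness[i], witness[j])
        out.append((i, j, catalog.orbit_of_edge(gid, canon_edge)))
    return out


def count_edge_orbits(
    network: Network,
    max_size: int = 5,
    catalog: GraphletCatalog | None = None,
) -> EdgeOrbitCounts:
    """Count, for every edge, its occurrences in each edge orbit."""
    if catalog is None:
        catalog = build_catalog(max_size)
    if catalog.max_size < max_size:
        raise ValueError(
            f"catalog covers graphlets up to {catalog.max_size} nodes, need {max_size}"
        )
    if max_size == 5 and network.n_nodes:
        dmax = max(network.degree(u) for u in network.nodes)
        if dmax > _DEGREE_WARN:
            warnings.warn(
                f"maximum degree {dmax}: size-5 subgraph enumeration may be slow",
                RuntimeWarning,
                stacklevel=2,
            )

    counts = {
        network.edge_key(u, v): np.zeros(N_ORBITS, dtype=np.int64)
        for u, v, _ in network.edges()
    }
    index = network.index
    # orbit maps are cached per adjacency bitmask: at most 2^10 shapes at size 5
    cache: dict[tuple[int, int], list[tuple[int, int, int]]] = {}

    for size in range(3, max_size + 1):
        pairs = [(i, j) for i in range(size) for j in range(i + 1, size)]
        for subset in enumerate_connected_subgraphs(network, size):
            snodes = sorted(subset, key=index)
            mask = 0
            for b, (i, j) in enumerate(pairs):
                if network.has_edge(snodes[i], snodes[j]):
                    mask |= 1 << b
            key = (size, mask)
            omap = cache.get(key)
            if omap is None:
                omap = cache[key] = _orbit_map_for_mask(mask, size, pairs, catalog)
            for i, j, orbit in omap:
                counts[network.edge_key(snodes[i], snodes[j])][orbit] += 1

    return EdgeOrbitCounts(counts=counts, max_size=max_size)


def edges_in_graphlet(
    counts: EdgeOrbitCounts,
    k: int,
    catalog: GraphletCatalog,
) -> list[tuple[str, str]]:
    """Edges participating in at least one induced occurrence of G_k.

    For k = 0 every edge qualifies (the G0-induced network is the network
    itself); for k >= 1 an edge qualifies when it has a positive count in
    any orbit of O_k.
    """
    if not 0 <= k < catalog.n_graphlets:
        raise ValueError(f"graphlet id {k} not in catalog")
    if k == 0:
        return list(counts.counts)
    if catalog.graphlet(k).size > counts.max_size:
        raise ValueError(
            f"counts were computed with max_size={counts.max_size}, "
            f"but G{k} has {catalog.graphlet(k).size} nodes"
        )
    ok = sorted(catalog.orbit_sets[k])
    return [e for e, vec in counts.counts.items() if int(vec[ok].sum()) > 0]
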