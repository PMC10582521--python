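"""Seeded synthetic networks with planted higher-order community structure.

The default generator plants communities tiled with triangles (every
within-community edge sits in at least one triangle) and joins them by
sparse tree-like bridge edges that are kept out of any triangle.  Edge
induction by the triangle graphlet G2 therefore removes exactly the
bridges, disconnecting the communities — the desk-scale analogue of a
protein interaction network whose functional modules are rich in a
specific graphlet while inter-module links are not.  Matched gene-set
collections (one set per planted community, with optional membership
noise) give the enrichment layer a ground-truth target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluate import GeneSetCollection
from .network import Network

__all__ = [
    "PlantedNetwork",
    "generate_planted_graphlet_network",
    "generate_matched_gene_sets",
    "toy_networks",
]


@dataclass
class PlantedNetwork:
    """A synthetic network with its ground-truth community partition."""

    network: Network
    communities: list[list[str]]
    params: dict = field(default_factory=dict)

    @property
    def partition(self) -> list[list[str]]:
        return [list(c) for c in self.communities]


def _triangle_tiling_edges(nodes: list[str]) -> list[tuple[str, str]]:
    """Cyclic triangle tiling: ring edges plus next-nearest chords.

    Every edge lies in a triangle, and the community is vertex-transitive,
    so MCL holds it together as one cluster at moderate inflation.
    """
    n = len(nodes)
    edges = {tuple(sorted((i, (i + d) % n))) for i in range(n) for d in (1, 2) if (i + d) % n != i}
    return [(nodes[i], nodes[j]) for i, j in sorted(edges)]


def generate_planted_graphlet_network(
    n_communities: int = 2,
    community_size: int = 6,
    pattern: str = "G2",
    p_between: float = 0.05,
    p_background: float = 0.0,
    seed: int = 0,
) -> PlantedNetwork:
    """Plant graphlet-rich communities joined by pattern-free bridges.

    pattern
        ``"G2"`` tiles each community with chained triangles (default);
        ``"clique"`` makes each community complete, so dense graphlets up
        to K5 are abundant inside communities.
    p_between
        Probability of a bridge edge per cross-community node pair.
        Bridges (and background edges) are rejected when they would close
        a triangle, keeping them invisible to triangle induction.
    p_background
        Probability of an extra triangle-free edge between any two
        non-adjacent nodes, added after the bridges.
    """
    if community_size < 3:
        raise ValueError("community sizes must be >= 3")
    if n_communities < 1:
        raise ValueError("need at least one community")
    for name, p in (("p_between", p_between), ("p_background", p_background)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if pattern not in ("G2", "clique"):
        raise ValueError(f"unknown pattern {pattern!r}")

    rng = np.random.default_rng(seed)
    communities = [
        [f"c{ci}_n{i}" for i in range(community_size)] for ci in range(n_communities)
    ]
    net = Network(nodes=[u for c in communities for u in c])
    for comm in communities:
        if pattern == "G2":
            for u, v in _triangle_tiling_edges(comm):
                net.add_edge(u, v)
        else:
            for i, u in enumerate(comm):
                for v in comm[i + 1:]:
                    net.add_edge(u, v)

    def closes_triangle(u: str, v: str) -> bool:
        return bool(net.neighbors(u) & net.neighbors(v))

    for ci in range(n_communities):
        for cj in range(ci + 1, n_communities):
            for u in communities[ci]:
                for v in communities[cj]:
                    if rng.random() < p_between and not net.has_edge(u, v) \
                            and not closes_triangle(u, v):
                        net.add_edge(u, v)
    if p_background > 0:
        nodes = net.nodes
        for i, u in enumerate(nodes):
            for v in nodes[i + 1:]:
                if rng.random() < p_background and not net.has_edge(u, v) \
                        and not closes_triangle(u, v):
                    net.add_edge(u, v)

    return PlantedNetwork(
        network=net,
        communities=communities,
        params={
            "n_communities": n_communities,
            "community_size": community_size,
            "pattern": pattern,
            "p_between": p_between,
            "p_background": p_background,
            "seed": seed,
        },
    )


def generate_matched_gene_sets(
    planted: PlantedNetwork,
    noise: float = 0.0,
    seed: int = 0,
) -> GeneSetCollection:
    """One gene set per planted community, with a noisy membership fraction.

    A ``noise`` fraction of each set's members is swapped for uniformly
    chosen off-community nodes, degrading the module/set overlap.
    """
    if not 0 <= noise < 1:
        raise ValueError("noise must be in [0, 1)")
    rng = np.random.default_rng(seed)
    all_nodes = planted.network.nodes
    sets: dict[str, frozenset[str]] = {}
    for ci, comm in enumerate(planted.communities):
        members = list(comm)
        n_swap = int(noise * len(members))
        if n_swap:
            out = rng.choice(len(members), size=n_swap, replace=False)
            pool = [u for u in all_nodes if u not in comm]
            repl = rng.choice(len(pool), size=min(n_swap, len(pool)), replace=False)
            for pos, r in zip(sorted(out), repl):
                members[pos] = pool[int(r)]
        sets[f"community_{ci}"] = frozenset(members)
    return GeneSetCollection(sets=sets, source="planted")


def toy_networks() -> dict[str, Network]:
    """Canonical small test graphs used throughout the suite."""
    toys = {
        "triangle": [("a", "b"), ("b", "c"), ("a", "c")],
        "path4": [("a", "b"), ("b", "c"), ("c", "d")],
        "paw": [("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")],
        "k4": [(u, v) for i, u in enumerate("abcd") for v in "abcd"[i + 1:]],
        "k5": [(u, v) for i, u in enumerate("abcde") for v in "abcde"[i + 1:]],
        # two triangles joined by one bridge edge
        "barbell": [
            ("a", "b"), ("b", "c"), ("a", "c"),
            ("d", "e"), ("e", "f"), ("d", "f"),
            ("c", "d"),
        ],
        # K3,3 is bipartite, hence triangle-free
        "bipartite": [(u, v) for u in "abc" for v in "xyz"],
    }
    return {name: Network.from_edges(edges) for name, edges in toys.items()}
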