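"""Graphlet catalog: connected, induced, non-isomorphic graphs on 2-5 nodes.

Graphlets G0-G29 are the 30 connected non-isomorphic graphs on 2 to 5
nodes.  The edges of each graphlet fall into *edge orbits*: two edges
share an orbit when some automorphism of the graphlet maps one onto the
other.  Sizes 3-5 contribute 68 edge orbits in total (12 for sizes 3-4,
56 for size 5); the single edge of G0 carries no orbit number, so global
orbit ids run 0-67 starting with G1's orbit.

Ordering convention.  G0-G8 (sizes 2-4) follow the established graphlet
numbering of the graphlet-counting literature: G0 edge, G1 3-path,
G2 triangle, G3 4-path, G4 claw, G5 4-cycle, G6 paw, G7 diamond, G8 K4,
which places the orbits of G1-G8 at global ids 0-11.  The 21 graphlets
on 5 nodes (G9-G29) are ordered deterministically by edge count and then
by canonical certificate; only the *membership* of each graphlet's orbit
set (never the global numbering of 5-node orbits) enters any downstream
computation.  Within a graphlet, orbits are ordered by their smallest
member edge, which for the 4-path puts the outer-edge orbit (global id 2)
before the middle-edge orbit (global id 3).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

__all__ = [
    "Graphlet",
    "EdgeOrbit",
    "GraphletCatalog",
    "build_catalog",
    "edge_orbit_partition",
]

Edge = tuple[int, int]

# Canonical edge lists for sizes 2-4, in the conventional G0-G8 order.
_SMALL_GRAPHLETS: list[tuple[Edge, ...]] = [
    ((0, 1),),                                                    # G0 edge
    ((0, 1), (1, 2)),                                             # G1 3-path
    ((0, 1), (0, 2), (1, 2)),                                     # G2 triangle
    ((0, 1), (1, 2), (2, 3)),                                     # G3 4-path
    ((0, 1), (0, 2), (0, 3)),                                     # G4 claw
    ((0, 1), (1, 2), (2, 3), (0, 3)),                             # G5 4-cycle
    ((0, 1), (0, 2), (1, 2), (2, 3)),                             # G6 paw
    ((0, 1), (0, 2), (1, 2), (1, 3), (2, 3)),                     # G7 diamond
    ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)),             # G8 K4
]


def _normalize_edges(edges) -> tuple[Edge, ...]:
    return tuple(sorted(tuple(sorted(e)) for e in edges))


def _certificate(n: int, edges) -> tuple[Edge, ...]:
    """Lexicographically minimal relabelling of the edge list (graph-iso key)."""
    eset = _normalize_edges(edges)
    best = None
    for p in itertools.permutations(range(n)):
        cand = tuple(sorted(tuple(sorted((p[u], p[v]))) for u, v in eset))
        if best is None or cand < best:
            best = cand
    return best


def _is_connected(n: int, edges) -> bool:
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen = {0}
    stack = [0]
    while stack:
        x = stack.pop()
        for y in adj[x]:
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return len(seen) == n


def _automorphisms(n: int, edges: tuple[Edge, ...]) -> tuple[tuple[int, ...], ...]:
    eset = set(edges)
    auts = []
    for p in itertools.permutations(range(n)):
        if all(tuple(sorted((p[u], p[v]))) in eset for u, v in eset):
            auts.append(p)
    return tuple(auts)


@dataclass(frozen=True)
class Graphlet:
    """One catalog entry on canonical node labels 0..size-1."""

    id: int
    size: int
    edges: tuple[Edge, ...]
    automorphisms: tuple[tuple[int, ...], ...]

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class EdgeOrbit:
    """An automorphism class of one graphlet's edges, with its global id."""

    global_id: int
    graphlet_id: int
    member_edges: frozenset[Edge]


@dataclass
class GraphletCatalog:
    """All graphlets up to ``max_size`` nodes with their edge orbits."""

    max_size: int
    graphlets: list[Graphlet]
    orbits: list[EdgeOrbit]
    orbit_sets: dict[int, frozenset[int]]
    _by_certificate: dict[tuple[Edge, ...], int] = field(repr=False, default_factory=dict)
    _edge_to_orbit: dict[int, dict[Edge, int]] = field(repr=False, default_factory=dict)

    @property
    def n_graphlets(self) -> int:
        return len(self.graphlets)

    @property
    def n_orbits(self) -> int:
        return len(self.orbits)

    def graphlet(self, k: int) -> Graphlet:
        if not 0 <= k < len(self.graphlets):
            raise ValueError(f"graphlet id {k} not in catalog (0..{len(self.graphlets) - 1})")
        return self.graphlets[k]

    def orbit_of_edge(self, k: int, edge: Edge) -> int:
        """Global orbit id of a canonical edge of graphlet G_k (k >= 1)."""
        e = tuple(sorted(edge))
        return self._edge_to_orbit[k][e]

    def classify_subgraph(self, edges) -> tuple[int, dict]:
        """Map a connected graph on <= max_size labelled nodes to its catalog id.

        Returns ``(graphlet_id, witness)`` where ``witness`` maps each input
        node to its canonical label, chosen deterministically as the first
        matching permutation over the sorted input nodes.
        """
        edges = [tuple(e) for e in edges]
        nodes = sorted({u for e in edges for u in e})
        n = len(nodes)
        if n < 2 or n > self.max_size:
            raise ValueError(f"subgraph has {n} nodes; supported range is 2..{self.max_size}")
        idx = {u: i for i, u in enumerate(nodes)}
        int_edges = _normalize_edges((idx[u], idx[v]) for u, v in edges)
        if not _is_connected(n, int_edges):
            raise ValueError("subgraph is not connected")
        cert = _certificate(n, int_edges)
        gid = self._by_certificate.get(cert)
        if gid is None:  # pragma: no cover - catalog covers all connected graphs
            raise ValueError("subgraph does not match any catalog graphlet")
        target = set(self.graphlets[gid].edges)
        for p in itertools.permutations(range(n)):
            if all(tuple(sorted((p[u], p[v]))) in target for u, v in int_edges):
                return gid, {u: p[idx[u]] for u in nodes}
        raise AssertionError("certificate matched but no witness found")  # pragma: no cover


def _enumerate_connected_classes(n: int) -> dict[tuple[Edge, ...], tuple[Edge, ...]]:
    """All connected graphs on n labelled nodes, one representative per iso class."""
    classes: dict[tuple[Edge, ...], tuple[Edge, ...]] = {}
    pairs = list(itertools.combinations(range(n), 2))
    for r in range(n - 1, len(pairs) + 1):
        for es in itertools.combinations(pairs, r):
            if not _is_connected(n, es):
                continue
            cert = _certificate(n, es)
            classes.setdefault(cert, _normalize_edges(es))
    return classes


def _edge_orbit_partition(graphlet_edges: tuple[Edge, ...], auts) -> list[frozenset[Edge]]:
    """Partition a graphlet's edges into automorphism orbits, ordered by min edge."""
    orbits: dict[Edge, set[Edge]] = {}
    for e in graphlet_edges:
        members = {tuple(sorted((p[e[0]], p[e[1]]))) for p in auts}
        orbits.setdefault(min(members), set()).update(members)
    return [frozenset(orbits[key]) for key in sorted(orbits)]


def build_catalog(max_size: int = 5) -> GraphletCatalog:
    """Enumerate all graphlets up to ``max_size`` nodes and their edge orbits.

    The graph classes are found by exhaustive enumeration with brute-force
    isomorphism testing; orbits come from explicit automorphism enumeration
    (at most 5! = 120 permutations per graphlet).
    """
    if max_size not in (3, 4, 5):
        raise ValueError(f"max_size must be 3, 4 or 5, got {max_size!r}")

    graphlets: list[Graphlet] = []
    by_cert: dict[tuple[Edge, ...], int] = {}
    small_certs = {_certificate(max(max(e) for e in edges) + 1, edges): edges
                   for edges in _SMALL_GRAPHLETS}

    for n in range(2, max_size + 1):
        classes = _enumerate_connected_classes(n)
        if n <= 4:
            # embedded conventional ordering; sanity-checked against enumeration
            ordered = [
                (cert, small_certs[cert])
                for cert in [_certificate(n, e) for e in _SMALL_GRAPHLETS
                             if max(max(p) for p in e) + 1 == n]
            ]
            if set(c for c, _ in ordered) != set(classes):
                raise AssertionError(
                    f"embedded graphlet table disagrees with enumeration at size {n}"
                )
        else:
            ordered = [(cert, classes[cert])
                       for cert in sorted(classes, key=lambda c: (len(c), c))]
        for cert, edges in ordered:
            gid = len(graphlets)
            graphlets.append(Graphlet(gid, n, edges, _automorphisms(n, edges)))
            by_cert[cert] = gid

    orbits: list[EdgeOrbit] = []
    orbit_sets: dict[int, frozenset[int]] = {}
    edge_to_orbit: dict[int, dict[Edge, int]] = {}
    for g in graphlets:
        if g.id == 0:
            continue  # G0's edge carries no orbit number
        ids = []
        edge_to_orbit[g.id] = {}
        for members in _edge_orbit_partition(g.edges, g.automorphisms):
            oid = len(orbits)
            orbits.append(EdgeOrbit(oid, g.id, members))
            ids.append(oid)
            for e in members:
                edge_to_orbit[g.id][e] = oid
        orbit_sets[g.id] = frozenset(ids)

    return GraphletCatalog(
        max_size=max_size,
        graphlets=graphlets,
        orbits=orbits,
        orbit_sets=orbit_sets,
        _by_certificate=by_cert,
        _edge_to_orbit=edge_to_orbit,
    )


def edge_orbit_partition(catalog: GraphletCatalog, k: int) -> list[EdgeOrbit]:
    """The edge-orbit classes of graphlet G_k (k >= 1), in global-id order."""
    if k == 0:
        raise ValueError(
            "G0 has no numbered edge orbit; the G0-induced network is the "
            "original network by definition"
        )
    if not 1 <= k < catalog.n_graphlets:
        raise ValueError(f"graphlet id {k} not in catalog")
    return [o for o in catalog.orbits if o.graphlet_id == k]
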