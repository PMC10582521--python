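"""Markov clustering: reference-implementation equivalence and post-processing."""

import random

import networkx as nx
import numpy as np
import pytest

from hoclust import (
    MCLOptions,
    Network,
    build_transition_matrix,
    cluster_graphlet,
    count_edge_orbits,
    induce_network,
    postprocess_clusters,
    run_mcl,
    sweep_inflation,
)
from hoclust.induce import InducedNetwork, TransitionMatrix


def reference_mcl(network, inflation=2.0, max_iter=200, tol=1e-8):
    """Independent textbook MCL: dense, column-stochastic, component extraction.

    Written against the classic description of the algorithm (add self-loops,
    normalise columns, alternate squaring with elementwise inflation) so it
    shares no code path with the library implementation.
    """
    nodes = network.nodes
    n = len(nodes)
    a = np.zeros((n, n))
    idx = {u: i for i, u in enumerate(nodes)}
    for u, v, w in network.edges():
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1.0
    a += np.eye(n)
    m = a / a.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = m.copy()
        m = m @ m
        m = m ** inflation
        m /= m.sum(axis=0, keepdims=True)
        m[m < 1e-10] = 0.0
        m /= m.sum(axis=0, keepdims=True)
        if np.max(np.abs(m - prev)) < tol:
            break
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(zip(*np.nonzero(m > 1e-6)))
    return sorted(
        (sorted(nodes[i] for i in comp) for comp in nx.connected_components(g)),
        key=lambda c: c[0],
    )


def assert_mcl_equivalent(network, inflation):
    """Compare library MCL with the reference, reconciling the one documented
    difference: a node flowing into several attractor systems is assigned to
    its first attractor here, whereas component extraction merges the systems."""
    from hoclust.mcl import mcl_iterate

    opts = MCLOptions(inflation=inflation)
    t = build_transition_matrix(full_induced(network))
    got = run_mcl(t, opts)
    expected = reference_mcl(network, inflation=inflation)
    if sorted(sorted(c) for c in got) == expected:
        return
    # locate multi-attractor nodes in the converged flow matrix and merge the
    # systems they straddle, as component extraction implicitly does
    m = mcl_iterate(t, opts).toarray()
    eps = 1e-5
    label = {u: i for i, c in enumerate(got) for u in c}
    merged = {i: i for i in range(len(got))}

    def find(x):
        while merged[x] != x:
            x = merged[x]
        return x

    attractors = [i for i in range(len(t.nodes)) if m[i, i] > eps]
    for i, u in enumerate(t.nodes):
        targets = {label[t.nodes[j]] for j in attractors if m[i, j] > eps}
        for a in targets:
            ra, rb = find(a), find(label[u])
            if ra != rb:
                merged[max(ra, rb)] = min(ra, rb)
    combined = {}
    for ci, cluster in enumerate(got):
        combined.setdefault(find(ci), []).extend(cluster)
    assert sorted(sorted(c) for c in combined.values()) == expected


def full_induced(network):
    return InducedNetwork(
        graphlet_id=0,
        parent=network,
        retained_edges={network.edge_key(u, v): w for u, v, w in network.edges()},
        isolated_nodes=frozenset(),
    )


def random_connected_network(rng, n, p):
    while True:
        net = Network(nodes=[f"n{i}" for i in range(n)])
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    net.add_edge(f"n{i}", f"n{j}")
        if net.n_edges >= n - 1:
            return net


class TestRunMCL:
    def test_barbell_splits_into_triangles(self, toys):
        raw = run_mcl(build_transition_matrix(full_induced(toys["barbell"])),
                      MCLOptions(inflation=2.0))
        assert sorted(sorted(c) for c in raw) == [["a", "b", "c"], ["d", "e", "f"]]

    def test_k5_single_cluster(self, toys):
        raw = run_mcl(build_transition_matrix(full_induced(toys["k5"])))
        assert sorted(sorted(c) for c in raw) == [["a", "b", "c", "d", "e"]]

    def test_no_cluster_spans_components(self):
        net = Network.from_edges(
            [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")]
        )
        raw = run_mcl(build_transition_matrix(full_induced(net)))
        for cluster in raw:
            kinds = {u in "abc" for u in cluster}
            assert len(kinds) == 1

    def test_rejects_non_stochastic_input(self, toys):
        t = build_transition_matrix(full_induced(toys["triangle"]))
        bad = TransitionMatrix(nodes=t.nodes, matrix=t.matrix * 2.0)
        with pytest.raises(ValueError):
            run_mcl(bad)

    def test_raw_clusters_cover_all_nodes(self, toys):
        for name, net in toys.items():
            raw = run_mcl(build_transition_matrix(full_induced(net)))
            covered = sorted(u for c in raw for u in c)
            assert covered == sorted(net.nodes), name

    @pytest.mark.parametrize("seed", range(20))
    def test_reference_equivalence_random_graphs(self, seed):
        """Partitions match an independently written dense MCL on random graphs."""
        rng = random.Random(seed)
        n = rng.randint(6, 14)
        net = random_connected_network(rng, n, rng.uniform(0.25, 0.5))
        inflation = rng.choice([1.6, 2.0, 2.5, 3.0])
        assert_mcl_equivalent(net, inflation)


class TestPostprocess:
    def test_isolated_member_removed(self, toys, catalog):
        counts = count_edge_orbits(toys["paw"], 5, catalog)
        induced = induce_network(toys["paw"], 2, counts, catalog)
        out = postprocess_clusters([["a", "b", "c", "d"]], induced)
        assert out.clusters == [["a", "b", "c"]]

    def test_small_cluster_dropped(self, toys, catalog):
        counts = count_edge_orbits(toys["paw"], 5, catalog)
        induced = induce_network(toys["paw"], 0, counts, catalog)
        out = postprocess_clusters([["a", "b"]], induced)
        assert out.clusters == []

    def test_connected_cluster_unchanged(self, toys, catalog):
        counts = count_edge_orbits(toys["triangle"], 3, catalog)
        induced = induce_network(toys["triangle"], 0, counts, catalog)
        out = postprocess_clusters([["a", "b", "c"]], induced)
        assert out.clusters == [["a", "b", "c"]]

    def test_largest_component_kept(self, catalog):
        # two components of sizes 3 and 4 inside one raw cluster
        net = Network.from_edges(
            [("a", "b"), ("b", "c"), ("a", "c"),
             ("p", "q"), ("q", "r"), ("r", "s"), ("p", "s")]
        )
        counts = count_edge_orbits(net, 3, catalog)
        induced = induce_network(net, 0, counts, catalog)
        out = postprocess_clusters([["a", "b", "c", "p", "q", "r", "s"]], induced)
        assert out.clusters == [["p", "q", "r", "s"]]


class TestClusterGraphlet:
    def test_invariants_on_every_run(self, toys, catalog):
        for name in ("barbell", "k4", "paw", "bipartite"):
            net = toys[name]
            counts = count_edge_orbits(net, 5, catalog)
            for k in (0, 1, 2):
                c = cluster_graphlet(net, k, 2.0, counts=counts, catalog=catalog)
                seen = set()
                induced = induce_network(net, k, counts, catalog)
                g = nx.Graph()
                g.add_edges_from(induced.retained_edges)
                for cluster in c.clusters:
                    assert len(cluster) >= 3
                    assert not (seen & set(cluster))  # disjoint
                    seen |= set(cluster)
                    assert nx.is_connected(g.subgraph(cluster))

    def test_empty_induced_network_gives_empty_clustering(self, toys, catalog):
        net = toys["bipartite"]
        counts = count_edge_orbits(net, 5, catalog)
        c = cluster_graphlet(net, 2, 2.0, counts=counts, catalog=catalog)
        assert c.clusters == []

    def test_deterministic(self, toys, catalog):
        counts = count_edge_orbits(toys["barbell"], 5, catalog)
        a = cluster_graphlet(toys["barbell"], 2, 2.0, counts=counts, catalog=catalog)
        b = cluster_graphlet(toys["barbell"], 2, 2.0, counts=counts, catalog=catalog)
        assert a.clusters == b.clusters


class TestSweep:
    def test_single_value_grid(self, toys, catalog):
        counts = count_edge_orbits(toys["barbell"], 5, catalog)
        table = sweep_inflation(toys["barbell"], 2, [2.0], counts=counts, catalog=catalog)
        assert len(table) == 1
        assert table.loc[0, "n_clusters"] == 2

    def test_consistent_with_cluster_graphlet(self, toys, catalog):
        counts = count_edge_orbits(toys["barbell"], 5, catalog)
        table = sweep_inflation(toys["barbell"], 0, [1.5, 2.0, 4.0],
                                counts=counts, catalog=catalog)
        for _, row in table.iterrows():
            c = cluster_graphlet(toys["barbell"], 0, row["inflation"],
                                 counts=counts, catalog=catalog)
            assert row["n_clusters"] == c.n_clusters
            assert row["largest_cluster"] == c.largest_cluster_size

    def test_granularity_trend_on_planted_graph(self, catalog):
        """Cluster count broadly non-decreasing in inflation (weak trend check)."""
        from hoclust import generate_planted_graphlet_network

        pl = generate_planted_graphlet_network(
            n_communities=5, community_size=6, p_between=0.02, seed=1
        )
        table = sweep_inflation(pl.network, 0, [1.4, 2.0, 3.0, 5.0], catalog=catalog)
        ns = table["n_clusters"].tolist()
        violations = sum(1 for a, b in zip(ns, ns[1:]) if b < a)
        assert violations <= 1  # small violations tolerated, trend must hold

    def test_rejects_invalid_grid(self, toys, catalog):
        with pytest.raises(ValueError):
            sweep_inflation(toys["barbell"], 0, [1.0, 2.0], catalog=catalog)
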