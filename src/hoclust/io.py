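"""Readers and writers: TSV edge lists, GMT gene sets, cluster and orbit tables."""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import pandas as pd

from .evaluate import GeneSetCollection
from .mcl import Clustering
from .network import Network
from .orbits import N_ORBITS, EdgeOrbitCounts

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
    "read_clusters",
    "write_clusters",
    "read_orbit_counts",
    "write_orbit_counts",
]

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file; the message carries the 1-based line number."""


def read_edge_list(path) -> Network:
    """Read an undirected TSV edge list ``u<TAB>v[<TAB>weight]``.

    ``#`` comment lines and blank lines are ignored.  Duplicate pairs keep
    the maximum weight (with a warning); self-loops are dropped (warning).
    A weight column makes the network weighted.
    """
    path = Path(path)
    net = Network()
    weighted = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected at least 2 columns")
            u, v = parts[0], parts[1]
            w = 1.0
            if len(parts) >= 3:
                try:
                    w = float(parts[2])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric weight {parts[2]!r}"
                    ) from None
                if w <= 0:
                    raise ParseError(f"{path}:{lineno}: weight must be > 0, got {w}")
                weighted = True
            if u == v:
                warnings.warn(f"{path}:{lineno}: self-loop on {u!r} dropped", RuntimeWarning,
                              stacklevel=2)
                net.add_node(u)
                continue
            if net.has_edge(u, v):
                old = net.weight(u, v)
                if old != w:
                    warnings.warn(
                        f"{path}:{lineno}: duplicate edge ({u}, {v}) with conflicting "
                        f"weights {old} / {w}; keeping max",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                w = max(old, w)
            net.add_edge(u, v, w)
    net.weighted = weighted
    return net


def write_edge_list(network: Network, path) -> None:
    with Path(path).open("w") as fh:
        for u, v, w in network.edges():
            if network.weighted:
                fh.write(f"{u}\t{v}\t{w:g}\n")
            else:
                fh.write(f"{u}\t{v}\n")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene...`` per line."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT lines need >= 3 tab-separated fields")
            name = parts[0]
            genes = frozenset(g for g in parts[2:] if g)
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            if not genes:
                warnings.warn(f"{path}:{lineno}: gene set {name!r} has no genes; skipped",
                              RuntimeWarning, stacklevel=2)
                continue
            sets[name] = genes
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with Path(path).open("w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, collection.source or "na", *sorted(genes)]) + "\n")


def read_clusters(path) -> Clustering:
    """Read a ``cluster_id<TAB>node`` membership table."""
    path = Path(path)
    members: dict[str, list[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns (cluster_id, node)")
            members.setdefault(parts[0], []).append(parts[1])
    return Clustering(
        clusters=list(members.values()),
        graphlet_id=-1,
        inflation=float("nan"),
    )


def write_clusters(clustering: Clustering, path) -> None:
    with Path(path).open("w") as fh:
        for ci, cluster in enumerate(clustering.clusters):
            for node in cluster:
                fh.write(f"{ci}\t{node}\n")


def write_orbit_counts(counts: EdgeOrbitCounts, path) -> None:
    counts.to_dataframe().to_csv(path, sep="\t", index=False)


def read_orbit_counts(path) -> EdgeOrbitCounts:
    df = pd.read_csv(path, sep="\t", dtype={"node_u": str, "node_v": str})
    cols = [f"o{i}" for i in range(N_ORBITS)]
    mat = df[cols].to_numpy(dtype="int64")
    out = {
        (str(r.node_u), str(r.node_v)): mat[i]
        for i, r in enumerate(df.itertuples(index=False))
    }
    max_size = 5 if mat[:, 12:].any() else 4
    return EdgeOrbitCounts(counts=out, max_size=max_size)
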