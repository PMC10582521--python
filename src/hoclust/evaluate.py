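"""Clustering comparison and gene-set scoring of modules.

Provides the Adjusted Rand Index between clusterings (restricted to
clusters of size >= 3), per-cluster transitivity of the parent network,
and hypergeometric gene-set enrichment with Benjamini-Hochberg control,
plus the coverage summaries used to compare clusterings: how many gene
sets found a significant module, how many modules found a significant
set, and the corresponding gene fractions.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from .mcl import Clustering
from .network import Network

__all__ = [
    "GeneSetCollection",
    "CoverageSummary",
    "adjusted_rand_index",
    "cluster_transitivity",
    "hypergeom_pvalue",
    "bh_adjust",
    "enrichment_table",
    "coverage_metrics",
    "unique_associations",
]

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways, disease genes, ...)."""

    sets: dict[str, frozenset[str]]
    source: str = ""

    def __post_init__(self):
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)


def _clusters_of(x, min_size: int) -> list[list]:
    clusters = x.clusters if isinstance(x, Clustering) else list(x)
    return [sorted(c) for c in clusters if len(c) >= min_size]


def adjusted_rand_index(
    a,
    b,
    min_size: int = 3,
    mode: str = "intersection",
) -> float:
    """ARI between two clusterings of the same network, chance-corrected.

    Only clusters with at least ``min_size`` nodes enter the comparison
    (pass ``min_size=1`` for generic partitions).  With
    ``mode="intersection"`` the index is computed on nodes covered by
    both clusterings; ``mode="pad"`` instead takes the union of covered
    nodes, treating nodes absent from one clustering as singletons there.
    Returns NaN with a warning when no node is shared.
    """
    ca, cb = _clusters_of(a, min_size), _clusters_of(b, min_size)
    la = {u: i for i, c in enumerate(ca) for u in c}
    lb = {u: i for i, c in enumerate(cb) for u in c}
    if mode == "intersection":
        shared = sorted(set(la) & set(lb))
    elif mode == "pad":
        shared = sorted(set(la) | set(lb))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not shared:
        warnings.warn("no common nodes between clusterings; ARI undefined", RuntimeWarning,
                      stacklevel=2)
        return float("nan")
    # padding: unseen nodes become distinct singleton labels
    xa = [la.get(u, -1 - i) for i, u in enumerate(shared)]
    xb = [lb.get(u, -1 - i) for i, u in enumerate(shared)]
    return float(adjusted_rand_score(xa, xb))


def cluster_transitivity(clustering, network: Network) -> list[float]:
    """Transitivity (3 x triangles / connected triples) of each cluster's subgraph."""
    g = network.to_networkx()
    clusters = clustering.clusters if isinstance(clustering, Clustering) else clustering
    return [float(nx.transitivity(g.subgraph(c))) for c in clusters]


def hypergeom_pvalue(
    overlap: int,
    module_size: int,
    set_size: int,
    universe_size: int,
) -> float:
    """Upper-tail P(X >= overlap) for the overlap of a module and a gene set.

    X follows the hypergeometric distribution of drawing ``module_size``
    genes from a universe containing ``set_size`` marked genes.  The sum
    is exact (integer combinatorics, one final float division).
    """
    if not (0 <= overlap <= min(module_size, set_size)):
        raise ValueError("overlap must be in [0, min(module_size, set_size)]")
    if module_size > universe_size or set_size > universe_size:
        raise ValueError("module and set sizes cannot exceed the universe size")
    numer = sum(
        math.comb(set_size, x) * math.comb(universe_size - set_size, module_size - x)
        for x in range(overlap, min(module_size, set_size) + 1)
    )
    return numer / math.comb(universe_size, module_size)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrichment_table(
    clustering,
    collection: GeneSetCollection,
    network: Network,
    alpha: float = 0.05,
    universe: str = "collection",
    min_size: int = 3,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every module x gene-set pair.

    The BH family is all pairs of this clustering x collection.  The gene
    universe is the network's nodes intersected with the collection's
    genes (``universe="collection"``, default) or all network nodes
    (``universe="network"``); modules and gene sets are restricted to the
    universe before sizing.
    """
    if universe == "collection":
        uni = set(network.nodes) & set(collection.all_genes())
    elif universe == "network":
        uni = set(network.nodes)
    else:
        raise ValueError(f"unknown universe policy {universe!r}")
    if not uni:
        warnings.warn(
            "universe is empty (collection genes disjoint from network); no rows",
            RuntimeWarning,
            stacklevel=2,
        )
        return _empty_enrichment()

    modules = _clusters_of(clustering, min_size)
    rows = []
    for mi, module in enumerate(modules):
        mod = set(module) & uni
        if not mod:
            continue
        for name, genes in collection.sets.items():
            gs = genes & uni
            if not gs:
                continue
            ov = len(mod & gs)
            rows.append(
                {
                    "module": mi,
                    "gene_set": name,
                    "overlap": ov,
                    "module_size": len(mod),
                    "set_size": len(gs),
                    "universe_size": len(uni),
                    "p_raw": hypergeom_pvalue(ov, len(mod), len(gs), len(uni)),
                }
            )
    if not rows:
        warnings.warn("no module/gene-set pair intersects the universe", RuntimeWarning,
                      stacklevel=2)
        return _empty_enrichment()
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
    table["significant"] = table["p_adj"] < alpha
    return table


def _empty_enrichment() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "module", "gene_set", "overlap", "module_size", "set_size",
            "universe_size", "p_raw", "p_adj", "significant",
        ]
    )


@dataclass(frozen=True)
class CoverageSummary:
    """How much of the collection / clustering the significant pairs touch."""

    gene_set_coverage: int       # sets with >= 1 significant module
    gene_set_percentage: float   # genes in significant sets / genes in all sets
    module_coverage: int         # modules significant for >= 1 set
    module_percentage: float     # genes in significant modules / genes in all modules


def coverage_metrics(
    result: pd.DataFrame,
    clustering,
    collection: GeneSetCollection,
    min_size: int = 3,
) -> CoverageSummary:
    """Coverage summaries of an enrichment table at its significance calls."""
    modules = _clusters_of(clustering, min_size)
    all_set_genes = collection.all_genes()
    all_module_genes = {u for m in modules for u in m}

    sig = result[result["significant"]] if len(result) else result
    sig_sets = set(sig["gene_set"]) if len(sig) else set()
    sig_modules = set(sig["module"]) if len(sig) else set()

    genes_in_sig_sets: set[str] = set()
    for name in sig_sets:
        genes_in_sig_sets |= collection.sets[name]
    genes_in_sig_modules = {u for mi in sig_modules for u in modules[mi]}

    return CoverageSummary(
        gene_set_coverage=len(sig_sets),
        gene_set_percentage=(
            len(genes_in_sig_sets) / len(all_set_genes) if all_set_genes else 0.0
        ),
        module_coverage=len(sig_modules),
        module_percentage=(
            len(genes_in_sig_modules) / len(all_module_genes) if all_module_genes else 0.0
        ),
    )


def unique_associations(
    result_k: pd.DataFrame,
    result_0: pd.DataFrame,
) -> tuple[set[str], set[str], set[str]]:
    """Significant gene sets found only by clustering k, only by the baseline, and by both."""
    sig_k = set(result_k.loc[result_k["significant"], "gene_set"]) if len(result_k) else set()
    sig_0 = set(result_0.loc[result_0["significant"], "gene_set"]) if len(result_0) else set()
    return sig_k - sig_0, sig_0 - sig_k, sig_k & sig_0
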