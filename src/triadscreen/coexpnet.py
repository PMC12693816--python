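"""Co-expression networks and the random-gene-set compactness null.

A network joins two genes whenever their two-tailed Spearman p-value
reaches the threshold (1e-3 and 1e-4 are the thresholds of interest for
candidate prioritization).  Whether the observed candidate+pathway network
is unusually compact is judged against an empirical null built by drawing
random gene sets of fixed size from the background transcriptome, building
a network per draw, and recording node and edge counts.  "Compactness" is
operationalized as the raw edge count, with edge density reported
alongside; the one-sided empirical p uses the add-one convention
(1 + #{null >= observed}) / (R + 1), so p is never zero at small R.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import networkx as nx
import numpy as np
import pandas as pd

from .rank_stats import spearman_matrix

__all__ = [
    "CoexpressionNetwork",
    "NullDistribution",
    "CompactnessResult",
    "build_network",
    "candidates_linked_to_pathway",
    "permutation_null",
    "compactness_test",
]


@dataclass
class CoexpressionNetwork:
    graph: nx.Graph                  # nodes carry a 'role' attribute
    p_threshold: float
    n_nodes: int                     # non-isolated by default
    n_edges: int
    include_isolated: bool = False

    @property
    def edge_density(self) -> float:
        if self.n_nodes < 2:
            return 0.0
        return self.n_edges / comb(self.n_nodes, 2)

    def edges(self):
        """Iterate (node_a, node_b, rho, p) tuples."""
        for a, b, data in self.graph.edges(data=True):
            yield a, b, data["rho"], data["p"]


@dataclass
class NullDistribution:
    records: list[tuple[int, int]]   # (n_nodes, n_edges) per replicate
    n_genes_per_draw: int
    n_reps: int
    seed: int
    p_threshold: float = 0.0

    @property
    def edge_counts(self) -> np.ndarray:
        return np.array([e for _, e in self.records])

    @property
    def node_counts(self) -> np.ndarray:
        return np.array([v for v, _ in self.records])


@dataclass
class CompactnessResult:
    empirical_p_edges: float
    z_edges: float
    empirical_p_nodes: float
    z_nodes: float
    observed_edges: int
    observed_nodes: int
    null_summary: dict = field(default_factory=dict)


def build_network(
    expr: pd.DataFrame,
    gene_set,
    p_threshold: float,
    roles: dict[str, str] | None = None,
    include_isolated: bool = False,
) -> CoexpressionNetwork:
    """Network over ``gene_set`` with an edge per pair at p <= threshold.

    ``roles`` optionally labels nodes (candidate/pathway); isolated nodes
    are excluded from ``n_nodes`` unless ``include_isolated`` is set,
    matching the convention of counting only genes that "form" a network.
    """
    genes = [g for g in gene_set]
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise ValueError(f"genes not in expression matrix: {missing[:5]}")
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to build a network")
    sub = expr.loc[genes].to_numpy(dtype=float)
    rho, p = spearman_matrix(sub)

    g = nx.Graph()
    for gene in genes:
        g.add_node(gene, role=(roles or {}).get(gene, "gene"))
    idx = np.triu_indices(len(genes), k=1)
    for i, j in zip(*idx):
        if p[i, j] <= p_threshold:
            g.add_edge(genes[i], genes[j], rho=float(rho[i, j]), p=float(p[i, j]))
    n_edges = g.number_of_edges()
    if include_isolated:
        n_nodes = g.number_of_nodes()
    else:
        n_nodes = sum(1 for n in g if g.degree(n) > 0)
    return CoexpressionNetwork(g, p_threshold, n_nodes, n_edges, include_isolated)


def candidates_linked_to_pathway(net: CoexpressionNetwork) -> set[str]:
    """Candidates with at least one edge to a pathway-role node."""
    out = set()
    for node, data in net.graph.nodes(data=True):
        if data.get("role") != "candidate":
            continue
        for nb in net.graph.neighbors(node):
            if net.graph.nodes[nb].get("role") == "pathway":
                out.add(node)
                break
    return out


def permutation_null(
    expr_all: pd.DataFrame,
    n_genes: int,
    n_reps: int,
    p_threshold: float,
    seed: int,
    include_isolated: bool = False,
) -> NullDistribution:
    """Null distribution of network size: draw ``n_genes`` uniformly without
    replacement from the pool, build a network, record (nodes, edges)."""
    pool = list(expr_all.index)
    if len(pool) < n_genes:
        raise ValueError(f"background pool ({len(pool)}) smaller than draw size {n_genes}")
    rng = np.random.default_rng(seed)
    records = []
    for _ in range(n_reps):
        draw = list(rng.choice(pool, size=n_genes, replace=False))
        net = build_network(expr_all, draw, p_threshold, include_isolated=include_isolated)
        records.append((net.n_nodes, net.n_edges))
    return NullDistribution(records, n_genes, n_reps, seed, p_threshold)


def _one_sided(observed: int, null_counts: np.ndarray) -> tuple[float, float]:
    r = null_counts.size
    p = (1.0 + int(np.sum(null_counts >= observed))) / (r + 1.0)
    sd = float(null_counts.std(ddof=1)) if r > 1 else 0.0
    z = (observed - float(null_counts.mean())) / sd if sd > 0 else float("nan")
    return p, z


def compactness_test(observed: CoexpressionNetwork, null: NullDistribution) -> CompactnessResult:
    """One-sided empirical test that the observed network is more compact
    (more edges; node counts reported alongside) than random gene sets."""
    if null.n_reps < 1:
        raise ValueError("null distribution has no replicates")
    p_e, z_e = _one_sided(observed.n_edges, null.edge_counts)
    p_v, z_v = _one_sided(observed.n_nodes, null.node_counts)
    return CompactnessResult(
        empirical_p_edges=p_e,
        z_edges=z_e,
        empirical_p_nodes=p_v,
        z_nodes=z_v,
        observed_edges=observed.n_edges,
        observed_nodes=observed.n_nodes,
        null_summary={
            "edges_mean": float(null.edge_counts.mean()),
            "edges_sd": float(null.edge_counts.std(ddof=1)) if null.n_reps > 1 else 0.0,
            "nodes_mean": float(null.node_counts.mean()),
            "n_reps": null.n_reps,
        },
    )
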