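"""Heatmap-style hierarchical co-clustering evidence line.

Candidates that fall into the same cluster as at least one pathway anchor
gene after cutting a complete-linkage Euclidean tree are taken as
co-expressed with the pathway.  Settings mirror the defaults of the
row-scaled clustered heatmaps common in this literature: log2(x+1), then
per-transcript z-score, Euclidean distance, complete linkage, tree cut
into k clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

log = logging.getLogger(__name__)

__all__ = ["ClusterAssignment", "preprocess_profiles", "hierarchical_cocluster", "cocluster_union"]


@dataclass
class ClusterAssignment:
    labels: dict[str, int]           # transcript -> cluster label
    linkage: np.ndarray              # scipy linkage matrix (merge heights)
    co_clustered: set[str]           # candidates sharing a cluster with >=1 pathway gene
    params: dict = field(default_factory=dict)


def preprocess_profiles(expr: pd.DataFrame) -> pd.DataFrame:
    """log2(x+1) then per-transcript z-score; zero-variance rows dropped."""
    if (expr.to_numpy() == 0).all():
        raise ValueError("all-zero expression matrix")
    logx = np.log2(expr.astype(float) + 1.0)
    sd = logx.std(axis=1, ddof=0)
    flat = sd[sd == 0].index.tolist()
    if flat:
        log.warning("dropping %d constant profile(s) from clustering: %s", len(flat), flat[:5])
    keep = logx.loc[sd > 0]
    return keep.sub(keep.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)


def hierarchical_cocluster(
    scaled: pd.DataFrame,
    candidates,
    pathway_genes,
    k: int = 10,
) -> ClusterAssignment:
    """Cut a complete-linkage Euclidean tree into k clusters; record which
    candidates share a cluster with a pathway gene."""
    rows = [g for g in scaled.index if g in set(candidates) | set(pathway_genes)]
    if len(rows) < 2:
        raise ValueError("need at least 2 transcripts to cluster")
    if not 1 <= k <= len(rows):
        raise ValueError(f"k={k} out of range for {len(rows)} transcripts")
    sub = scaled.loc[rows]
    link = hierarchy.linkage(sub.to_numpy(), method="complete", metric="euclidean")
    flat = hierarchy.fcluster(link, t=k, criterion="maxclust")
    labels = dict(zip(rows, (int(c) for c in flat)))
    pathway_clusters = {labels[g] for g in pathway_genes if g in labels}
    co = {g for g in candidates if g in labels and labels[g] in pathway_clusters}
    return ClusterAssignment(
        labels,
        link,
        co,
        params={"metric": "euclidean", "linkage": "complete", "k": k, "scaling": "row z-score of log2(x+1)"},
    )


def cocluster_union(panels, candidates, pathway_genes, k: int = 10) -> set[str]:
    """Evidence union over expression panels (e.g. tissue panel + age panel):
    a candidate qualifies if it co-clusters with the pathway in ANY panel."""
    out: set[str] = set()
    for expr in panels:
        scaled = preprocess_profiles(expr)
        out |= hierarchical_cocluster(scaled, candidates, pathway_genes, k).co_clustered
    return out
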