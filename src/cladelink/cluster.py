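"""Divergence-threshold clade clustering and tree simplification.

The clustering partitions the leaf set into maximal monophyletic clades whose
internal divergence does not exceed a threshold — exposing the most divergent
clades while grouping everything below the threshold.  Divergence of a clade
is summarised either as its diameter (maximum within-clade patristic distance,
``linkage="max"``) or as the mean within-clade pairwise distance
(``linkage="mean"``).

A single top-down pass from the root makes a node a cluster root iff its clade
divergence is ≤ the effective threshold while its parent's is not; a tie at
the threshold counts as qualifying.  Leaves always qualify (divergence 0), so
the result is always a partition.  The threshold may be given absolutely in
branch-length units, or as a fraction of the tree diameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .datalink import Classification
from .sequences import SequenceStore
from .tree import MissingBranchLengthError, Node, Tree, clade_stats, subtree_leaves

__all__ = [
    "ClusterConfig",
    "Cluster",
    "Clustering",
    "cluster_tree",
    "simplify_tree",
    "cluster_purity",
    "PurityResult",
    "cluster_table",
]

#: Default threshold: a quarter of the tree diameter, clade-diameter linkage.
DEFAULT_RELATIVE_FRACTION = 0.25


@dataclass(frozen=True)
class ClusterConfig:
    """Exactly one of ``threshold`` (absolute, branch-length units) or
    ``relative_fraction`` (of the tree diameter, in (0, 1]) must be set."""

    threshold: Optional[float] = None
    relative_fraction: Optional[float] = None
    linkage: str = "max"

    def __post_init__(self):
        if (self.threshold is None) == (self.relative_fraction is None):
            raise ValueError("set exactly one of threshold / relative_fraction")
        if self.threshold is not None and self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        if self.relative_fraction is not None and not 0 < self.relative_fraction <= 1:
            raise ValueError("relative_fraction must lie in (0, 1]")
        if self.linkage not in ("max", "mean"):
            raise ValueError("linkage must be 'max' or 'mean'")

    @classmethod
    def default(cls) -> "ClusterConfig":
        return cls(relative_fraction=DEFAULT_RELATIVE_FRACTION, linkage="max")


@dataclass
class Cluster:
    id: int
    node: Node  # defining clade root
    leaves: list[str]
    divergence: float

    @property
    def size(self) -> int:
        return len(self.leaves)


@dataclass
class Clustering:
    tree: Tree
    clusters: list[Cluster]
    effective_threshold: float
    config: ClusterConfig

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def leaf_to_cluster(self) -> dict[str, int]:
        return {leaf: c.id for c in self.clusters for leaf in c.leaves}

    def partition(self) -> list[frozenset[str]]:
        return [frozenset(c.leaves) for c in self.clusters]


def _divergence(stats, node: Node, linkage: str) -> float:
    cs = stats[node.id]
    if linkage == "max":
        return cs.diameter
    if cs.n_leaves < 2:
        return 0.0
    return cs.pair_sum / (cs.n_leaves * (cs.n_leaves - 1) / 2)


def cluster_tree(tree: Tree, config: ClusterConfig | None = None) -> Clustering:
    """Partition the leaves into maximal monophyletic clades below threshold.

    Requires branch lengths on every edge.  With a relative threshold on a
    zero-diameter tree the effective threshold is 0, which (under ``max``
    linkage with positive edges) makes every leaf a singleton cluster — the
    documented degenerate case.
    """
    if config is None:
        config = ClusterConfig.default()
    stats = clade_stats(tree)  # raises MissingBranchLengthError when lengths absent
    diameter = stats[tree.root.id].diameter if len(tree.leaves) >= 2 else 0.0
    if config.threshold is not None:
        threshold = config.threshold
    else:
        threshold = config.relative_fraction * diameter

    clusters: list[Cluster] = []

    def descend(node: Node) -> None:
        div = _divergence(stats, node, config.linkage)
        if div <= threshold:
            clusters.append(
                Cluster(
                    id=len(clusters) + 1,
                    node=node,
                    leaves=subtree_leaves(tree, node),
                    divergence=div,
                )
            )
            return
        for child in node.children:
            descend(child)

    descend(tree.root)
    return Clustering(
        tree=tree, clusters=clusters, effective_threshold=threshold, config=config
    )


def simplify_tree(tree: Tree, clustering: Clustering) -> Tree:
    """Collapse each cluster's clade into one leaf ``cluster_<id>_n<size>``.

    The replacement leaf's branch length is the clade's stem length plus the
    mean clade-root-to-leaf path length, so the average root-to-leaf depth of
    the collapsed members is preserved.  Internal structure above the clusters
    is kept unchanged.
    """
    if clustering.tree is not tree:
        raise ValueError("clustering was not produced from this tree")
    for c in clustering.clusters:
        if not tree.contains_node(c.node):
            raise ValueError(f"stale clustering: node {c.node.id} not in tree")
    stats = clade_stats(tree)
    by_node = {c.node.id: c for c in clustering.clusters}

    def build(node: Node) -> Node:
        c = by_node.get(node.id)
        if c is not None:
            cs = stats[node.id]
            mean_depth = cs.depth_sum / cs.n_leaves
            stem = node.parent_edge_length if node.parent_edge_length is not None else 0.0
            return Node(
                label=f"cluster_{c.id}_n{c.size}",
                parent_edge_length=stem + mean_depth,
            )
        out = Node(label=node.label, parent_edge_length=node.parent_edge_length)
        out.children = [build(ch) for ch in node.children]
        return out

    return Tree(build(tree.root))


@dataclass
class PurityResult:
    per_cluster: dict[int, float]
    overall: float  # leaf-weighted mean purity


def cluster_purity(clustering: Clustering, classification: Classification) -> PurityResult:
    """Majority-category fraction per cluster and leaf-weighted overall purity."""
    per: dict[int, float] = {}
    weighted = 0.0
    total = 0
    for c in clustering.clusters:
        counts: dict[str, int] = {}
        for leaf in c.leaves:
            try:
                cat = classification.assignment[leaf]
            except KeyError:
                raise ValueError(f"classification does not cover leaf {leaf!r}") from None
            counts[cat] = counts.get(cat, 0) + 1
        purity = max(counts.values()) / c.size
        per[c.id] = purity
        weighted += purity * c.size
        total += c.size
    overall = weighted / total if total else 1.0
    return PurityResult(per_cluster=per, overall=overall)


def cluster_table(
    clustering: Clustering, store: SequenceStore | None = None
) -> pd.DataFrame:
    """One row per leaf: leaf, cluster, divergence, cluster_size (CSV-writable).

    When a sequence store is supplied a ``has_sequence`` column marks leaves
    with a linked record; rows are ordered by cluster id then tree leaf order.
    """
    rows = []
    for c in clustering.clusters:
        for leaf in c.leaves:
            row = {
                "leaf": leaf,
                "cluster": c.id,
                "divergence": c.divergence,
                "cluster_size": c.size,
            }
            if store is not None:
                row["has_sequence"] = leaf in store
            rows.append(row)
    return pd.DataFrame(rows)
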