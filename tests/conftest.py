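"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own algorithms: patristic
distances are re-derived from a networkx node graph, parsimony scores and
optimal sets by exhaustive enumeration of internal assignments, and the
clustering by enumeration of every monophyletic partition (antichain of
clades covering the leaves).
"""

from __future__ import annotations

import itertools

import networkx as nx
import pytest

from cladelink import SimConfig, generate_tree, parse_newick
from cladelink.tree import Tree, Node


# ---------------------------------------------------------------------------
# Small hand-built trees
# ---------------------------------------------------------------------------


@pytest.fixture
def three_leaf_tree() -> Tree:
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def quartet_tree() -> Tree:
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


def random_tree(seed: int, n_leaves: int, model: str = "yule") -> Tree:
    return generate_tree(SimConfig(n_leaves=n_leaves, seed=seed, model=model))


# ---------------------------------------------------------------------------
# Distance oracle: shortest paths on the node graph
# ---------------------------------------------------------------------------


def nx_patristic(tree: Tree, a: str, b: str) -> float:
    g = nx.Graph()
    for node in tree.nodes:
        if node.parent is not None:
            g.add_edge(node.parent.id, node.id, weight=node.parent_edge_length)
    return nx.shortest_path_length(
        g, tree.leaf(a).id, tree.leaf(b).id, weight="weight"
    )


# ---------------------------------------------------------------------------
# Parsimony oracle: exhaustive enumeration of internal assignments
# ---------------------------------------------------------------------------


def brute_force_parsimony(tree: Tree, leaf_states: dict[str, str], cost=None):
    """(min score, node id -> set of states in some minimum-cost assignment).

    ``cost`` maps a state pair to a cost; default is unit cost.
    """
    if cost is None:
        cost = lambda a, b: 0 if a == b else 1
    states = sorted({v for v in leaf_states.values()})
    internal = [n for n in tree.nodes if not n.is_leaf]
    fixed = {n.id: leaf_states[n.label] for n in tree.nodes if n.is_leaf}
    edges = [(n.parent.id, n.id) for n in tree.nodes if n.parent is not None]

    best = float("inf")
    optimal: dict[int, set[str]] = {n.id: set() for n in tree.nodes}
    for combo in itertools.product(states, repeat=len(internal)):
        assign = dict(fixed)
        assign.update({n.id: s for n, s in zip(internal, combo)})
        score = sum(cost(assign[p], assign[c]) for p, c in edges)
        if score < best - 1e-12:
            best = score
            optimal = {nid: {assign[nid]} for nid in assign}
        elif abs(score - best) <= 1e-12:
            for nid in assign:
                optimal[nid].add(assign[nid])
    return best, optimal


# ---------------------------------------------------------------------------
# Clustering oracle: enumerate all monophyletic partitions
# ---------------------------------------------------------------------------


def all_clade_partitions(tree: Tree):
    """Every antichain of clades covering the leaf set, as lists of Nodes."""

    def rec(node: Node):
        yield [node]
        if node.children:
            for combo in itertools.product(*(list(rec(c)) for c in node.children)):
                yield [part for sub in combo for part in sub]

    return rec(tree.root)


def brute_force_min_partition(tree: Tree, threshold: float):
    """Minimum-cardinality monophyletic partition with clade diameters ≤ threshold.

    Diameters come from the networkx distance oracle.  Returns the partition
    as a set of frozensets of leaf labels (unique minimum, see tests).
    """
    labels = tree.leaf_labels
    dist = {
        (a, b): nx_patristic(tree, a, b)
        for a, b in itertools.combinations(labels, 2)
    }

    def clade_diameter(node: Node) -> float:
        leaves = [n.label for n in node.preorder() if n.is_leaf]
        if len(leaves) < 2:
            return 0.0
        return max(
            dist[(a, b)] if (a, b) in dist else dist[(b, a)]
            for a, b in itertools.combinations(leaves, 2)
        )

    best = None
    for parts in all_clade_partitions(tree):
        if all(clade_diameter(p) <= threshold for p in parts):
            if best is None or len(parts) < len(best):
                best = parts
    assert best is not None, "singleton partition always qualifies"
    return {
        frozenset(n.label for n in part.preorder() if n.is_leaf) for part in best
    }
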