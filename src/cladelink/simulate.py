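"""Synthetic trees and simulated characters for testing and demos.

Everything is a pure function of its configuration and seed (numpy
``default_rng``; no global random state), so every fixture is
bit-reproducible.

Generators:

* random topologies — Yule (random leaf split) or balanced — with
  exponentially distributed branch lengths;
* discrete characters evolved by a constant-rate jump process along edges;
* continuous characters evolved by Brownian motion;
* a clustered "subtype" fixture: k tight clades on long stems, with the
  matching metadata table and dummy sequences, guaranteeing that
  divergence-threshold clustering recovers the clades exactly for any
  threshold between the within-clade diameter and the stem separation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datalink import DataTable
from .sequences import SequenceStore
from .tree import Node, Tree

__all__ = [
    "SimConfig",
    "generate_tree",
    "simulate_discrete",
    "simulate_bm",
    "make_clustered_fixture",
]

#: Default branch-length scale (expected edge length, substitutions/site) —
#: typical of intra-species viral phylogenies.
DEFAULT_BRANCH_SCALE = 0.1


@dataclass(frozen=True)
class SimConfig:
    n_leaves: int
    seed: int
    model: str = "yule"
    branch_scale: float = DEFAULT_BRANCH_SCALE

    def __post_init__(self):
        if self.n_leaves < 2:
            raise ValueError("n_leaves must be >= 2")
        if self.model not in ("yule", "balanced"):
            raise ValueError("model must be 'yule' or 'balanced'")
        if self.branch_scale <= 0:
            raise ValueError("branch_scale must be positive")


def generate_tree(config: SimConfig) -> Tree:
    """Random tree with labels t1..tn and exponential branch lengths."""
    rng = np.random.default_rng(config.seed)
    if config.model == "yule":
        root = Node()
        root.children = [Node(), Node()]
        leaves = list(root.children)
        while len(leaves) < config.n_leaves:
            pick = int(rng.integers(len(leaves)))
            node = leaves.pop(pick)
            node.children = [Node(), Node()]
            leaves.extend(node.children)
    else:  # balanced

        def split(n: int) -> Node:
            node = Node()
            if n == 1:
                return node
            left = (n + 1) // 2
            node.children = [split(left), split(n - left)]
            return node

        root = split(config.n_leaves)

    counter = 0
    for node in root.preorder():
        if node is not root:
            node.parent_edge_length = float(rng.exponential(config.branch_scale))
        if not node.children:
            counter += 1
            node.label = f"t{counter}"
    return Tree(root)


def simulate_discrete(
    tree: Tree, states: list[str], rate: float, seed: int
) -> tuple[dict[str, str], dict[int, str]]:
    """Jump-process character: along an edge of length t the state changes
    with probability 1 − exp(−rate·t), to a uniform different state.

    Returns (leaf label → state, true node id → state); the root state is
    uniform over ``states``.
    """
    if len(states) < 2:
        raise ValueError("need at least 2 states")
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    true: dict[int, str] = {}
    for node in tree.root.preorder():
        if node.parent is None:
            true[node.id] = states[int(rng.integers(len(states)))]
            continue
        t = node.parent_edge_length
        if t is None:
            raise ValueError(f"node {node.id} has no branch length")
        parent_state = true[node.parent.id]
        if rng.random() < 1.0 - np.exp(-rate * t):
            others = [s for s in states if s != parent_state]
            true[node.id] = others[int(rng.integers(len(others)))]
        else:
            true[node.id] = parent_state
    leaf_states = {n.label: true[n.id] for n in tree.leaves}
    return leaf_states, true


def simulate_bm(
    tree: Tree, sigma2: float, root_value: float, seed: int
) -> tuple[dict[str, float], dict[int, float]]:
    """Brownian motion: child ~ Normal(parent, sigma²·edge length), pre-order.

    Returns (leaf label → value, true node id → value).
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    rng = np.random.default_rng(seed)
    true: dict[int, float] = {}
    for node in tree.root.preorder():
        if node.parent is None:
            true[node.id] = float(root_value)
            continue
        t = node.parent_edge_length
        if t is None:
            raise ValueError(f"node {node.id} has no branch length")
        true[node.id] = float(rng.normal(true[node.parent.id], np.sqrt(sigma2 * t)))
    leaf_values = {n.label: true[n.id] for n in tree.leaves}
    return leaf_values, true


def _dummy_sequence(label: str, length: int = 60) -> str:
    """Deterministic dummy nucleotide 60-mer derived from the label."""
    digest = hashlib.sha256(label.encode()).digest()
    bases = "ACGT"
    return "".join(bases[digest[i % len(digest)] >> (2 * (i % 4)) & 3] for i in range(length))


def make_clustered_fixture(
    k: int, n: int, d_in: float, separation: float, seed: int
) -> tuple[Tree, DataTable, SequenceStore]:
    """k well-separated rake-like clades of n leaves each.

    Each clade is a star of pendant edges drawn uniformly from
    [d_in/4, d_in/2] (so the within-clade diameter is ≤ d_in) hanging from a
    stem of length separation/2 off the root: any two leaves in different
    clades are ≥ separation apart.  The metadata table carries the generating
    clade in its ``subtype`` column; dummy sequences accompany every leaf.
    """
    if not separation > d_in > 0:
        raise ValueError("need separation > d_in > 0")
    if k < 2 or n < 1:
        raise ValueError("need k >= 2 clades of n >= 1 leaves")
    rng = np.random.default_rng(seed)
    root = Node()
    rows = []
    counter = 0
    for ci in range(1, k + 1):
        clade = Node(parent_edge_length=separation / 2)
        for _ in range(n):
            counter += 1
            label = f"t{counter}"
            clade.children.append(
                Node(
                    label=label,
                    parent_edge_length=float(rng.uniform(d_in / 4, d_in / 2)),
                )
            )
            rows.append({"id": label, "subtype": f"clade{ci}"})
        root.children.append(clade)
    tree = Tree(root)
    table = DataTable(pd.DataFrame(rows), key_column="id")
    store = SequenceStore(
        (r["id"], r["id"], _dummy_sequence(r["id"])) for r in rows
    )
    return tree, table, store
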