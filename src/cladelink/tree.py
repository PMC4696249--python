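"""Rooted phylogenetic trees: Newick parsing/writing, traversal, patristic distances.

The tree model is deliberately small and strict:

* exactly one root; every other node has exactly one parent;
* leaf labels are unique (duplicates are a parse error);
* a missing branch length is stored as ``None``, never silently as ``0.0`` —
  distance operations fail loudly when a needed length is absent;
* node ids are assigned in depth-first pre-order so that every enumeration of
  nodes is deterministic and stable under round-tripping.

Unrooted Newick (a basal trifurcation) is accepted as-is and treated as rooted
at the basal polytomy; no rerooting is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

__all__ = [
    "Node",
    "Tree",
    "NewickError",
    "MissingBranchLengthError",
    "parse_newick",
    "write_newick",
    "patristic_distance",
    "subtree_leaves",
    "tree_diameter",
]


class NewickError(ValueError):
    """Malformed Newick input; carries the 0-based character offset."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (at character offset {offset})"
        super().__init__(message)
        self.offset = offset


class MissingBranchLengthError(ValueError):
    """A distance operation needed a branch length that is absent."""


@dataclass(eq=False)
class Node:
    """A tree node. ``parent_edge_length`` is ``None`` when absent in the source."""

    id: int = -1
    label: Optional[str] = None
    parent_edge_length: Optional[float] = None
    children: list["Node"] = field(default_factory=list)
    parent: Optional["Node"] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out: list[Node] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.id} {kind} label={self.label!r}>"


class Tree:
    """A rooted tree with uniquely labelled leaves.

    Construct via :func:`parse_newick` or :meth:`Tree.from_root`; both assign
    stable pre-order node ids and validate leaf-label uniqueness.
    """

    def __init__(self, root: Node):
        self.root = root
        self.rooted = True
        self._reindex()

    @classmethod
    def from_root(cls, root: Node) -> "Tree":
        return cls(root)

    def _reindex(self) -> None:
        self._nodes: list[Node] = []
        seen_labels: set[str] = set()
        for i, node in enumerate(self.root.preorder()):
            node.id = i
            for child in node.children:
                child.parent = node
            self._nodes.append(node)
            if node.is_leaf:
                if node.label is None or node.label == "":
                    raise NewickError("leaf without a label")
                if node.label in seen_labels:
                    raise NewickError(f"duplicate leaf label {node.label!r}")
                seen_labels.add(node.label)
        self.root.parent = None
        self._leaf_index = {n.label: n for n in self._nodes if n.is_leaf}

    @property
    def nodes(self) -> list[Node]:
        """All nodes in pre-order (root first)."""
        return list(self._nodes)

    @property
    def leaves(self) -> list[Node]:
        """Leaves in pre-order (i.e. left-to-right tree order)."""
        return [n for n in self._nodes if n.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves]  # type: ignore[misc]

    def __len__(self) -> int:
        return len(self._nodes)

    def node(self, node_id: int) -> Node:
        if not 0 <= node_id < len(self._nodes):
            raise KeyError(f"no node with id {node_id}")
        return self._nodes[node_id]

    def leaf(self, label: str) -> Node:
        try:
            return self._leaf_index[label]
        except KeyError:
            raise KeyError(f"no leaf labelled {label!r}") from None

    def has_leaf(self, label: str) -> bool:
        return label in self._leaf_index

    def contains_node(self, node: Node) -> bool:
        return 0 <= node.id < len(self._nodes) and self._nodes[node.id] is node

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            c = Node(label=node.label, parent_edge_length=node.parent_edge_length)
            c.children = [clone(ch) for ch in node.children]
            return c

        return Tree(clone(self.root))

    def depths(self, unit: bool = False) -> dict[int, float]:
        """Root-to-node path lengths; ``unit=True`` counts edges instead.

        Raises :class:`MissingBranchLengthError` on an absent length unless
        ``unit`` is set.
        """
        out = {self.root.id: 0.0}
        for node in self.root.preorder():
            if node is self.root:
                continue
            if unit:
                step = 1.0
            else:
                if node.parent_edge_length is None:
                    raise MissingBranchLengthError(
                        f"node {node.id} ({node.label or 'internal'}) has no branch length"
                    )
                step = node.parent_edge_length
            out[node.id] = out[node.parent.id] + step  # type: ignore[union-attr]
        return out

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Tree with {len(self.leaves)} leaves, {len(self._nodes)} nodes>"


# ---------------------------------------------------------------------------
# Newick parsing
# ---------------------------------------------------------------------------

_UNQUOTED_TERMINATORS = set("(),:;'[]")


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, msg: str) -> NewickError:
        return NewickError(msg, offset=self.pos)

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def parse(self) -> Node:
        self.skip_ws()
        if self.pos >= len(self.text):
            raise self.error("empty Newick input")
        root = self.parse_clade()
        self.skip_ws()
        if self.peek() != ";":
            raise self.error("expected ';' at end of tree (unbalanced parentheses?)")
        self.pos += 1
        self.skip_ws()
        if self.pos < len(self.text):
            raise self.error("trailing content after ';' — only one tree per input is supported")
        return root

    def parse_clade(self) -> Node:
        self.skip_ws()
        node = Node()
        if self.peek() == "(":
            self.pos += 1
            while True:
                node.children.append(self.parse_clade())
                self.skip_ws()
                ch = self.peek()
                if ch == ",":
                    self.pos += 1
                    continue
                if ch == ")":
                    self.pos += 1
                    break
                raise self.error("expected ',' or ')' inside clade")
            node.label = self.parse_label(optional=True)
        else:
            label = self.parse_label(optional=False)
            node.label = label
        self.skip_ws()
        if self.peek() == ":":
            self.pos += 1
            node.parent_edge_length = self.parse_length()
        return node

    def parse_label(self, optional: bool) -> Optional[str]:
        self.skip_ws()
        ch = self.peek()
        if ch == "'":
            return self.parse_quoted()
        start = self.pos
        while self.pos < len(self.text):
            c = self.text[self.pos]
            if c in _UNQUOTED_TERMINATORS or c.isspace():
                break
            self.pos += 1
        label = self.text[start : self.pos]
        if not label:
            if optional:
                return None
            raise self.error("expected a leaf label")
        return label  # underscores kept literal by design

    def parse_quoted(self) -> str:
        assert self.peek() == "'"
        self.pos += 1
        out: list[str] = []
        while True:
            if self.pos >= len(self.text):
                raise self.error("unterminated quoted label")
            c = self.text[self.pos]
            if c == "'":
                if self.pos + 1 < len(self.text) and self.text[self.pos + 1] == "'":
                    out.append("'")
                    self.pos += 2
                    continue
                self.pos += 1
                break
            out.append(c)
            self.pos += 1
        return "".join(out)

    def parse_length(self) -> float:
        self.skip_ws()
        start = self.pos
        while self.pos < len(self.text) and (
            self.text[self.pos] not in _UNQUOTED_TERMINATORS
            and not self.text[self.pos].isspace()
        ):
            self.pos += 1
        token = self.text[start : self.pos]
        try:
            value = float(token)
        except ValueError:
            self.pos = start
            raise self.error(f"invalid branch length {token!r}") from None
        if value < 0:
            self.pos = start
            raise self.error(f"negative branch length {token!r}")
        return value


def parse_newick(text: str) -> Tree:
    """Parse a single Newick statement into a :class:`Tree`.

    Quoted labels are unquoted (with ``''`` → ``'``); internal labels are
    retained; child order is preserved. Errors report the character offset.
    """
    if not isinstance(text, str):
        raise TypeError("parse_newick expects a string")
    root = _Parser(text).parse()
    return Tree(root)


def _format_length(value: float) -> str:
    return format(value, ".10g")


def _format_label(label: str) -> str:
    if label == "" or any(c in _UNQUOTED_TERMINATORS or c.isspace() for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree) -> str:
    """Serialize a tree to Newick. Write∘parse∘write is byte-stable."""

    def emit(node: Node) -> str:
        if node.children:
            inner = ",".join(emit(c) for c in node.children)
            s = f"({inner})"
            if node.label:
                s += _format_label(node.label)
        else:
            s = _format_label(node.label or "")
        if node.parent_edge_length is not None:
            s += ":" + _format_length(node.parent_edge_length)
        return s

    return emit(tree.root) + ";"


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def _path_to_root(node: Node) -> list[Node]:
    path = [node]
    while path[-1].parent is not None:
        path.append(path[-1].parent)
    return path


def _edge_length(node: Node) -> float:
    if node.parent_edge_length is None:
        raise MissingBranchLengthError(
            f"branch above node {node.id} ({node.label or 'internal'}) has no length"
        )
    return node.parent_edge_length


def mrca(tree: Tree, a: Node, b: Node) -> Node:
    """Most recent common ancestor of two nodes."""
    ancestors_a = set(id(n) for n in _path_to_root(a))
    for n in _path_to_root(b):
        if id(n) in ancestors_a:
            return n
    raise ValueError("nodes share no ancestor — not in the same tree")


def patristic_distance(tree: Tree, a: str, b: str) -> float:
    """Sum of branch lengths on the unique path between leaves ``a`` and ``b``.

    Symmetric; ``d(a, a) == 0``. Raises ``KeyError`` for unknown labels and
    :class:`MissingBranchLengthError` when an edge on the path lacks a length
    (never silently treated as 0).
    """
    na, nb = tree.leaf(a), tree.leaf(b)
    if na is nb:
        return 0.0
    anc = mrca(tree, na, nb)
    total = 0.0
    for node in (na, nb):
        while node is not anc:
            total += _edge_length(node)
            node = node.parent  # type: ignore[assignment]
    return total


def subtree_leaves(tree: Tree, node: Node | int) -> list[str]:
    """Leaf labels descending from ``node`` (itself if a leaf), in tree order."""
    if isinstance(node, int):
        node = tree.node(node)
    elif not tree.contains_node(node):
        raise KeyError("node does not belong to this tree")
    return [n.label for n in node.preorder() if n.is_leaf]  # type: ignore[misc]


@dataclass
class _CladeStats:
    n_leaves: int
    max_depth: float  # deepest leaf below the clade root
    diameter: float  # max within-clade leaf-pair patristic distance
    depth_sum: float  # sum of clade-root-to-leaf distances
    pair_sum: float  # sum over within-clade leaf pairs of patristic distances


def clade_stats(tree: Tree) -> dict[int, _CladeStats]:
    """Per-node leaf counts, depth maxima/sums, clade diameters and pair sums.

    One post-order pass; requires branch lengths on every edge below an
    internal node with ≥ 1 leaf descendant (i.e. all edges).
    """
    stats: dict[int, _CladeStats] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            stats[node.id] = _CladeStats(1, 0.0, 0.0, 0.0, 0.0)
            continue
        diameter = 0.0
        depths: list[float] = []
        n_total = 0
        depth_sum = 0.0
        pair_sum = 0.0
        cum_n = 0
        cum_adj = 0.0  # sum over previous children of (depth_sum_i + n_i * e_i)
        for child in node.children:
            cs = stats[child.id]
            e = _edge_length(child)
            d = cs.max_depth + e
            depths.append(d)
            diameter = max(diameter, cs.diameter)
            adj = cs.depth_sum + cs.n_leaves * e
            pair_sum += cs.pair_sum + cum_n * adj + cs.n_leaves * cum_adj
            cum_n += cs.n_leaves
            cum_adj += adj
            n_total += cs.n_leaves
            depth_sum += adj
        depths.sort(reverse=True)
        if len(depths) >= 2:
            diameter = max(diameter, depths[0] + depths[1])
        stats[node.id] = _CladeStats(n_total, depths[0], diameter, depth_sum, pair_sum)
    return stats


def tree_diameter(tree: Tree) -> float:
    """Maximum patristic distance over all leaf pairs (0 for < 2 leaves)."""
    if len(tree.leaves) < 2:
        return 0.0
    return clade_stats(tree)[tree.root.id].diameter
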