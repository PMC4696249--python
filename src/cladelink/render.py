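"""Deterministic rectangular (phylogram) layout and static SVG export.

The layout places each node at x = cumulative branch length from the root
(unit edge lengths when the tree carries none) scaled to the canvas, and at
y = leaf index for leaves / mean of children's y for internal nodes.  The SVG
writer is a pure function of its inputs — no timestamps, no randomness — so
identical inputs give byte-identical documents.

Decorations: a Classification colours leaves by category with a legend (the
fixed 9-colour palette cycles, with a warning, past 9 categories); a
cross-reference set highlights matching leaves; a Clustering draws a labelled
box around every cluster clade.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from xml.sax.saxutils import escape

from .cluster import Clustering
from .datalink import Classification
from .tree import MissingBranchLengthError, Tree

__all__ = ["Layout", "layout_tree", "render_svg", "PALETTE"]

#: Fixed 9-colour palette (qualitative, colour-blind-conscious).
PALETTE = [
    "#e41a1c",
    "#377eb8",
    "#4daf4a",
    "#984ea3",
    "#ff7f00",
    "#a65628",
    "#f781bf",
    "#999999",
    "#66c2a5",
]

_LABEL_GUTTER = 140  # px reserved for leaf labels on the right


@dataclass
class Layout:
    tree: Tree
    x: dict[int, float]
    y: dict[int, float]
    width: float
    height: float
    margin: float


def layout_tree(tree: Tree, width: float = 800, height: float = 600, margin: float = 20) -> Layout:
    """Rectangular layout. Falls back to unit edge lengths when any is absent."""
    try:
        depths = tree.depths()
    except MissingBranchLengthError:
        depths = tree.depths(unit=True)
    max_depth = max(depths.values()) or 1.0
    span_x = width - 2 * margin - _LABEL_GUTTER
    x = {nid: margin + span_x * d / max_depth for nid, d in depths.items()}

    leaves = tree.leaves
    span_y = height - 2 * margin
    if len(leaves) == 1:
        ys = {leaves[0].id: margin + span_y / 2}
    else:
        step = span_y / (len(leaves) - 1)
        ys = {leaf.id: margin + i * step for i, leaf in enumerate(leaves)}
    y: dict[int, float] = dict(ys)
    for node in tree.root.postorder():
        if not node.is_leaf:
            y[node.id] = sum(y[c.id] for c in node.children) / len(node.children)
    return Layout(tree=tree, x=x, y=y, width=width, height=height, margin=margin)


def _f(v: float) -> str:
    return f"{v:.2f}"


def render_svg(
    layout: Layout,
    classification: Classification | None = None,
    highlight: set[str] | None = None,
    clustering: Clustering | None = None,
) -> str:
    """Render the laid-out tree as an SVG 1.1 document string.

    Every leaf label becomes exactly one ``<text>`` element; every edge one
    ``<path>`` (vertical-then-horizontal elbow) plus a short root stub.
    """
    tree = layout.tree
    x, y = layout.x, layout.y

    colors: dict[str, str] = {}
    legend: list[tuple[str, str]] = []
    if classification is not None:
        if len(classification.legend) > len(PALETTE):
            warnings.warn(
                f"{len(classification.legend)} categories exceed the "
                f"{len(PALETTE)}-colour palette; colours will cycle",
                stacklevel=2,
            )
        for category, i in classification.legend:
            colors[category] = PALETTE[i % len(PALETTE)]
            legend.append((category, colors[category]))

    parts: list[str] = []
    parts.append(
        '<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_f(layout.width)}" height="{_f(layout.height)}" '
        f'viewBox="0 0 {_f(layout.width)} {_f(layout.height)}">'
    )
    parts.append(
        "<style>path{stroke:#333;fill:none;stroke-width:1.5}"
        "text{font-family:sans-serif;font-size:11px}</style>"
    )

    if clustering is not None:
        parts.append('<g class="clusters">')
        for c in clustering.clusters:
            leaf_ids = [tree.leaf(l).id for l in c.leaves]
            x0 = x[c.node.id] - 3
            x1 = max(x[i] for i in leaf_ids) + 6
            y0 = min(y[i] for i in leaf_ids) - 7
            y1 = max(y[i] for i in leaf_ids) + 7
            parts.append(
                f'<rect x="{_f(x0)}" y="{_f(y0)}" width="{_f(x1 - x0)}" '
                f'height="{_f(y1 - y0)}" fill="#dddddd" fill-opacity="0.5" '
                'stroke="#888888" stroke-dasharray="3,2"/>'
            )
            parts.append(
                f'<text x="{_f(x1 + 4)}" y="{_f((y0 + y1) / 2 + 4)}" '
                f'fill="#555555">cluster {c.id} (n={c.size})</text>'
            )
        parts.append("</g>")

    parts.append('<g class="edges">')
    # root stub: short horizontal lead-in to the root
    rx, ry = x[tree.root.id], y[tree.root.id]
    parts.append(f'<path d="M {_f(rx - 8)} {_f(ry)} H {_f(rx)}"/>')
    for node in tree.nodes:
        if node.parent is None:
            continue
        px, py = x[node.parent.id], y[node.parent.id]
        parts.append(
            f'<path d="M {_f(px)} {_f(py)} V {_f(y[node.id])} H {_f(x[node.id])}"/>'
        )
    parts.append("</g>")

    if highlight:
        parts.append('<g class="highlight">')
        for leaf in tree.leaves:
            if leaf.label in highlight:
                parts.append(
                    f'<circle cx="{_f(x[leaf.id] + 3)}" cy="{_f(y[leaf.id])}" '
                    'r="4" fill="#ffcc00" stroke="#996600"/>'
                )
        parts.append("</g>")

    parts.append('<g class="labels">')
    for leaf in tree.leaves:
        fill = ""
        if classification is not None:
            category = classification.assignment[leaf.label]
            fill = f' fill="{colors[category]}"'
        parts.append(
            f'<text x="{_f(x[leaf.id] + 9)}" y="{_f(y[leaf.id] + 4)}"{fill}>'
            f"{escape(leaf.label)}</text>"
        )
    parts.append("</g>")

    if legend:
        parts.append('<g class="legend">')
        lx = layout.width - _LABEL_GUTTER + 10
        for i, (category, color) in enumerate(legend):
            ly = layout.margin + 16 * i
            parts.append(
                f'<rect x="{_f(lx)}" y="{_f(ly)}" width="10" height="10" '
                f'fill="{color}"/>'
            )
            parts.append(
                f'<text x="{_f(lx + 14)}" y="{_f(ly + 9)}">{escape(category)}</text>'
            )
        parts.append("</g>")

    parts.append("</svg>")
    return "\n".join(parts) + "\n"
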