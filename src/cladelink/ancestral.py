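"""Ancestral character state reconstruction and phylogeographic export.

Discrete characters (e.g. sampling country) are reconstructed by parsimony:
the Fitch algorithm for unordered states (Hartigan's generalization on
multifurcations) and the Sankoff dynamic program for an arbitrary cost
matrix — linear parsimony is the special case of cost ``|i - j|`` on ordered
numeric states.  Ambiguity is resolved by ACCTRAN (changes pulled toward the
root) or DELTRAN (changes delayed away from the root), with lexicographic
tie-breaks so outputs are bit-reproducible.

Continuous characters are reconstructed by maximum likelihood under Brownian
motion: ancestral values are the branch-length-weighted averages solving the
tree's weighted least-squares system (equivalently the GLS solution), the
rate sigma² is its ML estimate from the phylogenetic covariance, and each
internal node carries a conditional variance.

A transition table turns a resolved discrete reconstruction into per-edge
state movements with times equal to cumulative root-to-node path lengths,
optionally geocoded through a gazetteer, and exportable as GeoJSON.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .tree import MissingBranchLengthError, Node, Tree, tree_diameter

__all__ = [
    "CostMatrix",
    "ParsimonyResult",
    "fitch",
    "sankoff",
    "resolve",
    "BMResult",
    "bm_ancestral",
    "TransitionTable",
    "phylogeo_transitions",
    "read_gazetteer",
]

ACCTRAN = "acctran"
DELTRAN = "deltran"


def _check_leaf_states(tree: Tree, chr: Mapping[str, str]) -> list[str]:
    missing = [l for l in tree.leaf_labels if l not in chr]
    if missing:
        raise ValueError(f"leaves without a character state: {missing}")
    return sorted({chr[l] for l in tree.leaf_labels})


class CostMatrix:
    """Square non-negative state-change cost matrix with zero diagonal."""

    def __init__(self, states: Sequence[str], matrix, symmetric: bool = True):
        self.states = list(states)
        self.matrix = np.asarray(matrix, dtype=float)
        k = len(self.states)
        if self.matrix.shape != (k, k):
            raise ValueError("cost matrix shape does not match state count")
        if (self.matrix < 0).any():
            raise ValueError("costs must be non-negative")
        if np.diag(self.matrix).any():
            raise ValueError("diagonal costs must be zero")
        if symmetric and not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("matrix is not symmetric (pass symmetric=False to allow)")
        self.symmetric = symmetric
        self._index = {s: i for i, s in enumerate(self.states)}

    @classmethod
    def unit(cls, states: Sequence[str]) -> "CostMatrix":
        k = len(states)
        return cls(states, np.ones((k, k)) - np.eye(k))

    @classmethod
    def linear(cls, states: Sequence[str]) -> "CostMatrix":
        """Ordered-character cost ``|i - j|`` using the numeric value of each
        state label (falling back to lexicographic rank if non-numeric)."""
        try:
            values = [float(s) for s in states]
        except ValueError:
            values = list(range(len(sorted(states))))
            states = sorted(states)
        order = np.argsort(values, kind="stable")
        states = [list(states)[i] for i in order]
        values = [values[i] for i in order]
        v = np.asarray(values)
        return cls(states, np.abs(v[:, None] - v[None, :]))

    def index(self, state: str) -> int:
        try:
            return self._index[state]
        except KeyError:
            raise ValueError(f"state {state!r} missing from cost matrix") from None


@dataclass
class ParsimonyResult:
    """Minimum-cost reconstruction summary.

    ``state_sets`` holds the Fitch downpass sets (unit cost) or, for Sankoff,
    the per-state minimal subtree costs.  ``optimal_states`` is, for every
    node, the set of states attained by at least one minimum-cost
    reconstruction.  Use :func:`resolve` to pick a single state per node.
    """

    tree: Tree
    states: list[str]
    score: float
    state_sets: dict[int, object]
    optimal_states: dict[int, set[str]]
    _down: np.ndarray = field(repr=False, default=None)
    _costs: "CostMatrix" = field(repr=False, default=None)
    method: str = "fitch"


def _sankoff_down(tree: Tree, chr: Mapping[str, str], costs: CostMatrix) -> np.ndarray:
    """Per-node per-state minimal subtree cost (rows indexed by node id)."""
    k = len(costs.states)
    down = np.full((len(tree.nodes), k), np.inf)
    for node in tree.root.postorder():
        if node.is_leaf:
            down[node.id, costs.index(chr[node.label])] = 0.0
        else:
            total = np.zeros(k)
            for child in node.children:
                # min over child state t of cost(s, t) + down[child, t]
                total += (costs.matrix + down[child.id][None, :]).min(axis=1)
            down[node.id] = total
    return down


def _optimal_sets(tree: Tree, down: np.ndarray, costs: CostMatrix) -> dict[int, set[str]]:
    """States realized by at least one minimum-cost reconstruction, per node.

    Inside/outside dynamic program: ``up[v, s]`` is the minimal cost of the
    rest of the tree given node v takes state s; a state is optimal iff
    ``down + up == score``.
    """
    k = len(costs.states)
    up = np.zeros((len(tree.nodes), k))
    score = down[tree.root.id].min()
    for node in tree.root.preorder():
        if node.is_leaf:
            continue
        # contribution of each child to down[node]: child_min[c, s]
        child_min = {
            c.id: (costs.matrix + down[c.id][None, :]).min(axis=1)
            for c in node.children
        }
        base = up[node.id] + sum(child_min.values())
        for child in node.children:
            # parent cost excluding this child, then min over parent state s
            excl = base - child_min[child.id]  # indexed by parent state s
            up[child.id] = (excl[:, None] + costs.matrix).min(axis=0)
    total = down + up
    tol = 1e-9 * max(1.0, abs(score))
    return {
        n.id: {costs.states[j] for j in np.flatnonzero(total[n.id] <= score + tol)}
        for n in tree.nodes
    }


def fitch(tree: Tree, chr: Mapping[str, str]) -> ParsimonyResult:
    """Unordered-parsimony score and state sets (Hartigan on multifurcations).

    The downpass keeps, at each internal node, the states appearing in the
    maximal number of child sets; the score grows by (children − that count).
    On binary nodes this is the classic intersection/union rule.
    """
    states = _check_leaf_states(tree, chr)
    down_sets: dict[int, frozenset[str]] = {}
    score = 0
    for node in tree.root.postorder():
        if node.is_leaf:
            down_sets[node.id] = frozenset({chr[node.label]})
            continue
        counts: dict[str, int] = {}
        for child in node.children:
            for s in down_sets[child.id]:
                counts[s] = counts.get(s, 0) + 1
        top = max(counts.values())
        down_sets[node.id] = frozenset(s for s, c in counts.items() if c == top)
        score += len(node.children) - top
    costs = CostMatrix.unit(states)
    down = _sankoff_down(tree, chr, costs)
    return ParsimonyResult(
        tree=tree,
        states=states,
        score=score,
        state_sets={i: set(s) for i, s in down_sets.items()},
        optimal_states=_optimal_sets(tree, down, costs),
        _down=down,
        _costs=costs,
        method="fitch",
    )


def sankoff(tree: Tree, chr: Mapping[str, str], costs: CostMatrix) -> ParsimonyResult:
    """General-cost parsimony by dynamic programming over the cost matrix."""
    observed = _check_leaf_states(tree, chr)
    for s in observed:
        costs.index(s)  # raises for states missing from the matrix
    down = _sankoff_down(tree, chr, costs)
    score = float(down[tree.root.id].min())
    return ParsimonyResult(
        tree=tree,
        states=list(costs.states),
        score=score,
        state_sets={n.id: dict(zip(costs.states, down[n.id])) for n in tree.nodes},
        optimal_states=_optimal_sets(tree, down, costs),
        _down=down,
        _costs=costs,
        method="sankoff",
    )


def resolve(tree: Tree, pars: ParsimonyResult, rule: str = DELTRAN) -> dict[int, str]:
    """Pick one state per node by ACCTRAN or DELTRAN, ties lexicographic.

    A pre-order traceback of the dynamic program: at each node the candidate
    states are those minimizing (change cost from the parent's resolved state)
    + (subtree cost), so any choice preserves the optimal total score.
    DELTRAN takes the parent's state whenever it is a candidate (delaying
    changes tipward); ACCTRAN takes a differing candidate whenever one exists
    (accelerating changes rootward).  Leaves keep their observed states.
    """
    if rule not in (ACCTRAN, DELTRAN):
        raise ValueError(f"rule must be {ACCTRAN!r} or {DELTRAN!r}")
    if pars.tree is not tree:
        raise ValueError("parsimony result was not computed on this tree")
    down, costs = pars._down, pars._costs
    resolved: dict[int, str] = {}
    tol = 1e-9 * max(1.0, abs(pars.score))

    def candidates(node: Node, parent_state: Optional[str]) -> list[str]:
        row = down[node.id]
        if parent_state is None:
            total = row
        else:
            total = costs.matrix[costs.index(parent_state)] + row
        best = total.min()
        return sorted(costs.states[j] for j in np.flatnonzero(total <= best + tol))

    for node in tree.root.preorder():
        parent_state = None if node.parent is None else resolved[node.parent.id]
        cands = candidates(node, parent_state)
        if parent_state is None:
            choice = cands[0]
        elif rule == DELTRAN:
            choice = parent_state if parent_state in cands else cands[0]
        else:  # ACCTRAN
            differing = [s for s in cands if s != parent_state]
            choice = differing[0] if differing else parent_state
        resolved[node.id] = choice
    return resolved


# ---------------------------------------------------------------------------
# Brownian motion
# ---------------------------------------------------------------------------


@dataclass
class BMResult:
    """ML ancestral values under Brownian motion.

    ``values`` covers every node (leaves carry their observations);
    ``variance`` is the conditional variance of each internal value given the
    tips at the estimated rate (0 at leaves).  ``sigma2_hat`` is the ML rate
    estimate and ``root_value`` the estimated root state.
    """

    tree: Tree
    values: dict[int, float]
    variance: dict[int, float]
    sigma2_hat: float
    root_value: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "node": n.id,
                "label": n.label or "",
                "is_leaf": n.is_leaf,
                "value": self.values[n.id],
                "variance": self.variance[n.id],
            }
            for n in self.tree.nodes
        ]
        return pd.DataFrame(rows)


def _edge_lengths_floored(tree: Tree) -> dict[int, float]:
    """Branch lengths with zeros floored at 1e-9 × tree diameter (warned)."""
    diam = tree_diameter(tree)
    floor = 1e-9 * diam if diam > 0 else 1e-9
    lengths: dict[int, float] = {}
    floored = []
    for node in tree.nodes:
        if node.parent is None:
            continue
        l = node.parent_edge_length
        if l is None:
            raise MissingBranchLengthError(
                f"node {node.id} has no branch length; required for BM"
            )
        if l <= 0:
            floored.append(node.id)
            l = floor
        lengths[node.id] = l
    if floored:
        warnings.warn(
            f"zero-length branches floored at {floor:g} for nodes {floored}",
            stacklevel=3,
        )
    return lengths


def bm_ancestral(tree: Tree, chr: Mapping[str, float]) -> BMResult:
    """Maximum-likelihood ancestral values and rate under Brownian motion.

    Ancestral values solve the weighted least-squares system in which every
    edge pulls its endpoints together with weight 1/length — each internal
    value is the weighted average of its neighbours, so estimates always lie
    within the observed leaf range.  The rate is the ML (1/n) GLS estimate
    from the phylogenetic covariance matrix; conditional variances come from
    the inverse of the internal-node precision matrix scaled by the rate.
    """
    leaves = tree.leaves
    missing = [l.label for l in leaves if l.label not in chr]
    if missing:
        raise ValueError(f"leaves without a value: {missing}")
    values: dict[int, float] = {l.id: float(chr[l.label]) for l in leaves}

    if len(leaves) == 1:
        only = values[leaves[0].id]
        vals = {n.id: only for n in tree.nodes}
        var = {n.id: 0.0 for n in tree.nodes}
        return BMResult(tree, vals, var, 0.0, only)

    lengths = _edge_lengths_floored(tree)
    internal = [n for n in tree.nodes if not n.is_leaf]
    idx = {n.id: i for i, n in enumerate(internal)}
    m = len(internal)
    J = np.zeros((m, m))
    b = np.zeros(m)
    for node in tree.nodes:
        if node.parent is None:
            continue
        w = 1.0 / lengths[node.id]
        p = node.parent
        if node.is_leaf:
            J[idx[p.id], idx[p.id]] += w
            b[idx[p.id]] += w * values[node.id]
        else:
            i, j = idx[node.id], idx[p.id]
            J[i, i] += w
            J[j, j] += w
            J[i, j] -= w
            J[j, i] -= w
    Jinv = np.linalg.inv(J)
    x = Jinv @ b
    for n in internal:
        values[n.id] = float(x[idx[n.id]])

    # ML rate via GLS on the leaf covariance (shared root-to-MRCA path lengths)
    depths = {}
    depths[tree.root.id] = 0.0
    for node in tree.root.preorder():
        if node.parent is not None:
            depths[node.id] = depths[node.parent.id] + lengths[node.id]
    n = len(leaves)
    C = np.zeros((n, n))
    order = {l.id: i for i, l in enumerate(leaves)}
    # fill via common-ancestor depths: for each internal node, leaf pairs whose
    # MRCA it is get its depth; diagonal gets each leaf's own depth
    for node in tree.nodes:
        if node.is_leaf:
            C[order[node.id], order[node.id]] = depths[node.id]
            continue
        groups = [
            [order[l.id] for l in (c.preorder()) if l.is_leaf] for c in node.children
        ]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for bb in groups[gj]:
                        C[a, bb] = C[bb, a] = depths[node.id]
    y = np.array([values[l.id] for l in leaves])
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    mu = float(ones @ Cinv @ y / (ones @ Cinv @ ones))
    resid = y - mu
    sigma2 = float(resid @ Cinv @ resid / n)

    variance = {n_.id: 0.0 for n_ in leaves}
    for n_ in internal:
        variance[n_.id] = float(sigma2 * Jinv[idx[n_.id], idx[n_.id]])
    return BMResult(
        tree=tree,
        values=values,
        variance=variance,
        sigma2_hat=sigma2,
        root_value=float(values[tree.root.id]),
    )


# ---------------------------------------------------------------------------
# Phylogeography
# ---------------------------------------------------------------------------


def read_gazetteer(source) -> dict[str, tuple[float, float]]:
    """Read a CSV with columns state, lat, lon into a coordinate map."""
    frame = pd.read_csv(source)
    required = {"state", "lat", "lon"}
    if not required <= set(frame.columns):
        raise ValueError(f"gazetteer needs columns {sorted(required)}")
    return {
        str(r.state): (float(r.lat), float(r.lon)) for r in frame.itertuples()
    }


@dataclass
class TransitionTable:
    """Per-edge state movements with root-relative cumulative times.

    Every edge gets a row; rows whose endpoint states differ are flagged as
    transitions.  ``missing_coordinates`` lists states absent from the
    gazetteer (a warning, never fatal).
    """

    frame: pd.DataFrame
    missing_coordinates: list[str]

    @property
    def transitions(self) -> pd.DataFrame:
        return self.frame[self.frame["is_change"]]

    def to_geojson(self) -> str:
        """GeoJSON FeatureCollection: one LineString per flagged transition
        with both endpoints geocoded, carrying start/end times and states."""
        features = []
        for r in self.transitions.itertuples():
            if any(
                pd.isna(v)
                for v in (r.parent_lat, r.parent_lon, r.child_lat, r.child_lon)
            ):
                continue
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "LineString",
                        "coordinates": [
                            [r.parent_lon, r.parent_lat],
                            [r.child_lon, r.child_lat],
                        ],
                    },
                    "properties": {
                        "parent_state": r.parent_state,
                        "child_state": r.child_state,
                        "t_start": r.t_start,
                        "t_end": r.t_end,
                    },
                }
            )
        return json.dumps(
            {"type": "FeatureCollection", "features": features}, sort_keys=True
        )


def phylogeo_transitions(
    tree: Tree,
    resolved: Mapping[int, str],
    gazetteer: Optional[Mapping[str, tuple[float, float]]] = None,
) -> TransitionTable:
    """Tabulate state movement along every edge of a resolved reconstruction.

    Times are cumulative root-to-node path lengths (t_end − t_start equals the
    child's branch length); no calendar calibration is applied.
    """
    missing_nodes = [n.id for n in tree.nodes if n.id not in resolved]
    if missing_nodes:
        raise ValueError(f"resolved states missing for nodes {missing_nodes}")
    depths = tree.depths()
    rows = []
    missing_states: set[str] = set()

    def coords(state: str):
        if gazetteer is None:
            return (math.nan, math.nan)
        if state not in gazetteer:
            missing_states.add(state)
            return (math.nan, math.nan)
        return gazetteer[state]

    for node in tree.nodes:
        if node.parent is None:
            continue
        ps, cs = resolved[node.parent.id], resolved[node.id]
        plat, plon = coords(ps)
        clat, clon = coords(cs)
        rows.append(
            {
                "parent": node.parent.id,
                "child": node.id,
                "parent_state": ps,
                "child_state": cs,
                "t_start": depths[node.parent.id],
                "t_end": depths[node.id],
                "is_change": ps != cs,
                "parent_lat": plat,
                "parent_lon": plon,
                "child_lat": clat,
                "child_lon": clon,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "parent",
            "child",
            "parent_state",
            "child_state",
            "t_start",
            "t_end",
            "is_change",
            "parent_lat",
            "parent_lon",
            "child_lat",
            "child_lon",
        ],
    )
    out = TransitionTable(frame=frame, missing_coordinates=sorted(missing_states))
    if missing_states:
        warnings.warn(
            f"gazetteer has no coordinates for states {sorted(missing_states)}",
            stacklevel=2,
        )
    return out
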