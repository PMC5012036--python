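"""Neighbor-joining agglomeration.

This NJ variant is the backbone of the hybridization-network algorithm.
Pair selection uses the standard Q criterion

    Q(i, j) = (m - 2) d(i, j) - R_i - R_j,      R_i = sum_k d(i, k),

which is equivalent to picking, among all partly-resolved star
configurations, the one whose least-squares branch lengths minimise the
total tree length (a tested property, not an assumption).  After joining
i and j into X the matrix is reduced with the half-sum rule

    d(X, k) = (d(i, k) + d(j, k)) / 2,

i.e. without subtracting d(i, j)/2.  Under this rule an agglomerated node
behaves, on additive input, like a leaf whose pendant edge is extended by
the mean of the joined limb lengths; the builder tracks that offset per
active node and subtracts it when an edge is finally assigned, so that on
additive matrices leaf-to-leaf path lengths in the output tree reproduce
the input distances exactly.

Tie-breaking is lexicographic on label pairs everywhere; the output is a
deterministic function of the input matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .distances import DistanceMatrix

__all__ = ["TreeNode", "PhyloTree", "select_neighbors", "nj_update", "nj_tree"]

_TIE_ATOL = 1e-9


@dataclass
class TreeNode:
    """A node of a phylogeny; ``length`` is the edge to its parent."""

    label: Optional[str] = None
    length: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        yield self
        for ch in self.children:
            yield from ch.walk()


def _fmt_len(x: float) -> str:
    return format(x, ".6g")


class PhyloTree:
    """An unrooted phylogeny stored with an arbitrary root node.

    The root is a basal multifurcation (or the single leaf / cherry for
    degenerate sizes); it carries no parent edge.  Branch lengths are the
    raw NJ estimates and may be negative; path-length queries clamp
    negative edges to zero.
    """

    def __init__(self, root: TreeNode):
        self.root = root

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(sorted(n.label for n in self.root.walk() if n.is_leaf))

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self.root.walk() if n.is_leaf)

    def newick(self) -> str:
        def rec(node: TreeNode) -> str:
            if node.is_leaf:
                body = node.label or ""
            else:
                body = "(" + ",".join(rec(c) for c in node.children) + ")"
                if node.label:
                    body += node.label
            if node.length is not None:
                body += f":{_fmt_len(node.length)}"
            return body

        return rec(self.root) + ";"

    def path_lengths(self) -> DistanceMatrix:
        """Leaf-to-leaf path lengths with negative edges clamped to 0."""

        def down(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.label: 0.0}
            out: dict[str, float] = {}
            for ch in node.children:
                e = max(ch.length or 0.0, 0.0)
                for lab, dist in down(ch).items():
                    out[lab] = dist + e
            return out

        # accumulate distances pairing leaves from distinct child subtrees
        labels = self.leaf_labels
        idx = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        D = np.zeros((n, n))

        def visit(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.label: 0.0}
            maps = []
            for ch in node.children:
                m = visit(ch)
                e = max(ch.length or 0.0, 0.0)
                maps.append({lab: d + e for lab, d in m.items()})
            for a in range(len(maps)):
                for b in range(a + 1, len(maps)):
                    for la, da in maps[a].items():
                        for lb, db in maps[b].items():
                            D[idx[la], idx[lb]] = D[idx[lb], idx[la]] = da + db
            merged: dict[str, float] = {}
            for m in maps:
                merged.update(m)
            return merged

        visit(self.root)
        return DistanceMatrix(labels, D)

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each as the smaller-by-sorting leaf set side."""
        all_leaves = frozenset(self.leaf_labels)
        out: set[frozenset[str]] = set()

        def rec(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset().union(*(rec(c) for c in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                out.add(min(below, other, key=lambda s: sorted(s)))
            return below

        for child in self.root.children:
            rec(child)
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({self.newick()})"


def select_neighbors(D: DistanceMatrix) -> tuple[str, str]:
    """The NJ pair: argmin of Q, ties broken lexicographically.

    Minimising Q over pairs is equivalent to minimising the least-squares
    total tree length over the corresponding star configurations.
    """
    m = D.n
    if m < 3:
        raise ValueError("need at least 3 active nodes to select neighbors")
    vals = D.values
    R = vals.sum(axis=1)
    Q = (m - 2) * vals - R[:, None] - R[None, :]
    iu = np.triu_indices(m, k=1)
    qmin = Q[iu].min()
    best: Optional[tuple[str, str]] = None
    for a, b in zip(*iu):
        if Q[a, b] <= qmin + _TIE_ATOL:
            pair = tuple(sorted((D.labels[a], D.labels[b])))
            if best is None or pair < best:
                best = pair
    return best


def limb_lengths(D: DistanceMatrix, i: str, j: str) -> tuple[float, float]:
    """Standard NJ limb-length estimates for the pair about to be joined."""
    m = D.n
    a, b = D.index(i), D.index(j)
    dij = D.values[a, b]
    if m == 2:
        return dij / 2.0, dij / 2.0
    R = D.values.sum(axis=1)
    li = dij / 2.0 + (R[a] - R[b]) / (2.0 * (m - 2))
    return li, dij - li


def nj_update(D: DistanceMatrix, i: str, j: str, new_label: str) -> DistanceMatrix:
    """Replace i and j by a node X with d(X, k) = (d(i,k) + d(j,k)) / 2."""
    if i == j:
        raise ValueError("cannot join a node with itself")
    if new_label in D.labels:
        raise ValueError(f"label {new_label!r} already active")
    a, b = D.index(i), D.index(j)
    keep = [k for k in range(D.n) if k not in (a, b)]
    new_row = (D.values[a, keep] + D.values[b, keep]) / 2.0
    m = len(keep)
    out = np.zeros((m + 1, m + 1))
    out[:m, :m] = D.values[np.ix_(keep, keep)]
    out[m, :m] = new_row
    out[:m, m] = new_row
    labels = tuple(D.labels[k] for k in keep) + (new_label,)
    return DistanceMatrix(labels, out)


def _fresh_label(existing: set[str], step: int) -> str:
    lab = f"X{step}"
    while lab in existing:
        lab = "_" + lab
    return lab


def nj_tree(D: DistanceMatrix) -> PhyloTree:
    """Full NJ agglomeration of a distance matrix into an unrooted tree."""
    if D.n < 3:
        raise ValueError("need at least 3 taxa")
    nodes: dict[str, TreeNode] = {lab: TreeNode(label=lab) for lab in D.labels}
    offsets: dict[str, float] = {lab: 0.0 for lab in D.labels}
    work = D
    step = 0
    while work.n > 3:
        i, j = select_neighbors(work)
        li, lj = limb_lengths(work, i, j)
        step += 1
        work, parent_label = _join(work, nodes, offsets, i, j, li, lj, step)
    _finish(work, nodes, offsets)
    root_label = work.labels[0] if work.n == 1 else "__root__"
    return PhyloTree(nodes[root_label])


def _join(work, nodes, offsets, i, j, li, lj, step):
    """Create the parent of i and j and reduce the working matrix."""
    parent = TreeNode(
        children=[nodes[i], nodes[j]],
    )
    nodes[i].length = li - offsets[i]
    nodes[j].length = lj - offsets[j]
    new_label = _fresh_label(set(work.labels) | set(nodes), step)
    nodes[new_label] = parent
    offsets[new_label] = (li + lj) / 2.0
    return nj_update(work, i, j, new_label), new_label


def _finish(work, nodes, offsets):
    """Resolve the terminal 2- or 3-node configuration into a root."""
    if work.n == 3:
        a, b, c = work.labels
        dab, dac, dbc = work.d(a, b), work.d(a, c), work.d(b, c)
        la = (dab + dac - dbc) / 2.0
        lb = (dab + dbc - dac) / 2.0
        lc = (dac + dbc - dab) / 2.0
        root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
        for lab, limb in ((a, la), (b, lb), (c, lc)):
            nodes[lab].length = limb - offsets[lab]
    elif work.n == 2:
        a, b = work.labels
        e = work.d(a, b) - offsets[a] - offsets[b]
        root = TreeNode(children=[nodes[a], nodes[b]])
        nodes[a].length = e / 2.0
        nodes[b].length = e / 2.0
    else:  # single survivor
        nodes["__root__"] = nodes[work.labels[0]]
        return
    nodes["__root__"] = root
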