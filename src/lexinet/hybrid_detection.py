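"""Detection of hybrid taxa during neighbor-joining agglomeration.

The model behind the detection step: a recipient (hybrid) taxon h whose
distances to the remaining taxa are a convex combination of the distances
of two donors i and j,

    d(k, h) ~ alpha * d(k, i) + (1 - alpha) * d(k, j)    for all other k,

with alpha the hybridization degree attributed to donor i.  Centring both
sides with the row means S_l = sum_k d(k, l) / (n - 3) (l in {h, i, j},
k running over the n - 3 remaining active nodes) gives a one-parameter
least-squares problem

    LS(alpha) = sum_k (Y_k - S_h + S_j - alpha * X_k)^2,
    Y_k = d(k, h) - d(k, j),
    X_k = S_j - S_i + d(k, i) - d(k, j),

whose closed-form minimiser is the estimator implemented in
:func:`estimate_alpha`.  On exactly convex data the estimator is exact and
LS vanishes.

Two further statistics guard the decision.  The reticulation score

    Sc = min_k min{ d(i,j) + d(k,h) - d(i,h) - d(k,j),
                    d(i,j) + d(k,h) - d(j,h) - d(k,i) }

measures deviation from the four-point condition: it stays ~0 on additive
(tree-like) data and grows when h carries non-tree signal for the donor
pair.  The neighbor deviation

    Delta = sum_{k != i,j} (d(j,h) + d(i,k) - d(j,k) - d(i,h))

is identically zero when the NJ pair (i, j) are true neighbors in an
additive tree, so |Delta| quantifies how much candidate h perturbs the
pending join.

At each agglomeration step the algorithm finds h0 maximising |Delta| for
the selected NJ pair (i, j), then scans triplets (h0, i0, k) with i0 in
{i, j} and k any other active node, keeping those with Sc >= min_score and
alpha_min <= alpha <= alpha_max, and takes the one with minimal LS.  If
LS < Delta^2 the candidate is accepted: h0 is recorded as a hybrid of i0
and k with degrees (alpha, 1 - alpha) and removed from the matrix, and
pair selection restarts; otherwise i and j are joined as in plain NJ.
The whole loop is O(n^3), like NJ itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .distances import DistanceMatrix
from .nj_engine import (
    PhyloTree,
    TreeNode,
    _fresh_label,
    limb_lengths,
    nj_update,
    select_neighbors,
)

__all__ = [
    "DetectionParameters",
    "HybridCandidate",
    "Reticulation",
    "HybridizationNetwork",
    "default_parameters",
    "estimate_alpha",
    "least_squares",
    "hybridization_score",
    "neighbor_deviation",
    "detect_at_step",
    "infer_network",
    "iterate_removal",
]

#: matrix sizes up to this bound use the permissive parameter regime
SMALL_MATRIX_MAX = 20


@dataclass(frozen=True)
class DetectionParameters:
    """User-facing knobs of the detection rule.

    min_score
        minimum reticulation score Sc a candidate triplet must reach;
        raising it suppresses weak (near-additive) candidates.
    alpha_min, alpha_max
        admissible range of the hybridization degree, inside (0, 1);
        candidates whose estimated degree falls outside are rejected.
    """

    min_score: float = 0.0
    alpha_min: float = 0.1
    alpha_max: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_min < self.alpha_max < 1.0):
            raise ValueError(
                "require 0 < alpha_min < alpha_max < 1, got "
                f"({self.alpha_min}, {self.alpha_max})"
            )


def default_parameters(n_taxa: int) -> DetectionParameters:
    """Size-dependent defaults: permissive for small matrices
    (min_score=0, alpha in [0.1, 0.9]), restrictive for large ones
    (min_score=0.1, alpha in [0.25, 0.75]) to limit false positives."""
    if n_taxa <= SMALL_MATRIX_MAX:
        return DetectionParameters(0.0, 0.1, 0.9)
    return DetectionParameters(0.1, 0.25, 0.75)


@dataclass(frozen=True)
class HybridCandidate:
    """A scored triplet: h hybrid of donors i and j with degree alpha to i."""

    h: str
    i: str
    j: str
    alpha: float
    ls: float
    score: float
    delta: float

    @property
    def accepted(self) -> bool:
        return self.ls < self.delta**2


@dataclass(frozen=True)
class Reticulation:
    """An accepted hybridization event.

    Donors may be original taxa or agglomerated (ancestral) nodes; the
    ``*_members`` tuples list the original taxa each donor represents.
    ``degree1`` is the proportion of the recipient's signal attributed to
    donor1; degrees sum to 1 exactly.
    """

    recipient: str
    recipient_members: tuple[str, ...]
    donor1: str
    donor1_members: tuple[str, ...]
    degree1: float
    donor2: str
    donor2_members: tuple[str, ...]
    degree2: float
    score: float
    ls: float
    delta: float
    step: int
    round: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "degree2", 1.0 - self.degree1)


@dataclass
class HybridizationNetwork:
    """NJ tree over the surviving nodes plus the reticulation records."""

    tree: PhyloTree
    reticulations: list[Reticulation] = field(default_factory=list)
    #: active-node label -> TreeNode, for rendering reticulations in eNewick
    node_index: dict[str, TreeNode] = field(default_factory=dict, repr=False)

    @property
    def n_reticulations(self) -> int:
        return len(self.reticulations)

    def recipients(self) -> tuple[str, ...]:
        return tuple(r.recipient for r in self.reticulations)


def _stats(D: DistanceMatrix, h: str, i: str, j: str):
    """Common intermediates S_l, X_k, Y_k over k != h, i, j."""
    idx_h, idx_i, idx_j = D.index(h), D.index(i), D.index(j)
    mask = np.ones(D.n, dtype=bool)
    mask[[idx_h, idx_i, idx_j]] = False
    if not mask.any():
        raise ValueError("need at least one active node besides h, i, j")
    dk_h = D.values[mask, idx_h]
    dk_i = D.values[mask, idx_i]
    dk_j = D.values[mask, idx_j]
    s_h, s_i, s_j = dk_h.mean(), dk_i.mean(), dk_j.mean()
    X = s_j - s_i + dk_i - dk_j
    Y = dk_h - dk_j
    return X, Y, s_h, s_i, s_j


def estimate_alpha(D: DistanceMatrix, h: str, i: str, j: str) -> float:
    """Closed-form least-squares hybridization degree of h toward donor i.

    Returns ``nan`` when the donors are indistinguishable from every
    remaining node (sum X_k^2 == 0), in which case the degree is not
    identifiable and the caller should drop the candidate.
    """
    if len({h, i, j}) != 3:
        raise ValueError("h, i, j must be distinct")
    if D.n < 5:
        raise ValueError("degree estimation needs at least 5 active nodes")
    X, Y, s_h, _, s_j = _stats(D, h, i, j)
    sxx = float(X @ X)
    # Degenerate donors: when d(k, i) - d(k, j) is constant over k (e.g. i
    # and j form a cherry) X vanishes identically and the degree is not
    # identifiable; guard with a relative tolerance so rounding noise in X
    # is not divided out into an arbitrary ratio.
    scale = max(float(D.values.max()), 1e-300)
    if sxx <= len(X) * (1e-9 * scale) ** 2:
        return float("nan")
    return float(X @ (Y - s_h + s_j) / sxx)


def least_squares(D: DistanceMatrix, h: str, i: str, j: str, alpha: float) -> float:
    """Residual sum of squares of the convex-combination fit at ``alpha``."""
    X, Y, s_h, _, s_j = _stats(D, h, i, j)
    resid = Y - s_h + s_j - alpha * X
    return float(resid @ resid)


def hybridization_score(D: DistanceMatrix, h: str, i: str, j: str) -> float:
    """Four-point-condition deviation score for the triplet (h, i, j)."""
    if len({h, i, j}) != 3:
        raise ValueError("h, i, j must be distinct")
    if D.n < 4:
        raise ValueError("score needs at least 4 active nodes")
    idx_h, idx_i, idx_j = D.index(h), D.index(i), D.index(j)
    mask = np.ones(D.n, dtype=bool)
    mask[[idx_h, idx_i, idx_j]] = False
    dij = D.values[idx_i, idx_j]
    dih = D.values[idx_i, idx_h]
    djh = D.values[idx_j, idx_h]
    dk_h = D.values[mask, idx_h]
    dk_i = D.values[mask, idx_i]
    dk_j = D.values[mask, idx_j]
    expr1 = dij + dk_h - dih - dk_j
    expr2 = dij + dk_h - djh - dk_i
    return float(np.minimum(expr1, expr2).min())


def neighbor_deviation(D: DistanceMatrix, i: str, j: str) -> tuple[str, float]:
    """The candidate h maximising |Delta| for the NJ pair (i, j).

    Delta sums, over k != i, j, the four-point combination
    d(j,h) + d(i,k) - d(j,k) - d(i,h); it vanishes for every h when i and
    j are true neighbors in an additive tree.  Ties on |Delta| are broken
    lexicographically on h.  Returns ``(h0, Delta_{i,j}^{h0})``.
    """
    if D.n < 4:
        raise ValueError("neighbor deviation needs at least 4 active nodes")
    idx_i, idx_j = D.index(i), D.index(j)
    others_mask = np.ones(D.n, dtype=bool)
    others_mask[[idx_i, idx_j]] = False
    dk_i = D.values[others_mask, idx_i]
    dk_j = D.values[others_mask, idx_j]
    base = float((dk_i - dk_j).sum())
    m = int(others_mask.sum())
    best: Optional[tuple[str, float]] = None
    for pos, lab in zip(np.nonzero(others_mask)[0], np.array(D.labels)[others_mask]):
        dih = D.values[idx_i, pos]
        djh = D.values[idx_j, pos]
        delta = m * (djh - dih) + base
        if (
            best is None
            or abs(delta) > abs(best[1]) + _ABS_TIE
            or (abs(abs(delta) - abs(best[1])) <= _ABS_TIE and lab < best[0])
        ):
            best = (str(lab), delta)
    return best


_ABS_TIE = 1e-12

#: |Delta| below this fraction of the largest distance is treated as zero
_DELTA_RTOL = 1e-7


def detect_at_step(
    D: DistanceMatrix, i: str, j: str, params: DetectionParameters
) -> Optional[HybridCandidate]:
    """Scan for an acceptable hybrid before joining the NJ pair (i, j).

    Returns the accepted candidate, or ``None`` when no triplet survives
    the score/degree constraints and the LS < Delta^2 test (the normal
    outcome on tree-like data).
    """
    if D.n < 5:
        return None
    h0, delta = neighbor_deviation(D, i, j)
    # On additive data Delta is exactly zero and no candidate can pass
    # LS < Delta^2; guard the comparison against rounding noise so that
    # machine-epsilon deviations are not mistaken for signal.
    scale = float(D.values.max())
    if abs(delta) <= _DELTA_RTOL * max(scale, 1e-300):
        return None
    best: Optional[HybridCandidate] = None
    for i0 in sorted((i, j)):
        for k in D.labels:
            if k in (i, j, h0):
                continue
            alpha = estimate_alpha(D, h0, i0, k)
            if not np.isfinite(alpha):
                continue
            if not (params.alpha_min <= alpha <= params.alpha_max):
                continue
            score = hybridization_score(D, h0, i0, k)
            if score < params.min_score:
                continue
            ls = least_squares(D, h0, i0, k, alpha)
            key = (ls, i0, k)
            if best is None or key < (best.ls, best.i, best.j):
                best = HybridCandidate(
                    h=h0, i=i0, j=k, alpha=alpha, ls=ls, score=score, delta=delta
                )
    if best is not None and best.accepted:
        return best
    return None


def infer_network(
    D: DistanceMatrix,
    params: Optional[DetectionParameters] = None,
    _round: int = 1,
) -> HybridizationNetwork:
    """NJ agglomeration with per-step hybrid detection and removal.

    At every step the NJ pair is selected; if a hybrid candidate is
    accepted its node is removed (the pending join is *not* performed) and
    selection restarts on the reduced matrix, otherwise the pair is joined
    with the half-sum reduction.  Detection needs more than four active
    nodes; for n <= 4 the result is a plain NJ tree and a warning is
    emitted.
    """
    if D.n < 3:
        raise ValueError("need at least 3 taxa")
    if params is None:
        params = default_parameters(D.n)
    if D.n <= 4:
        warnings.warn(
            "hybrid detection needs a distance matrix of size greater than "
            "four; returning a plain NJ tree",
            stacklevel=2,
        )
    nodes: dict[str, TreeNode] = {lab: TreeNode(label=lab) for lab in D.labels}
    offsets: dict[str, float] = {lab: 0.0 for lab in D.labels}
    members: dict[str, tuple[str, ...]] = {lab: (lab,) for lab in D.labels}
    reticulations: list[Reticulation] = []
    work = D
    step = 0
    while work.n > 3:
        i, j = select_neighbors(work)
        cand = detect_at_step(work, i, j, params)
        if cand is not None:
            reticulations.append(
                Reticulation(
                    recipient=cand.h,
                    recipient_members=members[cand.h],
                    donor1=cand.i,
                    donor1_members=members[cand.i],
                    degree1=cand.alpha,
                    donor2=cand.j,
                    donor2_members=members[cand.j],
                    degree2=1.0 - cand.alpha,
                    score=cand.score,
                    ls=cand.ls,
                    delta=cand.delta,
                    step=step,
                    round=_round,
                )
            )
            work = work.drop([cand.h])
            continue
        li, lj = limb_lengths(work, i, j)
        step += 1
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = li - offsets[i]
        nodes[j].length = lj - offsets[j]
        new_label = _fresh_label(set(work.labels) | set(nodes), step)
        nodes[new_label] = parent
        offsets[new_label] = (li + lj) / 2.0
        members[new_label] = tuple(sorted(members[i] + members[j]))
        work = nj_update(work, i, j, new_label)
    _finish_tree(work, nodes, offsets)
    tree = PhyloTree(nodes["__root__"])
    return HybridizationNetwork(
        tree=tree, reticulations=reticulations, node_index=nodes
    )


def _finish_tree(work, nodes, offsets) -> None:
    from .nj_engine import _finish

    _finish(work, nodes, offsets)


def iterate_removal(
    D: DistanceMatrix,
    params: Optional[DetectionParameters] = None,
    max_rounds: int = 5,
) -> HybridizationNetwork:
    """Re-run network inference on hybrid-pruned matrices.

    After each run the original taxa belonging to detected recipients are
    removed from the *input* matrix and inference is repeated, so hybrids
    whose signal was masked by a stronger one can surface in later rounds.
    Stops when a run finds nothing new, the matrix gets too small, or
    ``max_rounds`` is reached.  Reticulations from all rounds are
    accumulated; the returned tree is the final round's tree.
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    all_retics: list[Reticulation] = []
    work = D
    net = infer_network(work, params, _round=1)
    all_retics.extend(net.reticulations)
    for rnd in range(2, max_rounds + 1):
        removed = {t for r in all_retics for t in r.recipient_members}
        remaining = [lab for lab in work.labels if lab not in removed]
        if len(remaining) < 5 or not net.reticulations:
            break
        work = D.drop(removed)
        net = infer_network(work, params, _round=rnd)
        all_retics.extend(net.reticulations)
    return HybridizationNetwork(
        tree=net.tree, reticulations=all_retics, node_index=net.node_index
    )
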