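"""Synthetic data with known ground truth.

Three generators cover the stages of the pipeline:

* :func:`random_additive_matrix` — a random unrooted binary tree with
  uniform branch lengths and its exact leaf-to-leaf path-length matrix
  (additive by construction, so NJ must recover the topology);
* :func:`inject_hybrid` — adds one taxon whose distances are an exact
  convex combination of two parents' distances, the noise-free model the
  degree estimator solves;
* :func:`simulate_cognate_database` — a cognate-level dataset: two
  lineages of taxa plus an outgroup, each character partitioned into
  cognate sets along lineage structure, and hybrid taxa whose per-meaning
  memberships are copied from one or the other parent in proportion to
  the hybridization degree.

All generators draw from a single seeded :class:`numpy.random.Generator`
stream, so outputs are bit-reproducible given the spec.

:func:`worked_example_database` builds, with no randomness, the canonical
8-taxon / 4-character / 16-cognate-set example of a balanced lexical
hybrid: L4's memberships are split evenly between the lineages of L3 and
L5, L8 is an outgroup, and the full pipeline attributes degree 0.5 to
each parent.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from math import floor
from typing import Optional

import numpy as np

from .cognate_io import CognateDatabase, CognateRecord
from .distances import DistanceMatrix
from .nj_engine import PhyloTree, TreeNode

__all__ = [
    "SimulationSpec",
    "random_additive_matrix",
    "inject_hybrid",
    "simulate_cognate_database",
    "worked_example_database",
    "taxon_labels",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of a synthetic dataset.

    ``hybrids`` lists ``(recipient_label, parent1, parent2, alpha)``
    tuples; parents must be distinct non-hybrid taxa and, for the cognate
    generator, lie in different lineages.  ``deterministic_split`` selects
    exact proportional allocation of the hybrid's meanings to its parents
    (floor rounding) instead of Bernoulli(alpha) draws.
    """

    n_taxa: int
    seed: int = 0
    branch_length_range: tuple[float, float] = (0.1, 1.0)
    hybrids: tuple[tuple[str, str, str, float], ...] = ()
    n_characters: int = 50
    cogsets_per_character: int = 4
    missing_rate: float = 0.0
    deterministic_split: bool = True

    def __post_init__(self) -> None:
        for h, p1, p2, alpha in self.hybrids:
            if not (0.0 < alpha < 1.0):
                raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
            if p1 == p2 or h in (p1, p2):
                raise ValueError(f"hybrid {h!r} needs two distinct parents")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


def taxon_labels(n: int, prefix: str = "L") -> tuple[str, ...]:
    """Zero-padded labels so lexicographic and numeric order agree."""
    width = len(str(n))
    return tuple(f"{prefix}{i:0{width}d}" for i in range(1, n + 1))


def random_additive_matrix(
    spec: SimulationSpec, labels: Optional[tuple[str, ...]] = None
) -> tuple[PhyloTree, DistanceMatrix]:
    """A random binary tree and its exact path-length distance matrix.

    The topology is grown by attaching each new leaf to a uniformly chosen
    existing edge; branch lengths are uniform in
    ``spec.branch_length_range``.
    """
    n = spec.n_taxa
    if n < 4:
        raise ValueError("need at least 4 taxa")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.branch_length_range
    if not (0 < lo <= hi):
        raise ValueError("branch length range must be positive")
    labels = tuple(labels) if labels is not None else taxon_labels(n)
    if len(labels) != n:
        raise ValueError("label count does not match n_taxa")

    def blen() -> float:
        return float(rng.uniform(lo, hi))

    # adjacency: node -> {neighbor: length}; leaves are labels, internals ints
    adj: dict = {}

    def add_edge(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    def del_edge(u, v):
        del adj[u][v]
        del adj[v][u]

    add_edge(labels[0], 0, blen())
    add_edge(labels[1], 0, blen())
    add_edge(labels[2], 0, blen())
    next_internal = 1
    def nodekey(x):
        return (isinstance(x, str), str(x))

    for leaf in labels[3:]:
        edges = sorted(
            {tuple(sorted((u, v), key=nodekey)) for u in adj for v in adj[u]},
            key=lambda e: (nodekey(e[0]), nodekey(e[1])),
        )
        u, v = edges[rng.integers(len(edges))]
        w = adj[u][v]
        split = float(rng.uniform(0.0, 1.0))
        mid = next_internal
        next_internal += 1
        del_edge(u, v)
        add_edge(u, mid, w * split)
        add_edge(mid, v, w * (1.0 - split))
        add_edge(leaf, mid, blen())

    # exact path lengths by depth-first traversal from each leaf
    vals = np.zeros((n, n))
    pos = {lab: i for i, lab in enumerate(labels)}
    for src in labels:
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for other in labels:
            vals[pos[src], pos[other]] = dist[other]
    np.fill_diagonal(vals, 0.0)
    D = DistanceMatrix(labels, vals)

    # root the tree at internal node 0 for a PhyloTree view
    def build(u, parent) -> TreeNode:
        node = TreeNode(label=u if isinstance(u, str) else None)
        for v, w in sorted(adj[u].items(), key=lambda kv: str(kv[0])):
            if v != parent:
                child = build(v, u)
                child.length = w
                node.children.append(child)
        return node

    return PhyloTree(build(0, None)), D


def inject_hybrid(
    D: DistanceMatrix, parent1: str, parent2: str, alpha: float, label: str
) -> DistanceMatrix:
    """Add a taxon h with d(k, h) = alpha d(k, p1) + (1 - alpha) d(k, p2).

    The distances to the parents themselves follow the same convex rule:
    d(h, p1) = (1 - alpha) d(p1, p2) and d(h, p2) = alpha d(p1, p2).
    Deleting h's row and column returns the input matrix exactly.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie strictly in (0, 1), got {alpha}")
    if label in D.labels:
        raise ValueError(f"label {label!r} already present")
    if parent1 == parent2:
        raise ValueError("parents must be distinct")
    a, b = D.index(parent1), D.index(parent2)
    n = D.n
    row = alpha * D.values[:, a] + (1.0 - alpha) * D.values[:, b]
    out = np.zeros((n + 1, n + 1))
    out[:n, :n] = D.values
    out[n, :n] = row
    out[:n, n] = row
    return DistanceMatrix(D.labels + (label,), out)


def _partition(group: list[str], k: int, rng) -> list[list[str]]:
    """Split a group into k blocks: k - 1 random singleton innovators
    plus the shared core.

    Modelling each extra cognate set as one taxon's lexical innovation
    keeps every taxon's presence-absence profile distinct across enough
    characters, which is what makes donors identifiable downstream; a
    partition into larger shared blocks would leave lineage-mates with
    identical profiles.
    """
    if k == 1:
        return [list(group)]
    innovators = list(rng.choice(np.array(group), size=k - 1, replace=False))
    core = [t for t in group if t not in innovators]
    blocks = [[t] for t in sorted(innovators)]
    if core:
        blocks.append(core)
    return blocks


def _base_form(rng) -> str:
    return "".join(rng.choice(list(string.ascii_lowercase), size=5))


def _variant(base: str, rng, prob: float = 0.3) -> str:
    """The base form, with one letter substituted with probability prob."""
    if rng.random() >= prob:
        return base
    pos = int(rng.integers(len(base)))
    letter = str(rng.choice([c for c in string.ascii_lowercase if c != base[pos]]))
    return base[:pos] + letter + base[pos + 1 :]


def lineages(spec: SimulationSpec) -> tuple[list[str], list[str], str]:
    """Lineage A, lineage B and the outgroup implied by a spec."""
    all_taxa = taxon_labels(spec.n_taxa)
    hybrid_labels = {h for h, *_ in spec.hybrids}
    base = [t for t in all_taxa if t not in hybrid_labels]
    if len(base) < 5:
        raise ValueError("need at least 5 non-hybrid taxa (two lineages + outgroup)")
    outgroup = base[-1]
    core = base[:-1]
    half = (len(core) + 1) // 2
    return core[:half], core[half:], outgroup


def simulate_cognate_database(spec: SimulationSpec) -> CognateDatabase:
    """Cognate-level dataset with lineage structure and known hybrids.

    Non-hybrid taxa form two lineages plus an outgroup.  Every character
    is partitioned into ``cogsets_per_character`` cognate sets: one for
    the outgroup and the rest splitting the two lineages into contiguous
    blocks (at least one block each; remaining splits are placed at
    random).  Each hybrid inherits, meaning by meaning, the memberships of
    one of its two parents: a fraction alpha of the meanings (floor
    rounding, spread evenly over the list) from parent1 and the rest from
    parent2, or Bernoulli(alpha) draws when ``deterministic_split`` is
    off.  ``missing_rate`` removes whole (taxon, character) slots.
    """
    rng = np.random.default_rng(spec.seed)
    lin_a, lin_b, outgroup = lineages(spec)
    in_a, in_b = set(lin_a), set(lin_b)
    hybrids = []
    for h, p1, p2, alpha in spec.hybrids:
        if p1 in in_b and p2 in in_a:
            p1, p2, alpha = p2, p1, 1.0 - alpha
        if not (p1 in in_a and p2 in in_b):
            raise ValueError(
                f"parents of {h!r} must come from different lineages "
                f"(A={lin_a}, B={lin_b})"
            )
        hybrids.append((h, p1, p2, alpha))

    cpc = spec.cogsets_per_character
    if cpc < 3:
        raise ValueError("need at least 3 cogsets per character")
    if cpc - 1 > len(lin_a) + len(lin_b):
        raise ValueError("more cogsets per character than lineage taxa")

    M = spec.n_characters
    mwidth = len(str(M))
    records: list[CognateRecord] = []
    # donor choice per hybrid per meaning, fixed before the meaning loop
    donor_is_p1: dict[str, np.ndarray] = {}
    for h, p1, p2, alpha in hybrids:
        if spec.deterministic_split:
            take = np.array(
                [floor((m + 1) * alpha) - floor(m * alpha) == 1 for m in range(M)]
            )
        else:
            take = rng.random(M) < alpha
        donor_is_p1[h] = take

    all_taxa = taxon_labels(spec.n_taxa)
    missing = (
        rng.random((len(all_taxa), M)) < spec.missing_rate
        if spec.missing_rate > 0
        else np.zeros((len(all_taxa), M), dtype=bool)
    )
    t_pos = {t: i for i, t in enumerate(all_taxa)}

    for m in range(M):
        char = f"m{m + 1:0{mwidth}d}"
        # how many cogsets each lineage gets this meaning
        n_lineage_sets = cpc - 1
        k_a = 1
        k_b = 1
        for _ in range(n_lineage_sets - 2):
            if rng.random() < 0.5 and k_a < len(lin_a):
                k_a += 1
            elif k_b < len(lin_b):
                k_b += 1
            else:
                k_a += 1
        blocks = (
            _partition(lin_a, k_a, rng)
            + _partition(lin_b, k_b, rng)
            + [[outgroup]]
        )
        member_cogset: dict[str, tuple[str, str]] = {}
        for ci, block in enumerate(blocks, start=1):
            cogset = f"{char}c{ci}"
            base = _base_form(rng)
            for taxon in block:
                form = _variant(base, rng)
                member_cogset[taxon] = (cogset, form)
                if not missing[t_pos[taxon], m]:
                    records.append(CognateRecord(taxon, char, cogset, form))
        for h, p1, p2, alpha in hybrids:
            donor = p1 if donor_is_p1[h][m] else p2
            cogset, donor_form = member_cogset[donor]
            if not missing[t_pos[h], m]:
                records.append(CognateRecord(h, char, cogset, _variant(donor_form, rng)))
    return CognateDatabase(records)


def worked_example_database() -> CognateDatabase:
    """The canonical balanced-hybrid example: 8 taxa, 4 characters, 16 cogsets.

    Languages L1-L3 and L5-L7 form two lineages, L8 is an outgroup, and L4
    is a hybrid whose cognate-set memberships are split evenly between the
    lineages of L3 and L5: in characters m1 and m3 it sits in L3's
    cognate set, in m2 and m4 in L5's.  The design is symmetric under the
    relabelling (L1,L2,L3) <-> (L7,L6,L5), which forces the estimated
    hybridization degree toward each parent to be exactly 0.5.
    """
    pattern_odd = [  # characters m1, m3
        ("c1", ["L1", "L2"]),
        ("c2", ["L3", "L4"]),
        ("c3", ["L5", "L6", "L7"]),
        ("c4", ["L8"]),
    ]
    pattern_even = [  # characters m2, m4
        ("c1", ["L1", "L2", "L3"]),
        ("c2", ["L4", "L5"]),
        ("c3", ["L6", "L7"]),
        ("c4", ["L8"]),
    ]
    records = []
    for m in range(1, 5):
        char = f"m{m}"
        pattern = pattern_odd if m % 2 == 1 else pattern_even
        for suffix, members in pattern:
            cogset = f"{char}{suffix}"
            for taxon in members:
                records.append(CognateRecord(taxon, char, cogset, form=cogset))
    return CognateDatabase(records)
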