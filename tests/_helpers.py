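"""Independent oracles used by the test suite.

Everything here recomputes quantities by a different route than the
package (brute force, exhaustive enumeration, external libraries) so the
tests compare two independent paths.
"""

from __future__ import annotations

import itertools

import numpy as np

from lexinet.distances import DistanceMatrix


def random_symmetric_matrix(n: int, rng) -> DistanceMatrix:
    M = rng.uniform(0.1, 2.0, size=(n, n))
    M = (M + M.T) / 2.0
    np.fill_diagonal(M, 0.0)
    return DistanceMatrix(tuple(f"T{t}" for t in range(n)), M)


def ls_configuration_total_length(D: DistanceMatrix, i: str, j: str) -> float:
    """OLS-fitted total tree length of the star configuration where the
    pair (i, j) hangs off the centre through one internal edge."""
    labs = list(D.labels)
    others = [l for l in labs if l not in (i, j)]
    off = 3
    oidx = {l: off + t for t, l in enumerate(others)}
    rows, y = [], []
    for a, b in itertools.combinations(labs, 2):
        r = np.zeros(off + len(others))
        if {a, b} == {i, j}:
            r[0] = 1
            r[1] = 1
        elif a in (i, j) or b in (i, j):
            p = a if a in (i, j) else b
            q = b if a in (i, j) else a
            r[0 if p == i else 1] = 1
            r[2] = 1
            r[oidx[q]] = 1
        else:
            r[oidx[a]] = 1
            r[oidx[b]] = 1
        rows.append(r)
        y.append(D.d(a, b))
    beta, *_ = np.linalg.lstsq(np.array(rows), np.array(y), rcond=None)
    return float(beta.sum())


def scan_best_pair(D: DistanceMatrix) -> tuple[tuple[str, str], float]:
    """Exhaustive least-squares configuration scan over all pairs."""
    totals = {
        tuple(sorted(p)): ls_configuration_total_length(D, *p)
        for p in itertools.combinations(D.labels, 2)
    }
    best = min(totals, key=lambda p: (totals[p], p))
    return best, totals[best]


def hamming_bruteforce(pam, strategy: str):
    """Column-by-column scan of the presence-absence matrix."""
    n = pam.n_taxa
    char_of = [pam.cogset_character[c] for c in pam.cogsets]
    char_pos = {c: k for k, c in enumerate(pam.characters)}
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            if strategy == "missing_as_zero":
                out[a, b] = sum(
                    1
                    for col in range(pam.n_cogsets)
                    if pam.values[a, col] != pam.values[b, col]
                )
            else:
                shared = [
                    m
                    for m in range(len(pam.characters))
                    if pam.missing_mask[a, m] == 0 and pam.missing_mask[b, m] == 0
                ]
                count = sum(
                    1
                    for col in range(pam.n_cogsets)
                    if char_pos[char_of[col]] in shared
                    and pam.values[a, col] != pam.values[b, col]
                )
                out[a, b] = count / len(shared)
    return out


def levenshtein_recursive(a: str, b: str) -> int:
    """Memoised textbook recursion; independent of the package's DP."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            rec(i - 1, j) + 1,
            rec(i, j - 1) + 1,
            rec(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )

    return rec(len(a), len(b))


def delta_direct(D: DistanceMatrix, i: str, j: str, h: str) -> float:
    """Direct term-by-term evaluation of the neighbor-deviation sum."""
    total = 0.0
    for k in D.labels:
        if k in (i, j):
            continue
        total += D.d(j, h) + D.d(i, k) - D.d(j, k) - D.d(i, h)
    return total


def score_direct(D: DistanceMatrix, h: str, i: str, j: str) -> float:
    vals = []
    for k in D.labels:
        if k in (h, i, j):
            continue
        vals.append(
            min(
                D.d(i, j) + D.d(k, h) - D.d(i, h) - D.d(k, j),
                D.d(i, j) + D.d(k, h) - D.d(j, h) - D.d(k, i),
            )
        )
    return min(vals)


def max_four_point_violation(D: DistanceMatrix) -> float:
    worst = 0.0
    v = D.values
    for i, j, k, l in itertools.combinations(range(D.n), 4):
        sums = sorted((v[i, j] + v[k, l], v[i, k] + v[j, l], v[i, l] + v[j, k]))
        worst = max(worst, sums[2] - sums[1])
    return worst


def dendropy_rf(newick1: str, newick2: str) -> int:
    """Unweighted Robinson-Foulds distance via dendropy."""
    import dendropy

    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick1, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=newick2, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(t1, t2)
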