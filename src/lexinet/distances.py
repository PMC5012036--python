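"""Distance matrices for lexical data.

Three encodings feed the network-inference pipeline:

* **Hamming** distances between binary presence-absence profiles, either
  treating missing slots as plain absence (``missing_as_zero``) or
  restricting each pairwise comparison to the characters observed in both
  taxa and normalising by their number (``normalized``);
* **normalized Levenshtein** distance between orthographic word forms
  (edit distance over code points divided by the longer word's length);
* the **per-meaning distance**: for one character, the sum over its cogsets
  of a per-cogset distance (0 if neither taxon is present, 1 if exactly
  one is, otherwise the minimum normalized Levenshtein distance over
  cross-taxon form pairs), divided by the number of the character's
  cogsets containing a form of either taxon.

The module also reads and writes square PHYLIP distance matrices in a
relaxed dialect: full labels (no 10-character truncation), whitespace
separated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .cognate_io import CognateDatabase, PresenceAbsenceMatrix

__all__ = [
    "DistanceMatrix",
    "hamming_distance",
    "normalized_levenshtein",
    "levenshtein",
    "meaning_distance",
    "read_phylip",
    "write_phylip",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """A symmetric, zero-diagonal, nonnegative matrix over named nodes."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.array(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate node labels")
        if vals.shape != (n, n):
            raise ValueError(f"matrix shape {vals.shape} does not match {n} labels")
        if not np.allclose(vals, vals.T, atol=1e-8):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(vals), 0.0, atol=1e-8):
            raise ValueError("distance matrix has nonzero diagonal")
        if (vals < -1e-12).any():
            raise ValueError("distance matrix has negative entries")
        # exact symmetry/zero diagonal from here on
        vals[:] = (vals + vals.T) / 2.0
        np.fill_diagonal(vals, 0.0)
        np.clip(vals, 0.0, None, out=vals)
        object.__setattr__(
            self, "_index", {lab: i for i, lab in enumerate(self.labels)}
        )

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self._index[label]

    def d(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, keep: Sequence[str]) -> "DistanceMatrix":
        idx = [self._index[lab] for lab in keep]
        return DistanceMatrix(tuple(keep), self.values[np.ix_(idx, idx)])

    def drop(self, labels: Iterable[str]) -> "DistanceMatrix":
        drop = set(labels)
        keep = [lab for lab in self.labels if lab not in drop]
        return self.submatrix(keep)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    @classmethod
    def from_dataframe(cls, df) -> "DistanceMatrix":
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float))


def hamming_distance(
    pam: PresenceAbsenceMatrix, strategy: str = "missing_as_zero"
) -> DistanceMatrix:
    """Pairwise Hamming distances between presence-absence profiles.

    ``missing_as_zero``
        d(i, j) = number of cogsets containing a form of exactly one of the
        two taxa, with missing slots kept as 0 (plain absence).
    ``normalized``
        the same count restricted to the cogsets of characters observed in
        *both* taxa, divided by the number of such shared characters.

    With the ``normalized`` strategy a pair of taxa sharing no observed
    character is an error: their distance is undefined.
    """
    if pam.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    X = pam.values.astype(np.int16)
    if strategy == "missing_as_zero":
        diff = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
        return DistanceMatrix(pam.taxa, diff.astype(float))
    if strategy == "normalized":
        observed = pam.missing_mask == 0  # taxa x characters
        char_of = pam.cogset_character_index()  # cogsets -> character index
        n = pam.n_taxa
        out = np.zeros((n, n), dtype=float)
        # shared[i,j,m]: character m observed in both i and j
        for i in range(n):
            for j in range(i + 1, n):
                both = observed[i] & observed[j]
                n_shared = int(both.sum())
                if n_shared == 0:
                    raise ValueError(
                        "no shared observed characters for pair "
                        f"({pam.taxa[i]!r}, {pam.taxa[j]!r}); "
                        "normalized Hamming distance undefined"
                    )
                cols = both[char_of]
                diff = int(np.abs(X[i, cols] - X[j, cols]).sum())
                out[i, j] = out[j, i] = diff / n_shared
        return DistanceMatrix(pam.taxa, out)
    raise ValueError(f"unknown strategy {strategy!r}")


def levenshtein(w1: str, w2: str) -> int:
    """Plain edit distance (insert / delete / substitute one code point)."""
    if w1 == w2:
        return 0
    if not w1:
        return len(w2)
    if not w2:
        return len(w1)
    # one-row DP over code points; word forms are short so this is cheap
    prev = list(range(len(w2) + 1))
    for i, ch in enumerate(w1, start=1):
        cur = [i]
        for j, ch2 in enumerate(w2, start=1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ch != ch2))
            )
        prev = cur
    return prev[-1]


def normalized_levenshtein(w1: str, w2: str) -> float:
    """Edit distance divided by the longer word's length; in [0, 1].

    Two empty strings are identical by convention (distance 0).
    """
    if not w1 and not w2:
        return 0.0
    return levenshtein(w1, w2) / max(len(w1), len(w2))


def meaning_distance(db: CognateDatabase, character: str) -> DistanceMatrix:
    """Per-meaning distance matrix over the taxa attested for one character.

    For taxa l1, l2 the distance is ``sum_c d_c(l1, l2) / n_{l1,l2}`` where
    the sum runs over the character's cogsets, ``d_c`` is 0 / 1 / minimum
    normalized Levenshtein distance depending on which of the two taxa have
    forms in cogset c, and ``n_{l1,l2}`` counts the cogsets containing a
    form of at least one of them.  Only records carrying a form string
    participate.
    """
    # forms[cogset][taxon] -> list of forms
    forms: dict[str, dict[str, list[str]]] = {}
    for rec in db.records:
        if rec.character != character or rec.form is None:
            continue
        forms.setdefault(rec.cogset, {}).setdefault(rec.taxon, []).append(rec.form)
    taxa = sorted({t for per in forms.values() for t in per})
    if len(taxa) < 2:
        raise ValueError(
            f"character {character!r} has fewer than 2 taxa with forms"
        )
    n = len(taxa)
    out = np.zeros((n, n), dtype=float)
    cogsets = sorted(forms)
    for a in range(n):
        for b in range(a + 1, n):
            l1, l2 = taxa[a], taxa[b]
            total = 0.0
            denom = 0
            for c in cogsets:
                per = forms[c]
                in1, in2 = l1 in per, l2 in per
                if not in1 and not in2:
                    continue  # d_c = 0 and excluded from the denominator
                denom += 1
                if in1 and in2:
                    total += min(
                        normalized_levenshtein(f1, f2)
                        for f1 in per[l1]
                        for f2 in per[l2]
                    )
                else:
                    total += 1.0
            out[a, b] = out[b, a] = total / denom
    return DistanceMatrix(tuple(taxa), out)


def write_phylip(dm: DistanceMatrix, path) -> None:
    """Write a square PHYLIP matrix; labels are not truncated."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{dm.n}\n")
        for i, lab in enumerate(dm.labels):
            row = " ".join(format(v, ".10g") for v in dm.values[i])
            fh.write(f"{lab} {row}\n")


def read_phylip(path) -> DistanceMatrix:
    """Read a square PHYLIP matrix (relaxed: whitespace split, full labels)."""
    with open(path, encoding="utf-8") as fh:
        tokens = fh.readline().split()
        if not tokens:
            raise ValueError(f"{path}: missing taxon count on first line")
        n = int(tokens[0])
        labels: list[str] = []
        rows: list[list[float]] = []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != n + 1:
                raise ValueError(
                    f"{path}: expected label + {n} values, got {len(parts)} fields"
                )
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if len(labels) != n:
        raise ValueError(f"{path}: expected {n} rows, found {len(labels)}")
    return DistanceMatrix(tuple(labels), np.array(rows))
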