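"""Per-meaning (per-character) word trees.

For every character with enough attested taxa, a distance matrix over its
taxa is computed from form-level distances within cognate sets
(:func:`lexinet.distances.meaning_distance`) and an unrooted NJ tree is
built from it.  Characters attested in fewer than ``min_taxa`` taxa are
skipped and reported: below four leaves all unrooted topologies coincide,
so such trees carry no grouping signal.  The exported multi-Newick file
(one tree per line, character label as a trailing comment) is meant as
input to external consensus-network software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cognate_io import CognateDatabase
from .distances import DistanceMatrix, meaning_distance, write_phylip
from .nj_engine import PhyloTree, nj_tree

__all__ = ["WordTreeSet", "build_word_trees", "export_trees"]


@dataclass
class WordTreeSet:
    """Word trees keyed by character, with their matrices and a skip report."""

    trees: dict[str, PhyloTree] = field(default_factory=dict)
    matrices: dict[str, DistanceMatrix] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trees)


def build_word_trees(db: CognateDatabase, min_taxa: int = 4) -> WordTreeSet:
    """One NJ tree per character attested (with forms) in >= min_taxa taxa."""
    if not db.records:
        raise ValueError("empty database")
    if min_taxa < 3:
        raise ValueError("min_taxa must be at least 3 (NJ needs 3 leaves)")
    out = WordTreeSet()
    with_forms: dict[str, set[str]] = {}
    for rec in db.records:
        if rec.form is not None:
            with_forms.setdefault(rec.character, set()).add(rec.taxon)
    for char in db.characters:
        n_m = len(with_forms.get(char, ()))
        if n_m < min_taxa:
            out.skipped[char] = f"only {n_m} taxa with forms (need {min_taxa})"
            continue
        dm = meaning_distance(db, char)
        out.matrices[char] = dm
        out.trees[char] = nj_tree(dm)
    return out


def export_trees(wts: WordTreeSet, path, matrices_dir=None) -> None:
    """Write one Newick per line, tagging each with its character label.

    The character name rides in a bracket comment before the terminating
    semicolon, which strict Newick parsers treat as ignorable.  With
    ``matrices_dir`` set, the per-character PHYLIP matrices are written
    alongside as ``<character>.phylip``.
    """
    if not wts.trees:
        raise ValueError("no trees to export")
    with open(path, "w", encoding="utf-8") as fh:
        for char in sorted(wts.trees):
            nwk = wts.trees[char].newick()
            assert nwk.endswith(";")
            fh.write(f"{nwk[:-1]}[&character={char}];\n")
    if matrices_dir is not None:
        import os

        os.makedirs(matrices_dir, exist_ok=True)
        for char, dm in wts.matrices.items():
            write_phylip(dm, os.path.join(matrices_dir, f"{char}.phylip"))
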