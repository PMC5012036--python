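"""Reading cognate databases and building presence-absence matrices.

A cognate database is a flat table of records ``(taxon, character, cogset,
form)``: one row says that language *taxon* has the word *form* for the
meaning *character*, and that this form belongs to the homology class
(cognate set) *cogset*.  Cognate sets are nested inside characters: every
cogset identifier belongs to exactly one character.

The binary presence-absence encoding turns such a database into a taxa x
cogsets 0/1 matrix, together with a taxa x characters mask flagging the
slots where a taxon has no recorded form at all for a meaning (missing
data).  Distances over these profiles are computed in
:mod:`lexinet.distances`.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "CognateRecord",
    "CognateDatabase",
    "PresenceAbsenceMatrix",
    "DatabaseParseError",
    "read_database",
    "build_presence_absence",
    "write_database",
]

REQUIRED_COLUMNS = ("taxon", "character", "cogset")
FORM_COLUMN = "form"


class DatabaseParseError(ValueError):
    """Raised when a database file is malformed; carries the line number."""


@dataclass(frozen=True)
class CognateRecord:
    """One observation: taxon has a form of this character in this cogset."""

    taxon: str
    character: str
    cogset: str
    form: Optional[str] = None


@dataclass
class CognateDatabase:
    """A list of cognate records with consistency checks.

    Invariants enforced at construction:

    * taxon, character and cogset labels are non-empty;
    * every cogset identifier belongs to exactly one character.
    """

    records: list[CognateRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        cogset_char: dict[str, str] = {}
        for rec in self.records:
            if not rec.taxon or not rec.character or not rec.cogset:
                raise ValueError(f"empty label in record {rec}")
            prev = cogset_char.setdefault(rec.cogset, rec.character)
            if prev != rec.character:
                raise ValueError(
                    f"cogset {rec.cogset!r} appears under two characters "
                    f"({prev!r} and {rec.character!r})"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(sorted({r.taxon for r in self.records}))

    @property
    def characters(self) -> tuple[str, ...]:
        return tuple(sorted({r.character for r in self.records}))

    @property
    def cogsets(self) -> tuple[str, ...]:
        return tuple(sorted({r.cogset for r in self.records}))

    def cogset_character(self) -> dict[str, str]:
        """Map each cogset identifier to its (unique) character."""
        return {r.cogset: r.character for r in self.records}

    def restrict_taxa(self, keep: Iterable[str]) -> "CognateDatabase":
        keep = set(keep)
        return CognateDatabase([r for r in self.records if r.taxon in keep])


@dataclass
class PresenceAbsenceMatrix:
    """Binary taxa x cogsets matrix plus a taxa x characters missing mask.

    ``values[i, j] == 1`` iff taxon ``taxa[i]`` has at least one form in
    cogset ``cogsets[j]``.  ``missing_mask[i, m] == 1`` iff taxon ``taxa[i]``
    has no recorded form for character ``characters[m]``; by construction
    such a taxon scores 0 in every cogset of that character.
    """

    taxa: tuple[str, ...]
    cogsets: tuple[str, ...]
    characters: tuple[str, ...]
    values: np.ndarray
    missing_mask: np.ndarray
    cogset_character: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.missing_mask = np.asarray(self.missing_mask, dtype=np.int8)
        if self.values.shape != (len(self.taxa), len(self.cogsets)):
            raise ValueError("values shape does not match taxa x cogsets")
        if self.missing_mask.shape != (len(self.taxa), len(self.characters)):
            raise ValueError("missing_mask shape does not match taxa x characters")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("presence-absence values must be 0/1")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_cogsets(self) -> int:
        return len(self.cogsets)

    def cogset_character_index(self) -> np.ndarray:
        """Index of each cogset's character into ``self.characters``."""
        char_pos = {c: k for k, c in enumerate(self.characters)}
        return np.array(
            [char_pos[self.cogset_character[c]] for c in self.cogsets], dtype=int
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=list(self.taxa), columns=list(self.cogsets))


def read_database(path, dialect: str = "tsv") -> CognateDatabase:
    """Read a 4-column (taxon, character, cogset, form) table.

    The header row must name at least the first three columns; ``form`` is
    optional and may be empty.  Duplicate identical rows are dropped with a
    warning; a row with a missing required field raises
    :class:`DatabaseParseError` naming the offending line.
    """
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "\t" if dialect == "tsv" else ","
    records: list[CognateRecord] = []
    seen: set[CognateRecord] = set()
    n_dupes = 0
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=sep)
        try:
            header = next(reader)
        except StopIteration:
            raise DatabaseParseError(f"{path}: empty file, expected a header row")
        header = [h.strip() for h in header]
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise DatabaseParseError(
                f"{path}: header lacks required column(s) {', '.join(missing)}"
            )
        idx = {c: header.index(c) for c in REQUIRED_COLUMNS}
        form_idx = header.index(FORM_COLUMN) if FORM_COLUMN in header else None
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue  # blank line
            if len(row) < len(header) - (1 if form_idx == len(header) - 1 else 0):
                raise DatabaseParseError(f"{path}:{lineno}: too few fields")
            vals = {}
            for col, i in idx.items():
                if i >= len(row) or not row[i].strip():
                    raise DatabaseParseError(
                        f"{path}:{lineno}: missing value for column {col!r}"
                    )
                vals[col] = row[i].strip()
            form = None
            if form_idx is not None and form_idx < len(row) and row[form_idx].strip():
                form = row[form_idx].strip()
            rec = CognateRecord(vals["taxon"], vals["character"], vals["cogset"], form)
            if rec in seen:
                n_dupes += 1
                continue
            seen.add(rec)
            records.append(rec)
    if n_dupes:
        warnings.warn(f"{path}: dropped {n_dupes} duplicate record(s)", stacklevel=2)
    return CognateDatabase(records)


def write_database(db: CognateDatabase, path, dialect: str = "tsv") -> None:
    """Write a database back to the 4-column table format."""
    sep = "\t" if dialect == "tsv" else ","
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(list(REQUIRED_COLUMNS) + [FORM_COLUMN])
        for r in db.records:
            writer.writerow([r.taxon, r.character, r.cogset, r.form or ""])


def build_presence_absence(db: CognateDatabase) -> PresenceAbsenceMatrix:
    """Encode a database as a binary taxa x cogsets matrix.

    Taxa and cogsets are ordered lexicographically so that the encoding, and
    everything downstream of it, is deterministic.  A taxon with no record
    for a character is flagged in ``missing_mask`` for that character and
    scores 0 in all of the character's cogsets.
    """
    if not db.records:
        raise ValueError("cannot encode an empty database")
    taxa = db.taxa
    cogsets = db.cogsets
    characters = db.characters
    t_pos = {t: i for i, t in enumerate(taxa)}
    c_pos = {c: j for j, c in enumerate(cogsets)}
    m_pos = {m: k for k, m in enumerate(characters)}

    values = np.zeros((len(taxa), len(cogsets)), dtype=np.int8)
    has_char = np.zeros((len(taxa), len(characters)), dtype=bool)
    for rec in db.records:
        values[t_pos[rec.taxon], c_pos[rec.cogset]] = 1
        has_char[t_pos[rec.taxon], m_pos[rec.character]] = True
    missing_mask = (~has_char).astype(np.int8)
    return PresenceAbsenceMatrix(
        taxa=taxa,
        cogsets=cogsets,
        characters=characters,
        values=values,
        missing_mask=missing_mask,
        cogset_character=db.cogset_character(),
    )
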