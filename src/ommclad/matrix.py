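"""Discrete morphological character matrices.

Cells hold a small-integer state, :data:`MISSING` (``?``) or
:data:`INAPPLICABLE` (``-``).  The two non-states are stored distinctly
so that files round-trip exactly, but both are scored as the full state
set during parsimony (no reductive coding).

Supported dialects: NEXUS (read via dendropy), TNT ``xread``, and a
plain CSV layout (first column taxon, one column per character, header
row with character indices).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "MISSING", "INAPPLICABLE", "CharacterDefinition", "CharacterMatrix",
    "TaxonSet", "read_matrix", "write_matrix",
]

#: Cell code for an unobservable ("?") entry.
MISSING: int = -1
#: Cell code for an inapplicable ("-") entry.
INAPPLICABLE: int = -2

_MAX_STATES = 8


class MatrixParseError(ValueError):
    """Raised when a matrix file cannot be parsed."""


@dataclass(frozen=True)
class CharacterDefinition:
    """One column of the matrix.

    ``ordered`` is kept for completeness; every character handled here
    is unordered (non-additive), i.e. any state may change into any
    other at unit cost.
    """

    index: int
    label: str = ""
    n_states: int = 2
    ordered: bool = False

    def __post_init__(self):
        if not 2 <= self.n_states <= _MAX_STATES:
            raise ValueError(f"character {self.index}: n_states must be in "
                             f"[2, {_MAX_STATES}], got {self.n_states}")
        if self.ordered:
            raise ValueError("ordered characters are not supported")


@dataclass(frozen=True)
class TaxonSet:
    """A named set of taxon labels (outgroup or constraint group)."""

    name: str
    members: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self):
        return len(self.members)


@dataclass
class CharacterMatrix:
    """Rectangular taxa x characters table of discrete states."""

    taxa: list[str]
    characters: list[CharacterDefinition]
    cells: np.ndarray  # int8 [n_taxa, n_characters]

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=np.int8)
        self.validate()

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        n, c = len(self.taxa), len(self.characters)
        if c == 0:
            raise ValueError("matrix has no characters")
        if len(set(self.taxa)) != n:
            raise ValueError("taxon labels are not unique")
        if sorted(ch.index for ch in self.characters) != list(range(c)):
            raise ValueError("character indices must be 0..n_characters-1")
        if self.cells.shape != (n, c):
            raise ValueError(f"cells shape {self.cells.shape} does not match "
                             f"{n} taxa x {c} characters")
        for j, ch in enumerate(self.characters):
            col = self.cells[:, j]
            bad = col[(col >= ch.n_states)]
            if bad.size:
                raise ValueError(f"character {j}: state {bad[0]} out of range "
                                 f"(n_states={ch.n_states})")
            if (col < INAPPLICABLE).any():
                raise ValueError(f"character {j}: invalid cell code")

    # -- shapes and views ---------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def column(self, j: int) -> np.ndarray:
        return self.cells[:, j]

    def taxon_index(self, label: str) -> int:
        try:
            return self.taxa.index(label)
        except ValueError:
            raise KeyError(f"unknown taxon {label!r}") from None

    def state_masks(self) -> np.ndarray:
        """Bitmask encoding used by the parsimony kernels.

        MISSING and INAPPLICABLE both expand to the full state set of
        their character; a state ``s`` becomes ``1 << s``.
        """
        masks = np.zeros((self.n_taxa, self.n_characters), dtype=np.int64)
        for j, ch in enumerate(self.characters):
            full = (1 << ch.n_states) - 1
            col = self.cells[:, j]
            masks[:, j] = np.where(col >= 0, 1 << col.astype(np.int64), full)
        return masks

    def is_informative(self, j: int) -> bool:
        """True if character j can distinguish among trees (two or more
        states each observed in two or more taxa)."""
        col = self.cells[:, j]
        vals, counts = np.unique(col[col >= 0], return_counts=True)
        return int(np.sum(counts >= 2)) >= 2

    def subset_taxa(self, labels: Sequence[str]) -> "CharacterMatrix":
        idx = [self.taxon_index(t) for t in labels]
        return CharacterMatrix(list(labels), list(self.characters),
                               self.cells[idx, :].copy())

    def taxon_set(self, name: str, members: Iterable[str]) -> TaxonSet:
        members = list(members)
        for t in members:
            self.taxon_index(t)
        return TaxonSet(name, frozenset(members))

    def __eq__(self, other) -> bool:
        return (isinstance(other, CharacterMatrix)
                and self.taxa == other.taxa
                and [c.n_states for c in self.characters]
                == [c.n_states for c in other.characters]
                and np.array_equal(self.cells, other.cells))


# ---------------------------------------------------------------------
# symbols

def _cell_to_symbol(v: int) -> str:
    if v == MISSING:
        return "?"
    if v == INAPPLICABLE:
        return "-"
    return str(v)


def _symbol_to_cell(s: str, where: str) -> int:
    if s == "?":
        return MISSING
    if s == "-":
        return INAPPLICABLE
    if s.isdigit():
        return int(s)
    raise MatrixParseError(f"{where}: unexpected state symbol {s!r}")


def _infer_characters(rows: list[list[int]], labels: Sequence[str] | None = None
                      ) -> list[CharacterDefinition]:
    ncols = len(rows[0])
    chars = []
    for j in range(ncols):
        states = [r[j] for r in rows if r[j] >= 0]
        n_states = max(max(states, default=0) + 1, 2)
        lab = labels[j] if labels else ""
        chars.append(CharacterDefinition(j, lab, n_states))
    return chars


# ---------------------------------------------------------------------
# readers

def read_matrix(path, dialect: str) -> CharacterMatrix:
    """Read a matrix file.  ``dialect`` is one of nexus, tnt, csv."""
    path = Path(path)
    if dialect == "nexus":
        return _read_nexus(path)
    if dialect == "tnt":
        return _read_tnt(path)
    if dialect == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_nexus(path: Path) -> CharacterMatrix:
    try:
        dmat = dendropy.StandardCharacterMatrix.get(path=str(path),
                                                    schema="nexus")
    except Exception as exc:  # dendropy raises many error types
        raise MatrixParseError(f"{path}: {exc}") from exc
    taxa = [t.label.replace(" ", "_") for t in dmat.taxon_namespace]
    rows = []
    for t in dmat.taxon_namespace:
        row = []
        for cell in dmat[t]:
            row.append(_symbol_to_cell(str(cell), f"{path}:{t.label}"))
        rows.append(row)
    if not rows:
        raise MatrixParseError(f"{path}: empty matrix")
    return CharacterMatrix(taxa, _infer_characters(rows),
                           np.array(rows, dtype=np.int8))


def _read_tnt(path: Path) -> CharacterMatrix:
    text = path.read_text()
    m = re.search(r"xread\s*(?:'[^']*'\s*)?(\d+)\s+(\d+)(.*?);", text,
                  re.S | re.I)
    if not m:
        raise MatrixParseError(f"{path}: no xread block found")
    nchar, ntax = int(m.group(1)), int(m.group(2))
    taxa, rows = [], []
    for lineno, line in enumerate(m.group(3).strip().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise MatrixParseError(f"{path} line {lineno}: expected "
                                   f"'taxon states', got {line!r}")
        name, states = parts
        if len(states) != nchar:
            raise MatrixParseError(f"{path} line {lineno}: {len(states)} "
                                   f"states, header says {nchar}")
        taxa.append(name)
        rows.append([_symbol_to_cell(s, f"{path} line {lineno}")
                     for s in states])
    if len(taxa) != ntax:
        raise MatrixParseError(f"{path}: {len(taxa)} taxa, header says {ntax}")
    return CharacterMatrix(taxa, _infer_characters(rows),
                           np.array(rows, dtype=np.int8))


def _read_csv(path: Path) -> CharacterMatrix:
    with open(path, newline="") as fh:
        reader = list(csv.reader(fh))
    if len(reader) < 2:
        raise MatrixParseError(f"{path}: need a header row and taxa rows")
    header = reader[0]
    taxa, rows = [], []
    for lineno, rec in enumerate(reader[1:], 2):
        if not rec:
            continue
        if len(rec) != len(header):
            raise MatrixParseError(f"{path} line {lineno}: ragged row")
        taxa.append(rec[0])
        rows.append([_symbol_to_cell(s.strip(), f"{path} line {lineno}")
                     for s in rec[1:]])
    return CharacterMatrix(taxa, _infer_characters(rows),
                           np.array(rows, dtype=np.int8))


# ---------------------------------------------------------------------
# writers

def write_matrix(matrix: CharacterMatrix, path, dialect: str) -> None:
    """Write ``matrix`` to ``path`` in the named dialect.

    The emitted file re-reads to an equal matrix (cells, taxon order and
    the MISSING/INAPPLICABLE distinction are all preserved).
    """
    matrix.validate()
    path = Path(path)
    if dialect == "nexus":
        _write_nexus(matrix, path)
    elif dialect == "tnt":
        _write_tnt(matrix, path)
    elif dialect == "csv":
        _write_csv(matrix, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _row_string(matrix: CharacterMatrix, i: int) -> str:
    return "".join(_cell_to_symbol(int(v)) for v in matrix.cells[i])


def _write_nexus(matrix: CharacterMatrix, path: Path) -> None:
    k = max(ch.n_states for ch in matrix.characters)
    symbols = "".join(str(s) for s in range(k))
    width = max(len(t) for t in matrix.taxa) + 2
    lines = [
        "#NEXUS", "",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};",
        f"    FORMAT DATATYPE=STANDARD SYMBOLS=\"{symbols}\" MISSING=? GAP=-;",
        "    MATRIX",
    ]
    for i, t in enumerate(matrix.taxa):
        lines.append(f"        {t:<{width}}{_row_string(matrix, i)}")
    lines += ["    ;", "END;", ""]
    path.write_text("\n".join(lines))


def _write_tnt(matrix: CharacterMatrix, path: Path) -> None:
    lines = ["xread", f"{matrix.n_characters} {matrix.n_taxa}"]
    for i, t in enumerate(matrix.taxa):
        lines.append(f"{t} {_row_string(matrix, i)}")
    lines += [";", ""]
    path.write_text("\n".join(lines))


def _write_csv(matrix: CharacterMatrix, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["taxon"] + [str(ch.index) for ch in matrix.characters])
        for i, t in enumerate(matrix.taxa):
            writer.writerow([t] + [_cell_to_symbol(int(v))
                                   for v in matrix.cells[i]])
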