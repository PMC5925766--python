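"""Labeled numeric matrices and categorical annotation tables.

The substrate of every heatmap here is a :class:`DataMatrix`: a dense 2-D
float array with unique row and column labels and an explicit missing-value
mask. Missing cells are stored as IEEE NaN internally; on disk they are any
of a configurable set of sentinel tokens (``NA``, ``NaN``, empty by default).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DataMatrix",
    "AnnotationTrack",
    "MatrixParseError",
    "MatrixValidationError",
    "read_matrix",
    "write_matrix",
    "read_annotations",
]

DEFAULT_MISSING_TOKENS = ("NA", "NaN", "")


class MatrixParseError(ValueError):
    """A cell could not be parsed as a number or a missing-value token."""


class MatrixValidationError(ValueError):
    """Shape or label constraints violated (duplicates, empty matrix, ...)."""


@dataclass
class DataMatrix:
    """A labeled numeric matrix with a missing-value mask.

    Parameters
    ----------
    values
        2-D float array, shape ``(n_rows, n_cols)``. Missing cells are NaN.
    row_labels, col_labels
        Unique label strings matching the array dimensions.
    """

    values: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise MatrixValidationError("values must be 2-dimensional")
        n_rows, n_cols = self.values.shape
        if n_rows < 1 or n_cols < 1:
            raise MatrixValidationError("matrix must have at least one row and one column")
        self.row_labels = [str(x) for x in self.row_labels]
        self.col_labels = [str(x) for x in self.col_labels]
        if len(self.row_labels) != n_rows:
            raise MatrixValidationError(
                f"{len(self.row_labels)} row labels for {n_rows} rows")
        if len(self.col_labels) != n_cols:
            raise MatrixValidationError(
                f"{len(self.col_labels)} column labels for {n_cols} columns")
        for kind, labels in (("row", self.row_labels), ("column", self.col_labels)):
            dupes = {x for x in labels if labels.count(x) > 1}
            if dupes:
                raise MatrixValidationError(
                    f"duplicate {kind} label(s): {sorted(dupes)}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean array, True where the value is missing."""
        return np.isnan(self.values)

    def copy_with(self, values: np.ndarray) -> "DataMatrix":
        """New matrix with the same labels and fresh values."""
        return DataMatrix(np.array(values, dtype=float), list(self.row_labels),
                          list(self.col_labels))

    def transpose(self) -> "DataMatrix":
        return DataMatrix(self.values.T.copy(), list(self.col_labels), list(self.row_labels))


@dataclass
class AnnotationTrack:
    """One categorical annotation vector along a matrix axis."""

    axis: str  # "row" or "column"
    name: str
    categories: list[str]
    level_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.axis not in ("row", "column"):
            raise MatrixValidationError(f"axis must be 'row' or 'column', got {self.axis!r}")
        if not self.level_order:
            # levels in order of first appearance
            seen: dict[str, None] = {}
            for c in self.categories:
                seen.setdefault(c, None)
            self.level_order = list(seen)
        extra = set(self.categories) - set(self.level_order)
        if extra:
            raise MatrixValidationError(
                f"categories not in level_order: {sorted(extra)}")


def read_matrix(path, delimiter: str = ",",
                missing_tokens=DEFAULT_MISSING_TOKENS) -> DataMatrix:
    """Read a labeled matrix from a delimited text file.

    First row holds column labels (its first cell — the header of the
    row-label column — is ignored), first column holds row labels. Every
    other cell must parse as a float or be one of ``missing_tokens``.
    """
    missing = set(missing_tokens)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delimiter))
    rows = [r for r in rows if r]  # drop blank trailing lines
    if len(rows) < 2 or len(rows[0]) < 2:
        raise MatrixValidationError(f"{path}: empty matrix (need >=1 row and >=1 column)")
    col_labels = [c.strip() for c in rows[0][1:]]
    row_labels: list[str] = []
    values = np.empty((len(rows) - 1, len(col_labels)), dtype=float)
    for i, row in enumerate(rows[1:]):
        if len(row) != len(col_labels) + 1:
            raise MatrixParseError(
                f"{path}: line {i + 2} has {len(row)} fields, expected {len(col_labels) + 1}")
        row_labels.append(row[0].strip())
        for j, cell in enumerate(row[1:]):
            tok = cell.strip()
            if tok in missing:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(tok)
            except ValueError:
                raise MatrixParseError(
                    f"{path}: cell at row {row[0]!r}, column {col_labels[j]!r} "
                    f"is not numeric: {cell!r}") from None
    return DataMatrix(values, row_labels, col_labels)


def write_matrix(m: DataMatrix, path, delimiter: str = ",",
                 missing_token: str = "NA") -> None:
    """Write a matrix so that :func:`read_matrix` round-trips it bit-exactly.

    Finite values are written with ``repr``, which round-trips doubles.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow([""] + m.col_labels)
        for i, lab in enumerate(m.row_labels):
            cells = [missing_token if np.isnan(v) else repr(float(v))
                     for v in m.values[i]]
            w.writerow([lab] + cells)


def read_annotations(path, axis: str, labels: list[str],
                     delimiter: str = ",") -> list[AnnotationTrack]:
    """Read categorical annotation tracks and align them to a matrix axis.

    The file's first column carries axis labels, the header row carries track
    names; one :class:`AnnotationTrack` is returned per remaining column,
    with categories reordered to match ``labels``.
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delimiter))
    rows = [r for r in rows if r]
    if len(rows) < 2 or len(rows[0]) < 2:
        raise MatrixValidationError(f"{path}: annotation file needs a header and >=1 track column")
    names = [c.strip() for c in rows[0][1:]]
    table: dict[str, list[str]] = {}
    for row in rows[1:]:
        table[row[0].strip()] = [c.strip() for c in row[1:]]
    absent = [lab for lab in labels if lab not in table]
    if absent:
        raise MatrixValidationError(
            f"{path}: annotation file lacks label(s): {absent}")
    tracks = []
    for t, name in enumerate(names):
        cats = [table[lab][t] for lab in labels]
        tracks.append(AnnotationTrack(axis=axis, name=name, categories=cats))
    return tracks
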