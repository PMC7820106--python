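"""Contingency tables and the chi-squared statistic of independence.

A contingency table cross-classifies ``n`` samples into ``I`` groups (rows)
and ``J`` conditions (columns).  Rows are the dimension whose totals
``m_i`` are treated as public throughout this package: the privacy
mechanisms assume the row margins are released alongside the private
statistic, and the global-sensitivity formulas depend on that orientation.
Transposing a table therefore changes the sensitivity; CSV input follows
the same rows-are-groups convention (see :func:`read_table_csv`).

The test statistic is the classical Pearson chi-squared

    chi2 = sum_ij (E_ij - O_ij)^2 / E_ij,   E_ij = s_j * m_i / n,

with ``(I-1)(J-1)`` degrees of freedom, where ``O_ij`` are observed counts,
``m_i`` row totals and ``s_j`` column totals.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import (
    DimensionError,
    InvalidCountError,
    TableFormatError,
    ZeroMarginError,
)

__all__ = [
    "ContingencyTable",
    "ChiSquaredResult",
    "build_table",
    "chi_squared",
    "min_cell_ok",
    "read_table_csv",
    "write_table_csv",
    "write_outcome",
]


@dataclass(frozen=True)
class ContingencyTable:
    """An I x J matrix of non-negative integer counts with derived margins."""

    counts: np.ndarray

    @property
    def row_margins(self) -> np.ndarray:
        """Row totals ``m_i`` (the public dimension)."""
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        """Column totals ``s_j``."""
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_rows(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cols(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class ChiSquaredResult:
    """Chi-squared statistic with its per-cell decomposition.

    ``statistic`` is the sum of ``contributions``; ``expected`` carries the
    independence-model expected counts and ``dof = (I-1)(J-1)``.
    """

    statistic: float
    contributions: np.ndarray
    expected: np.ndarray
    dof: int


def build_table(counts) -> ContingencyTable:
    """Validate a count matrix and wrap it as a :class:`ContingencyTable`.

    Requires at least 2 rows and 2 columns, all entries integral and >= 0,
    and a positive grand total.
    """
    arr = np.asarray(counts)
    if arr.ndim != 2:
        raise DimensionError(f"counts must be a 2-D matrix, got ndim={arr.ndim}")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DimensionError(
            f"table must be at least 2x2, got {arr.shape[0]}x{arr.shape[1]}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        as_float = np.asarray(arr, dtype=float)
        if not np.all(np.isfinite(as_float)) or np.any(as_float != np.floor(as_float)):
            raise InvalidCountError("counts must all be integers")
        arr = as_float.astype(np.int64)
    if np.any(arr < 0):
        i, j = np.argwhere(arr < 0)[0]
        raise InvalidCountError(f"negative count at cell [{i},{j}]")
    arr = arr.astype(np.int64)
    if arr.sum() < 1:
        raise InvalidCountError("table is all zeros")
    arr = arr.copy()
    arr.setflags(write=False)
    return ContingencyTable(counts=arr)


def chi_squared(table: ContingencyTable) -> ChiSquaredResult:
    """Pearson chi-squared statistic of independence for ``table``.

    Every row and column margin must be positive, otherwise some expected
    count is zero and the statistic is undefined; such tables are rejected
    with :class:`ZeroMarginError`.
    """
    m = table.row_margins
    s = table.col_margins
    if np.any(m == 0):
        i = int(np.argwhere(m == 0)[0][0])
        raise ZeroMarginError(f"row {i} has zero margin; chi-squared is undefined")
    if np.any(s == 0):
        j = int(np.argwhere(s == 0)[0][0])
        raise ZeroMarginError(f"column {j} has zero margin; chi-squared is undefined")
    n = table.total
    expected = np.outer(m, s) / n
    contributions = (expected - table.counts) ** 2 / expected
    dof = (table.n_rows - 1) * (table.n_cols - 1)
    return ChiSquaredResult(
        statistic=float(contributions.sum()),
        contributions=contributions,
        expected=expected,
        dof=dof,
    )


def min_cell_ok(counts, threshold: float = 5.0) -> bool:
    """Rule-of-thumb check: True iff every entry is >= ``threshold``.

    The chi-squared approximation to the null distribution is unreliable
    when cells are small; the conventional cutoff is five, inclusive.
    Accepts real-valued matrices (noisy tables are checked too).
    """
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0:
        raise InvalidCountError("empty matrix")
    return bool(np.all(arr >= threshold))


def _is_int_token(tok: str) -> bool:
    try:
        int(tok)
        return True
    except ValueError:
        return False


def read_table_csv(path) -> ContingencyTable:
    """Read a contingency table from CSV.

    Rows are groups (public margins), columns are conditions.  A single
    header row and/or a leading row-label column are auto-detected: any row
    or column whose entries do not parse as integers is treated as labels.
    """
    path = Path(path)
    rows: list[list[str]] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            cells = [c.strip() for c in row]
            if not cells or all(c == "" for c in cells):
                continue
            rows.append(cells)
            if len(cells) != len(rows[0]):
                raise TableFormatError(
                    f"ragged row: expected {len(rows[0])} fields, got {len(cells)}",
                    line=lineno,
                )
    if not rows:
        raise TableFormatError("empty CSV file", line=1)

    has_header = not all(_is_int_token(c) for c in rows[0][1:] or rows[0])
    body = rows[1:] if has_header else rows
    if not body:
        raise TableFormatError("no data rows after header", line=1)
    has_labels = not all(_is_int_token(r[0]) for r in body)
    counts = []
    offset = 1 + (1 if has_header else 0)
    for lineno, row in enumerate(body, start=offset):
        data = row[1:] if has_labels else row
        parsed = []
        for tok in data:
            if not _is_int_token(tok):
                raise TableFormatError(f"non-integer count {tok!r}", line=lineno)
            parsed.append(int(tok))
        counts.append(parsed)
    return build_table(counts)


def write_table_csv(path, table: ContingencyTable) -> None:
    """Write counts as plain CSV (no header); round-trips with reader."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for row in np.asarray(table.counts):
            writer.writerow([int(v) for v in row])


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and not math.isfinite(obj):
        return repr(obj)
    return obj


def write_outcome(path, outcome) -> None:
    """Serialize a test outcome (dataclass or dict) as JSON.

    Floats keep full precision via Python's repr round-trip guarantee.
    """
    with open(path, "w") as fh:
        json.dump(_jsonable(outcome), fh, indent=2)
        fh.write("\n")
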