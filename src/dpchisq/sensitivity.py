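"""Global sensitivity of the chi-squared statistic with public row margins.

With the row totals ``m_i`` published, two neighboring tables differ by
moving one unit between two columns within a single row.  The global
sensitivity is the maximum change of the chi-squared statistic over all
such neighbor pairs, taken over every table with the given margins.

Closed forms implemented here:

* :func:`randchidist_sensitivity` -- the I x J formula used by the
  RandChiDist mechanism.  With ``m_a`` the smallest and ``m_b`` the second
  smallest row margin and ``n = sum m_i``::

      Delta_R = (m_a + m_b) * n / (m_a * (1 + m_b))   for J >= 3
      Delta_R = n^2 / (m_a * (n - m_a + 1))           for J = 2

* :func:`yu_sensitivity` -- the 2 x 3 formula of Yu et al.,
  ``Delta_Y = n^2/(m1 m2) * (1 - 1/(max(m1,m2)+1))``.

* :func:`fienberg_sensitivity` -- the equal-margin 2-row formula of
  Fienberg et al., ``Delta_F = 4n/(n+2)``.

* :func:`brute_force_sensitivity` -- an exhaustive oracle that enumerates
  every table with the given margins and every neighbor move, and returns
  the maximum observed |chi2(D1) - chi2(D2)|.  It validates the closed
  forms empirically and is deliberately independent of them.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, prod

import numpy as np

from .exceptions import EnumerationBudgetError, SensitivityError

__all__ = [
    "SensitivitySpec",
    "randchidist_sensitivity",
    "yu_sensitivity",
    "fienberg_sensitivity",
    "brute_force_sensitivity",
]


@dataclass(frozen=True)
class SensitivitySpec:
    """A computed global sensitivity and the quantities it was built from."""

    value: float
    variant: str
    row_margins: tuple[int, ...]
    n_cols: int
    total: int
    min_margin: int | None = None
    second_min_margin: int | None = None


def _validate_margins(row_margins) -> tuple[int, ...]:
    margins = tuple(int(m) for m in np.atleast_1d(np.asarray(row_margins)))
    if len(margins) < 2:
        raise SensitivityError("need at least two row margins")
    if any(m < 1 for m in margins):
        raise SensitivityError("all row margins must be >= 1")
    return margins


def randchidist_sensitivity(row_margins, n_cols: int) -> SensitivitySpec:
    """Global sensitivity of chi-squared for an I x J table, margins public.

    Ties for the smallest margin are broken by the lowest row index; the
    result depends only on the two smallest values, so tie-breaking cannot
    change it (checked by a property test).
    """
    margins = _validate_margins(row_margins)
    n_cols = int(n_cols)
    if n_cols < 2:
        raise SensitivityError(f"need at least 2 columns, got {n_cols}")
    n = sum(margins)
    order = sorted(range(len(margins)), key=lambda i: (margins[i], i))
    m_a = margins[order[0]]
    m_b = margins[order[1]]
    if n_cols == 2:
        value = n * n / (m_a * (n - m_a + 1))
    else:
        value = (m_a + m_b) * n / (m_a * (1 + m_b))
    return SensitivitySpec(
        value=float(value),
        variant="randchidist",
        row_margins=margins,
        n_cols=n_cols,
        total=n,
        min_margin=m_a,
        second_min_margin=m_b,
    )


def yu_sensitivity(m1: int, m2: int) -> SensitivitySpec:
    """Two-row (2 x 3) sensitivity with both row margins public."""
    m1, m2 = int(m1), int(m2)
    if m1 < 1 or m2 < 1:
        raise SensitivityError("row margins must be >= 1")
    n = m1 + m2
    value = (n * n / (m1 * m2)) * (1.0 - 1.0 / (max(m1, m2) + 1))
    return SensitivitySpec(
        value=float(value),
        variant="yu",
        row_margins=(m1, m2),
        n_cols=3,
        total=n,
        min_margin=min(m1, m2),
        second_min_margin=max(m1, m2),
    )


def fienberg_sensitivity(n: int) -> SensitivitySpec:
    """Equal-margin two-row sensitivity, ``Delta_F = 4n/(n+2)``.

    Requires ``n`` even, since the premise is m1 = m2 = n/2.
    """
    n = int(n)
    if n < 2:
        raise SensitivityError("n must be >= 2")
    if n % 2 != 0:
        raise SensitivityError("n must be even (equal margins m1 = m2 = n/2)")
    m = n // 2
    return SensitivitySpec(
        value=float(4.0 * n / (n + 2)),
        variant="fienberg",
        row_margins=(m, m),
        n_cols=3,
        total=n,
        min_margin=m,
        second_min_margin=m,
    )


def _compositions(m: int, j: int) -> np.ndarray:
    """All (C(m+j-1, j-1), j) weak compositions of m into j parts, lex order."""
    bars = np.array(list(combinations(range(m + j - 1), j - 1)), dtype=np.int64)
    if j == 1:
        return np.full((1, 1), m, dtype=np.int64)
    padded = np.concatenate(
        [
            np.full((bars.shape[0], 1), -1, dtype=np.int64),
            bars,
            np.full((bars.shape[0], 1), m + j - 1, dtype=np.int64),
        ],
        axis=1,
    )
    return np.diff(padded, axis=1) - 1


def _cartesian_tables(comps: list[np.ndarray]) -> np.ndarray:
    """Stack per-row composition choices into a (N, I, J) count tensor."""
    sizes = [c.shape[0] for c in comps]
    n_tables = prod(sizes)
    i_rows = len(comps)
    j_cols = comps[0].shape[1]
    out = np.empty((n_tables, i_rows, j_cols), dtype=np.int64)
    for i, c in enumerate(comps):
        inner = prod(sizes[i + 1 :])
        outer = prod(sizes[:i])
        out[:, i, :] = np.tile(np.repeat(c, inner, axis=0), (outer, 1))
    return out


def _max_neighbor_diff(
    counts: np.ndarray, margins: np.ndarray, zero_columns: str
) -> float:
    """Max |chi2(D1) - chi2(D2)| over unit moves within rows, vectorized.

    Uses the column decomposition chi2 = sum_j (n*Q_j/s_j - s_j) with
    Q_j = sum_i O_ij^2 / m_i, so a move touching columns k and l only
    needs those two columns re-evaluated.

    ``zero_columns`` controls the domain at empty columns, where the raw
    statistic is 0/0: ``"extend"`` assigns empty columns zero contribution
    (the continuous limit, and what the closed form's maximizing tables
    require); ``"skip"`` drops every neighbor pair touching a table with
    an empty column.
    """
    n = int(margins.sum())
    i_rows, j_cols = counts.shape[1], counts.shape[2]
    s = counts.sum(axis=1).astype(float)
    q = (counts.astype(float) ** 2 / margins[None, :, None].astype(float)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        col_contrib = np.where(s > 0, n * q / np.where(s > 0, s, 1.0) - s, 0.0)
    strict = zero_columns == "skip"
    valid = (s > 0).all(axis=1) if strict else np.ones(counts.shape[0], dtype=bool)
    best = 0.0
    for a in range(i_rows):
        m_a = float(margins[a])
        for l in range(j_cols):
            o_al = counts[:, a, l]
            for k in range(j_cols):
                if k == l:
                    continue
                feas = valid & (o_al >= 1)
                if strict:
                    feas &= s[:, l] >= 2
                if not feas.any():
                    continue
                sk = s[feas, k]
                sl = s[feas, l]
                qk = q[feas, k] + (2 * counts[feas, a, k] + 1) / m_a
                ql = q[feas, l] - (2 * o_al[feas] - 1) / m_a
                new_k = n * qk / (sk + 1) - (sk + 1)
                sl_new = sl - 1
                new_l = np.where(
                    sl_new > 0, n * ql / np.where(sl_new > 0, sl_new, 1.0) - sl_new, 0.0
                )
                diff = np.abs(
                    new_k + new_l - col_contrib[feas, k] - col_contrib[feas, l]
                )
                cand = float(diff.max())
                if cand > best:
                    best = cand
    return best


def brute_force_sensitivity(
    row_margins, n_cols: int, *, budget: int = 10_000_000, zero_columns: str = "extend"
) -> SensitivitySpec:
    """Exhaustive global-sensitivity oracle.

    Enumerates every table with the given row margins (compositions of each
    ``m_i`` into ``J`` parts, lexicographic per row) and maximizes the
    statistic's change over every neighbor obtained by moving one unit
    between two columns of one row.  Enumeration is chunked over the first
    row so memory stays bounded.

    At an empty column the raw statistic is a 0/0 form; by default
    (``zero_columns="extend"``) empty columns contribute zero, the
    continuous limit, under which the maximizing table pairs of the closed
    form exist.  ``zero_columns="skip"`` instead excludes every neighbor
    pair touching a table with an empty column, which can only lower the
    maximum.
    """
    margins = _validate_margins(row_margins)
    if zero_columns not in ("extend", "skip"):
        raise SensitivityError(f"zero_columns must be 'extend' or 'skip', got {zero_columns!r}")
    n_cols = int(n_cols)
    if n_cols < 2:
        raise SensitivityError(f"need at least 2 columns, got {n_cols}")
    n_tables = prod(comb(m + n_cols - 1, n_cols - 1) for m in margins)
    if n_tables > budget:
        raise EnumerationBudgetError(
            f"{n_tables} tables with margins {margins} exceeds budget {budget}"
        )
    comps = [_compositions(m, n_cols) for m in margins]
    marr = np.asarray(margins, dtype=np.int64)
    tail = _cartesian_tables(comps[1:]) if len(comps) > 1 else None
    n_tail = tail.shape[0]
    chunk = max(1, 2_000_000 // max(n_tail, 1))
    best = 0.0
    first = comps[0]
    for start in range(0, first.shape[0], chunk):
        block = first[start : start + chunk]
        b = block.shape[0]
        counts = np.empty((b * n_tail, len(margins), n_cols), dtype=np.int64)
        counts[:, 0, :] = np.repeat(block, n_tail, axis=0)
        counts[:, 1:, :] = np.tile(tail, (b, 1, 1))
        best = max(best, _max_neighbor_diff(counts, marr, zero_columns))
    m_sorted = sorted(margins)
    return SensitivitySpec(
        value=best,
        variant="brute_force",
        row_margins=margins,
        n_cols=n_cols,
        total=sum(margins),
        min_margin=m_sorted[0],
        second_min_margin=m_sorted[1],
    )
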