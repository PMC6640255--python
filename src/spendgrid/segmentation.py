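"""Within-person monthly spending-order indices and the month-by-index
segment grids.

Each beneficiary's M monthly totals are ranked highest-to-lowest into a
*spending-order index*: index 1 marks that beneficiary's highest-spend
month, index M the lowest.  Indices are unique even under tied values (zero
months included), so each beneficiary's month-to-index map is a permutation
of 1..M.  Aggregating cohort spend and headcounts over (calendar month,
index) yields two M x M grids — 144 cells in the standard 12-month setting —
that expose within-year concentration the plain monthly series hides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .claims import MonthlySpendMatrix

TieRule = Literal["chronological", "reverse-chronological"]


def assign_spending_order(
    monthly_spend: Sequence[int] | np.ndarray,
    tie_rule: TieRule = "chronological",
) -> np.ndarray:
    """Rank one beneficiary's months by spending, descending, ties unique.

    Returns an array ``idx`` with ``idx[m-1]`` the 1-based spending-order
    index of calendar month m.  Under the default ``chronological`` rule the
    earlier of two tied months takes the smaller (higher-spend) index;
    ``reverse-chronological`` gives it to the later month.  An all-zero year
    is legal — the indices then follow the tie rule alone.

    >>> assign_spending_order([5, 0, 7]).tolist()
    [2, 3, 1]
    """
    v = np.asarray(monthly_spend)
    if v.ndim != 1:
        raise ValueError("monthly_spend must be a 1-D vector")
    return _orders_for_rows(v[np.newaxis, :], tie_rule)[0]


def _orders_for_rows(values: np.ndarray, tie_rule: TieRule) -> np.ndarray:
    """Vectorised spending-order assignment for an (n, M) int array."""
    n, m = values.shape
    if tie_rule == "chronological":
        # stable argsort keeps earlier months first among ties
        perm = np.argsort(-values, axis=1, kind="stable")
    elif tie_rule == "reverse-chronological":
        rev = np.argsort(-values[:, ::-1], axis=1, kind="stable")
        perm = m - 1 - rev
    else:
        raise ValueError(f"unknown tie rule {tie_rule!r}")
    orders = np.empty((n, m), dtype=np.int64)
    np.put_along_axis(orders, perm, np.arange(1, m + 1, dtype=np.int64)[None, :], axis=1)
    return orders


@dataclass(frozen=True)
class OrderAssignment:
    """Per-beneficiary permutation mapping calendar month to spending index.

    ``orders[i, m-1]`` is the index (1..M) held by beneficiary i in month m.
    """

    beneficiary_ids: tuple[str, ...]
    orders: np.ndarray  # (n, M) int64, each row a permutation of 1..M
    tie_rule: TieRule = "chronological"

    def __post_init__(self) -> None:
        orders = np.asarray(self.orders, dtype=np.int64)
        if orders.ndim != 2 or orders.shape[0] != len(self.beneficiary_ids):
            raise ValueError("orders shape does not match beneficiary_ids")
        object.__setattr__(self, "orders", orders)
        object.__setattr__(
            self, "_index", {b: i for i, b in enumerate(self.beneficiary_ids)}
        )

    @property
    def months(self) -> int:
        return self.orders.shape[1]

    def for_beneficiary(self, beneficiary_id: str) -> np.ndarray:
        return self.orders[self._index[beneficiary_id]]

    def row_indices(self, beneficiary_ids: Iterable[str]) -> np.ndarray:
        index = self._index
        try:
            return np.array([index[b] for b in beneficiary_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"no order assignment for beneficiary {exc.args[0]!r}")

    @classmethod
    def from_matrix(
        cls,
        matrix: MonthlySpendMatrix,
        cohort_ids: Optional[Iterable[str]] = None,
        tie_rule: TieRule = "chronological",
    ) -> "OrderAssignment":
        """Assign spending-order indices for every (or a subset of) beneficiary."""
        if cohort_ids is None:
            ids = matrix.beneficiary_ids
            values = matrix.values
        else:
            ids = tuple(cohort_ids)
            values = matrix.values[matrix.row_indices(ids)]
        return cls(ids, _orders_for_rows(values, tie_rule), tie_rule)


@dataclass(frozen=True)
class SegmentGrid:
    """Month-by-index aggregate of cohort spend (cents) or headcounts.

    ``cells[m-1, k-1]`` is the aggregate over beneficiaries holding spending
    index k in calendar month m.  Spend-grid columns of a month sum to that
    month's baseline total; count-grid columns each sum to the cohort size.
    """

    kind: Literal["spend", "count"]
    cells: np.ndarray  # (M months, M indices) int64

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=np.int64)
        if cells.ndim != 2 or cells.shape[0] != cells.shape[1]:
            raise ValueError("grid must be square (months x indices)")
        object.__setattr__(self, "cells", cells)

    @property
    def months(self) -> int:
        return self.cells.shape[0]

    def month_totals(self) -> np.ndarray:
        """Per-month sum across indices (baseline totals / cohort size)."""
        return self.cells.sum(axis=1)

    def index_series(self, index: int) -> np.ndarray:
        """The cells of one spending index across all months."""
        return self.cells[:, index - 1]

    def to_frame(self) -> pd.DataFrame:
        """Wide layout: one row per index, one column per month."""
        m = self.months
        df = pd.DataFrame(
            self.cells.T,
            index=pd.Index(range(1, m + 1), name="index"),
            columns=[f"m{i}" for i in range(1, m + 1)],
        )
        return df

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def read(cls, path: str | Path, kind: Literal["spend", "count"]) -> "SegmentGrid":
        df = pd.read_csv(path, index_col="index")
        return cls(kind, df.to_numpy(dtype=np.int64).T)


def segment_spend(
    matrix: MonthlySpendMatrix,
    orders: OrderAssignment,
    cohort_ids: Iterable[str],
) -> SegmentGrid:
    """Aggregate cohort spending over (month, spending index).

    cell(m, k) = sum of value(b, m) over cohort members b whose month-m
    index is k.  Raises KeyError if a cohort member lacks an order
    assignment.
    """
    ids = tuple(cohort_ids)
    m = matrix.months
    grid = np.zeros((m, m), dtype=np.int64)
    if not ids:
        return SegmentGrid("spend", grid)
    values = matrix.values[matrix.row_indices(ids)]
    ranks = orders.orders[orders.row_indices(ids)]
    if ranks.shape[1] != m:
        raise ValueError("order assignment and matrix disagree on month count")
    for month in range(m):
        np.add.at(grid[month], ranks[:, month] - 1, values[:, month])
    return SegmentGrid("spend", grid)


def segment_counts(
    orders: OrderAssignment,
    cohort_ids: Iterable[str],
) -> SegmentGrid:
    """Count cohort members per (month, spending index) cell."""
    ids = tuple(cohort_ids)
    m = orders.months
    grid = np.zeros((m, m), dtype=np.int64)
    if not ids:
        return SegmentGrid("count", grid)
    ranks = orders.orders[orders.row_indices(ids)]
    for month in range(m):
        grid[month] = np.bincount(ranks[:, month] - 1, minlength=m)
    return SegmentGrid("count", grid)


def segment_summary(
    grid: SegmentGrid,
    sd_convention: Literal["population", "sample"] = "population",
) -> pd.DataFrame:
    """Per-index mean, SD, and share across the M months.

    The share column gives each index's portion (percent, unrounded) of the
    grand total — for a spend grid, the index's share of mean baseline
    monthly spending; for a count grid, its share of the cohort.
    """
    cells = grid.cells.astype(float)
    means = cells.mean(axis=0)
    ddof = 0 if sd_convention == "population" else 1
    sds = cells.std(axis=0, ddof=ddof) if grid.months > ddof else np.zeros_like(means)
    total = means.sum()
    shares = 100.0 * means / total if total else np.zeros_like(means)
    return pd.DataFrame(
        {
            "index": np.arange(1, grid.months + 1),
            "mean": means,
            "sd": sds,
            "share_pct": shares,
        }
    )


def grids_to_long(
    spend: SegmentGrid, counts: SegmentGrid
) -> pd.DataFrame:
    """Long-format (month, index, spend_cents, count) table for plotting."""
    if spend.months != counts.months:
        raise ValueError("grids have different month counts")
    m = spend.months
    month, index = np.divmod(np.arange(m * m), m)
    return pd.DataFrame(
        {
            "month": month + 1,
            "index": index + 1,
            "spend_cents": spend.cells.ravel(),
            "count": counts.cells.ravel(),
        }
    )


def write_grid_metadata(
    path: str | Path, tie_rule: TieRule, months: int, n_cohort: int
) -> None:
    Path(path).write_text(
        json.dumps(
            {"tie_rule": tie_rule, "months": months, "n_cohort": n_cohort},
            sort_keys=True,
            indent=2,
        )
        + "\n"
    )
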