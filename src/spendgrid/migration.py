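"""Anchor subgroups and their migration through the segment grids.

The *anchor subgroup* of month m is every cohort member whose spending-order
index equals 1 in m — the people who made up that month's highest-spending
segment.  Because each beneficiary has exactly one index-1 month, the M
anchor subgroups partition the cohort.  Tracking each subgroup's occupancy
of all (month, index) cells shows how members climb from lower segments into
their anchor month and fall back afterwards, while the full grids stay in a
dynamic equilibrium: cell totals are stable month to month even though their
membership turns over.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .claims import MonthlySpendMatrix
from .segmentation import OrderAssignment, SegmentGrid, segment_counts, segment_spend


@dataclass(frozen=True)
class Subgroup:
    """Beneficiaries holding spending index 1 in the anchor month."""

    anchor_month: int
    member_ids: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class OccupancyGrid:
    """One subgroup's contribution to every (month, index) cell.

    The anchor month's index-1 cells hold the whole subgroup; every other
    index-1 cell is empty (a beneficiary has only one index-1 month), and the
    subgroup headcount summed over indices is constant across months.
    """

    anchor_month: int
    counts: SegmentGrid
    spend: SegmentGrid

    @property
    def n_members(self) -> int:
        return int(self.counts.cells[self.anchor_month - 1, 0])

    def monthly_spend(self) -> np.ndarray:
        """Subgroup total spend per calendar month (cents) — its trajectory."""
        return self.spend.month_totals()


def isolate_top_subgroup(orders: OrderAssignment, anchor_month: int) -> Subgroup:
    """Members whose spending-order index in ``anchor_month`` is 1."""
    if not 1 <= anchor_month <= orders.months:
        raise ValueError(
            f"anchor_month must be in 1..{orders.months}, got {anchor_month}"
        )
    mask = orders.orders[:, anchor_month - 1] == 1
    members = tuple(b for b, hit in zip(orders.beneficiary_ids, mask) if hit)
    return Subgroup(anchor_month, members)


def subgroup_occupancy(
    subgroup: Subgroup,
    matrix: MonthlySpendMatrix,
    orders: OrderAssignment,
) -> OccupancyGrid:
    """Count and spend grids restricted to the subgroup's members."""
    return OccupancyGrid(
        anchor_month=subgroup.anchor_month,
        counts=segment_counts(orders, subgroup.member_ids),
        spend=segment_spend(matrix, orders, subgroup.member_ids),
    )


def all_subgroup_occupancy(
    matrix: MonthlySpendMatrix,
    orders: OrderAssignment,
) -> list[OccupancyGrid]:
    """One occupancy grid per anchor month, 1..M.

    The returned grids sum cell-wise to the full cohort grids, and each
    anchor month's index-1 cell is covered entirely by its own subgroup —
    the stacked-layer decomposition.
    """
    return [
        subgroup_occupancy(isolate_top_subgroup(orders, m), matrix, orders)
        for m in range(1, matrix.months + 1)
    ]


def occupancy_to_long(grids: list[OccupancyGrid]) -> pd.DataFrame:
    """Long-format (anchor_month, month, index, count, spend_cents) table."""
    frames = []
    for g in grids:
        m = g.counts.months
        month, index = np.divmod(np.arange(m * m), m)
        frames.append(
            pd.DataFrame(
                {
                    "anchor_month": g.anchor_month,
                    "month": month + 1,
                    "index": index + 1,
                    "count": g.counts.cells.ravel(),
                    "spend_cents": g.spend.cells.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def migration_summary(
    spend_grid: SegmentGrid,
    count_grid: SegmentGrid,
    occupancies: list[OccupancyGrid],
) -> list[dict]:
    """Per-anchor-month migration summary.

    For each anchor month: the subgroup's share of the cohort, its share of
    that month's baseline spending, and its monthly spend trajectory
    (totals, in cents).  Shares are unrounded percentages.
    """
    n_cohort = int(count_grid.month_totals()[0]) if count_grid.months else 0
    baseline = spend_grid.month_totals()
    out = []
    for g in occupancies:
        m = g.anchor_month
        anchor_total = int(baseline[m - 1])
        anchor_spend = int(g.spend.cells[m - 1, 0])
        out.append(
            {
                "anchor_month": m,
                "subgroup_size": g.n_members,
                "share_of_cohort_pct": (
                    100.0 * g.n_members / n_cohort if n_cohort else 0.0
                ),
                "share_of_anchor_month_spend_pct": (
                    100.0 * anchor_spend / anchor_total if anchor_total else 0.0
                ),
                "monthly_spend_cents": [int(v) for v in g.monthly_spend()],
            }
        )
    return out
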