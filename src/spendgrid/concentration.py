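"""Yearly spending concentration: high-cost cohort selection and the
cohort's baseline monthly spending series.

The high-cost subpopulation is the top fraction of beneficiaries ranked by
yearly total expenditure.  The cohort size is ``ceil(fraction * N)`` — the
rounding rule under which a 10% cut of 1,222,402 beneficiaries yields exactly
122,241 members.  Ties at the cutoff are broken by a documented,
configurable rule (default: ascending beneficiary id).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np

from .claims import MonthlySpendMatrix

TieRule = Literal["ascending_id", "descending_id"]
SdConvention = Literal["population", "sample"]

# Guards against float representation pushing fraction*N just above an
# integer boundary (e.g. 0.1 * 1222402 -> 122240.20000000001 is harmless,
# but 0.3 * 10 -> 2.9999999999999996 would mis-ceil without it).
_CEIL_EPS = 1e-9


def cohort_size(n_population: int, fraction: float) -> int:
    """Number of beneficiaries in the top-``fraction`` cohort: ceil(f*N)."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if n_population < 1:
        raise ValueError("population must be non-empty")
    return min(n_population, max(1, math.ceil(fraction * n_population - _CEIL_EPS)))


@dataclass(frozen=True)
class CohortSelection:
    """The selected high-cost cohort, ordered highest yearly spender first."""

    cohort_ids: tuple[str, ...]
    fraction: float
    cutoff_rank: int
    cohort_yearly_total: int  # cents
    population_yearly_total: int  # cents

    def __post_init__(self) -> None:
        if len(self.cohort_ids) != self.cutoff_rank:
            raise ValueError("cohort size must equal the cutoff rank")


@dataclass(frozen=True)
class BaselineSeries:
    """The cohort's aggregate spending per calendar month, in cents."""

    monthly_totals: tuple[int, ...]
    mean_monthly: float
    sd_monthly: float
    sd_convention: SdConvention = "population"


def yearly_totals(matrix: MonthlySpendMatrix) -> dict[str, int]:
    """Per-beneficiary yearly total expenditure (row sums), in cents."""
    sums = matrix.values.sum(axis=1)
    return {b: int(s) for b, s in zip(matrix.beneficiary_ids, sums)}


def select_top_fraction(
    totals: Mapping[str, int],
    fraction: float,
    tie_rule: TieRule = "ascending_id",
) -> CohortSelection:
    """Select the top-spending ``ceil(fraction * N)`` beneficiaries.

    Beneficiaries are ordered by yearly total descending; equal totals are
    ordered by beneficiary id (ascending by default) so the cutoff is
    deterministic.
    """
    if not totals:
        raise ValueError("totals must be non-empty")
    k = cohort_size(len(totals), fraction)
    if tie_rule == "ascending_id":
        ordered = sorted(totals, key=lambda b: (-totals[b], b))
    elif tie_rule == "descending_id":
        ordered = sorted(totals, key=lambda b: b, reverse=True)
        ordered.sort(key=lambda b: -totals[b])  # stable: keeps id order in ties
    else:
        raise ValueError(f"unknown tie rule {tie_rule!r}")
    cohort = tuple(ordered[:k])
    return CohortSelection(
        cohort_ids=cohort,
        fraction=fraction,
        cutoff_rank=k,
        cohort_yearly_total=int(sum(totals[b] for b in cohort)),
        population_yearly_total=int(sum(totals.values())),
    )


def concentration_share(selection: CohortSelection) -> float:
    """Cohort share of population yearly spending, in percent (unrounded)."""
    if selection.population_yearly_total == 0:
        raise ValueError("population yearly total is zero")
    return 100.0 * selection.cohort_yearly_total / selection.population_yearly_total


def baseline_monthly(
    matrix: MonthlySpendMatrix,
    cohort_ids: Iterable[str],
    sd_convention: SdConvention = "population",
) -> BaselineSeries:
    """Aggregate cohort spending by calendar month.

    The mean and standard deviation are taken over the M monthly totals.
    The SD convention defaults to population (divide by M); sample
    (divide by M-1) is available since reported figures rarely state which
    was used.
    """
    idx = matrix.row_indices(cohort_ids)
    monthly = matrix.values[idx].sum(axis=0)
    ddof = 0 if sd_convention == "population" else 1
    return BaselineSeries(
        monthly_totals=tuple(int(v) for v in monthly),
        mean_monthly=float(np.mean(monthly)),
        sd_monthly=float(np.std(monthly, ddof=ddof)) if len(monthly) > ddof else 0.0,
        sd_convention=sd_convention,
    )
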