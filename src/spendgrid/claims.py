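"""Claim-level and eligibility data: types, delimited-text readers, and the
beneficiary-by-month expenditure matrix.

All currency is held as **integer cents** internally.  Dollar amounts appear
only at the file boundary (input columns, human-readable reports), which lets
aggregate sums satisfy exact conservation identities without float drift.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default column names expected in delimited claim files.  Pass a ``dialect``
#: mapping to :func:`read_claims` to adapt to other headers.
CLAIM_COLUMNS = {
    "beneficiary_id": "beneficiary_id",
    "claim_through_date": "claim_through_date",
    "paid_amount": "paid_amount",
}

ELIGIBILITY_COLUMNS = {
    "beneficiary_id": "beneficiary_id",
    "age_eligible": "age_eligible",
    "continuously_enrolled": "continuously_enrolled",
    "death_month": "death_month",
}


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class RowParseError(ValueError):
    """A row's date or amount could not be parsed; carries the line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class ClaimRecord:
    """One paid claim line.

    A claim is attributed to the calendar month of its *claim-through date*
    (the service-period end date).  ``paid_cents`` may be negative for
    payment adjustments.
    """

    beneficiary_id: str
    claim_through_date: datetime.date
    paid_cents: int

    def __post_init__(self) -> None:
        if not self.beneficiary_id:
            raise ValueError("beneficiary_id must be non-empty")


@dataclass(frozen=True)
class EligibilityRecord:
    """Denominator-file entry: precomputed enrollment booleans.

    ``death_month`` is 1-based within the study period; decedents stay in the
    study denominator all year (their post-death months carry zero spending).
    """

    beneficiary_id: str
    age_eligible: bool
    continuously_enrolled: bool
    death_month: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.beneficiary_id:
            raise ValueError("beneficiary_id must be non-empty")
        if self.death_month is not None and self.death_month < 1:
            raise ValueError(f"death_month must be >= 1, got {self.death_month}")


def parse_amount_cents(text: str) -> int:
    """Parse a dollar amount (optional sign, up to 2 decimals) to integer cents.

    >>> parse_amount_cents("-15.00")
    -1500
    """
    try:
        cents = Decimal(text.strip()) * 100
    except InvalidOperation as exc:
        raise ValueError(f"unparseable amount {text!r}") from exc
    if cents != cents.to_integral_value():
        raise ValueError(f"amount {text!r} has sub-cent precision")
    return int(cents)


def _parse_date(text: str) -> datetime.date:
    try:
        return datetime.date.fromisoformat(text.strip())
    except ValueError as exc:
        raise ValueError(f"unparseable date {text!r}") from exc


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: Path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def read_claims(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> list[ClaimRecord]:
    """Read claim records from a delimited text file.

    Parameters
    ----------
    path
        File with one header row.  Dates are ISO-8601; amounts are dollars
        with an optional sign and up to two decimals.
    dialect
        Maps the canonical field names (``beneficiary_id``,
        ``claim_through_date``, ``paid_amount``) to the file's actual column
        headers.  Defaults to the canonical names themselves.
    """
    path = Path(path)
    cols = {**CLAIM_COLUMNS, **(dialect or {})}
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    _require_columns(df, cols.values(), path)

    records: list[ClaimRecord] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # header is line 1
        raw = dict(zip(df.columns, row))
        try:
            records.append(
                ClaimRecord(
                    beneficiary_id=raw[cols["beneficiary_id"]].strip(),
                    claim_through_date=_parse_date(raw[cols["claim_through_date"]]),
                    paid_cents=parse_amount_cents(raw[cols["paid_amount"]]),
                )
            )
        except ValueError as exc:
            raise RowParseError(str(exc), line) from exc
    return records


def read_eligibility(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> list[EligibilityRecord]:
    """Read the eligibility/denominator table.

    Boolean columns accept 0/1 or true/false (any case); ``death_month`` may
    be blank for survivors.
    """
    path = Path(path)
    cols = {**ELIGIBILITY_COLUMNS, **(dialect or {})}
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    _require_columns(df, cols.values(), path)

    def parse_bool(text: str, line: int) -> bool:
        t = text.strip().lower()
        if t in ("1", "true", "t", "yes"):
            return True
        if t in ("0", "false", "f", "no"):
            return False
        raise RowParseError(f"unparseable boolean {text!r}", line)

    records: list[EligibilityRecord] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2
        raw = dict(zip(df.columns, row))
        death_text = raw[cols["death_month"]].strip()
        try:
            records.append(
                EligibilityRecord(
                    beneficiary_id=raw[cols["beneficiary_id"]].strip(),
                    age_eligible=parse_bool(raw[cols["age_eligible"]], line),
                    continuously_enrolled=parse_bool(
                        raw[cols["continuously_enrolled"]], line
                    ),
                    death_month=int(death_text) if death_text else None,
                )
            )
        except ValueError as exc:
            if isinstance(exc, RowParseError):
                raise
            raise RowParseError(str(exc), line) from exc
    return records


@dataclass(frozen=True)
class MonthlySpendMatrix:
    """Beneficiary-by-month expenditure totals in integer cents, zero-filled.

    Every beneficiary has a defined value for every month; months with no
    utilization are explicit zeros.  This zero-filling is what makes the
    within-person monthly ranking well defined for the whole cohort.
    """

    beneficiary_ids: tuple[str, ...]
    values: np.ndarray  # shape (n, M), int64 cents
    year: Optional[int] = None
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D (beneficiary x month) array")
        if not np.issubdtype(values.dtype, np.integer):
            raise ValueError("values must be integer cents")
        if len(self.beneficiary_ids) != values.shape[0]:
            raise ValueError("beneficiary_ids length does not match values rows")
        if len(set(self.beneficiary_ids)) != len(self.beneficiary_ids):
            raise ValueError("beneficiary_ids must be unique")
        object.__setattr__(self, "values", values.astype(np.int64, copy=False))
        object.__setattr__(
            self, "_index", {b: i for i, b in enumerate(self.beneficiary_ids)}
        )

    @property
    def n_beneficiaries(self) -> int:
        return len(self.beneficiary_ids)

    @property
    def months(self) -> int:
        return self.values.shape[1]

    @property
    def total_cents(self) -> int:
        return int(self.values.sum())

    def row(self, beneficiary_id: str) -> np.ndarray:
        return self.values[self._index[beneficiary_id]]

    def row_indices(self, beneficiary_ids: Iterable[str]) -> np.ndarray:
        """Positions of the given ids, raising KeyError on unknown ids."""
        return np.array([self._index[b] for b in beneficiary_ids], dtype=np.intp)

    def subset(self, beneficiary_ids: Sequence[str]) -> "MonthlySpendMatrix":
        idx = self.row_indices(beneficiary_ids)
        return MonthlySpendMatrix(
            tuple(beneficiary_ids), self.values[idx].copy(), self.year
        )

    def to_frame(self) -> pd.DataFrame:
        cols = [f"m{m}" for m in range(1, self.months + 1)]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "beneficiary_id", list(self.beneficiary_ids))
        return df

    def write(self, path: str | Path) -> None:
        """Write the matrix as delimited text plus a JSON metadata sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        meta = {
            "year": self.year,
            "months": self.months,
            "n_beneficiaries": self.n_beneficiaries,
            "total_cents": self.total_cents,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, sort_keys=True, indent=2) + "\n"
        )

    @classmethod
    def read(cls, path: str | Path) -> "MonthlySpendMatrix":
        path = Path(path)
        df = pd.read_csv(path, dtype={"beneficiary_id": str})
        month_cols = [c for c in df.columns if c != "beneficiary_id"]
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        year = None
        if meta_path.exists():
            year = json.loads(meta_path.read_text()).get("year")
        return cls(
            tuple(df["beneficiary_id"]),
            df[month_cols].to_numpy(dtype=np.int64),
            year,
        )


def write_claims(claims: Sequence[ClaimRecord], path: str | Path) -> None:
    """Write claims as delimited text readable by :func:`read_claims`."""
    df = pd.DataFrame(
        {
            "beneficiary_id": [c.beneficiary_id for c in claims],
            "claim_through_date": [c.claim_through_date.isoformat() for c in claims],
            "paid_amount": [f"{c.paid_cents / 100:.2f}" for c in claims],
        }
    )
    df.to_csv(path, index=False)


def write_eligibility(records: Sequence[EligibilityRecord], path: str | Path) -> None:
    """Write eligibility records readable by :func:`read_eligibility`."""
    df = pd.DataFrame(
        {
            "beneficiary_id": [e.beneficiary_id for e in records],
            "age_eligible": [int(e.age_eligible) for e in records],
            "continuously_enrolled": [int(e.continuously_enrolled) for e in records],
            "death_month": ["" if e.death_month is None else e.death_month for e in records],
        }
    )
    df.to_csv(path, index=False)


def filter_initial_population(
    claims: Sequence[ClaimRecord],
    eligibility: Sequence[EligibilityRecord],
) -> set[str]:
    """Select the study denominator.

    A beneficiary enters the initial population when they are age-eligible,
    continuously enrolled (decedents count as enrolled up to death), and have
    at least one claim in the study year.  Beneficiaries with no claims are
    excluded; claims whose id is absent from the eligibility table are
    dropped with a warning.
    """
    eligible = {
        e.beneficiary_id
        for e in eligibility
        if e.age_eligible and e.continuously_enrolled
    }
    with_claims: set[str] = set()
    unknown: set[str] = set()
    for claim in claims:
        if claim.beneficiary_id in eligible:
            with_claims.add(claim.beneficiary_id)
        elif claim.beneficiary_id not in {e.beneficiary_id for e in eligibility}:
            unknown.add(claim.beneficiary_id)
    if unknown:
        logger.warning(
            "%d claim beneficiary id(s) absent from eligibility table; excluded",
            len(unknown),
        )
    return with_claims


def build_monthly_matrix(
    claims: Sequence[ClaimRecord],
    population: Iterable[str],
    months: int = 12,
    year: Optional[int] = None,
) -> MonthlySpendMatrix:
    """Aggregate claims into the beneficiary-by-month matrix.

    ``value(b, m)`` is the sum of paid cents over b's claims whose
    claim-through date falls in calendar month m.  Months without claims are
    zero.  Claims for ids outside ``population`` are ignored.  A claim dated
    outside the study year (or beyond month M) raises, since it signals a
    wrong-year extract.
    """
    ids = tuple(sorted(set(population)))
    if year is None and claims:
        year = claims[0].claim_through_date.year
    matrix = np.zeros((len(ids), months), dtype=np.int64)
    index = {b: i for i, b in enumerate(ids)}
    for claim in claims:
        d = claim.claim_through_date
        if year is not None and d.year != year:
            raise ValueError(
                f"claim for {claim.beneficiary_id} dated {d} is outside study year {year}"
            )
        if d.month > months:
            raise ValueError(
                f"claim for {claim.beneficiary_id} dated {d} is beyond study month {months}"
            )
        i = index.get(claim.beneficiary_id)
        if i is not None:
            matrix[i, d.month - 1] += claim.paid_cents
    return MonthlySpendMatrix(ids, matrix, year)
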