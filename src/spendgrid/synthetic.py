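"""Seeded synthetic claims panels with the structure the method assumes.

Real Medicare research extracts are access-restricted, so this module
generates beneficiary spending panels that reproduce the features the
segmentation method relies on: heavy-tailed yearly totals (a log-normal
chronic level per beneficiary), zero-utilization months, episodic acute
spikes that create month-to-month migration, and decedents whose post-death
months are truncated to zero but who stay in the denominator.

The default calibration targets a top-decile yearly spending share in the
neighbourhood of the high-50s percent observed in fee-for-service Medicare;
``scripts/calibrate_generator.py`` reproduces the calibration sweep.
"""

from __future__ import annotations

import calendar
import datetime
from dataclasses import dataclass, replace
import numpy as np

from .claims import ClaimRecord, EligibilityRecord, MonthlySpendMatrix


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic spending panel.

    Monetary scale parameters are on the natural-log scale of *dollars per
    month*.  A month is zeroed (no utilization at all, spikes included) with
    ``zero_month_prob``; otherwise it spends the chronic level times a
    log-normal month noise, plus — with ``spike_prob`` — an acute episode.
    """

    n_beneficiaries: int = 1000
    months: int = 12
    chronic_log_mean: float = 6.2  # exp ~ $490/month chronic level
    chronic_log_sd: float = 1.8
    month_noise_log_sd: float = 0.6
    zero_month_prob: float = 0.35
    spike_prob: float = 0.07
    spike_log_mean: float = 9.2  # exp ~ $9,900 per acute episode
    spike_log_sd: float = 1.2
    death_prob: float = 0.04
    claims_per_positive_month: float = 3.0
    year: int = 2012
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_beneficiaries < 1:
            raise ValueError("n_beneficiaries must be >= 1")
        if self.months < 1:
            raise ValueError("months must be >= 1")
        for name in ("zero_month_prob", "spike_prob", "death_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("chronic_log_sd", "month_noise_log_sd", "spike_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.claims_per_positive_month < 1:
            raise ValueError("claims_per_positive_month must be >= 1")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


def _beneficiary_ids(n: int) -> tuple[str, ...]:
    width = max(6, len(str(n - 1)))
    return tuple(f"B{i:0{width}d}" for i in range(n))


def generate_monthly_matrix(
    config: GeneratorConfig,
) -> tuple[MonthlySpendMatrix, list[EligibilityRecord]]:
    """Draw a beneficiary-by-month spending matrix and eligibility records.

    Fully reproducible from ``config.seed``.  Decedents are recorded with a
    ``death_month`` and have zero spending strictly after it; they remain in
    the matrix (and hence the denominator) all year.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_beneficiaries, config.months

    chronic = rng.lognormal(config.chronic_log_mean, config.chronic_log_sd, n)
    if config.month_noise_log_sd > 0:
        noise = rng.lognormal(0.0, config.month_noise_log_sd, (n, m))
    else:
        noise = np.ones((n, m))
    spend = chronic[:, None] * noise

    spike_hit = rng.random((n, m)) < config.spike_prob
    spikes = rng.lognormal(config.spike_log_mean, config.spike_log_sd, (n, m))
    spend = spend + np.where(spike_hit, spikes, 0.0)

    # a zero month has no utilization at all, episodes included
    zero_month = rng.random((n, m)) < config.zero_month_prob
    spend = np.where(zero_month, 0.0, spend)

    dies = rng.random(n) < config.death_prob
    death_month = rng.integers(1, m + 1, n)
    after_death = dies[:, None] & (np.arange(1, m + 1)[None, :] > death_month[:, None])
    spend = np.where(after_death, 0.0, spend)

    cents = np.round(spend * 100).astype(np.int64)
    ids = _beneficiary_ids(n)
    matrix = MonthlySpendMatrix(ids, cents, config.year)
    eligibility = [
        EligibilityRecord(
            beneficiary_id=b,
            age_eligible=True,
            continuously_enrolled=True,
            death_month=int(death_month[i]) if dies[i] else None,
        )
        for i, b in enumerate(ids)
    ]
    return matrix, eligibility


def generate_claims(
    config: GeneratorConfig,
) -> tuple[list[ClaimRecord], list[EligibilityRecord]]:
    """Emit claim-level records whose monthly sums match the drawn matrix.

    Each positive (beneficiary, month) cell is split cent-exactly into one
    or more claims with through-dates inside that calendar month; the number
    of claims per positive month is 1 + Poisson(mean - 1).  Rebuilding the
    matrix from these claims reproduces :func:`generate_monthly_matrix`
    bit-exactly under the same config.
    """
    if config.months > 12:
        raise ValueError("claim-level generation requires months <= 12")
    matrix, eligibility = generate_monthly_matrix(config)
    split_rng = np.random.default_rng([config.seed, 0x5EED])

    claims: list[ClaimRecord] = []
    extra = max(config.claims_per_positive_month - 1.0, 0.0)
    rows, cols = np.nonzero(matrix.values > 0)
    n_claims = 1 + split_rng.poisson(extra, len(rows))
    for b_idx, m_idx, k in zip(rows, cols, n_claims):
        total = int(matrix.values[b_idx, m_idx])
        month = int(m_idx) + 1
        if k > 1:
            parts = split_rng.multinomial(total, np.full(k, 1.0 / k))
            parts = parts[parts > 0]
        else:
            parts = np.array([total])
        n_days = calendar.monthrange(config.year, month)[1]
        days = np.sort(split_rng.integers(1, n_days + 1, len(parts)))
        bid = matrix.beneficiary_ids[b_idx]
        for amount, day in zip(parts, days):
            claims.append(
                ClaimRecord(
                    beneficiary_id=bid,
                    claim_through_date=datetime.date(config.year, month, int(day)),
                    paid_cents=int(amount),
                )
            )
    return claims, eligibility
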