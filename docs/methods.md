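# Methods

## The segmentation procedure

The pipeline operates on three structures:

1. **Monthly spend matrix.** Claim records (beneficiary id, claim-through
   date, paid amount) are aggregated by the calendar month of the
   claim-through date into a beneficiary × month matrix of integer cents.
   Whole claims are attributed to their through-month; claims spanning
   months are not prorated. Months without claims are explicit zeros, so
   every beneficiary has a defined value for all M months — this
   zero-filling is what makes the within-person ranking total. The study
   denominator is beneficiaries who are age-eligible, continuously
   enrolled (decedents count as enrolled up to death), and have at least
   one claim in the study year. Decedents keep their post-death months as
   zeros and stay in the matrix all year, so subgroup headcounts are
   constant by construction.

2. **Spending-order assignment.** Each beneficiary's M monthly values are
   ranked descending into indices 1..M. Ties (most commonly runs of
   zero-spend months) are broken deterministically: under the default
   `chronological` rule the earlier tied month receives the smaller
   (higher-spend) index; `reverse-chronological` is available and the rule
   in force is recorded in the output metadata. Uniqueness matters: it
   makes every month→index map a permutation, which in turn makes the
   count-grid columns exact partitions of the cohort and the anchor
   subgroups an exact partition of the cohort membership.

3. **Grids and occupancy.** Spend and count grids are aggregated over
   (month, index) for the high-cost cohort — the top `ceil(fraction · N)`
   beneficiaries by yearly total, default fraction 0.10. Ceiling is the
   only rounding rule consistent with a top-decile cohort of 122,241 out
   of 1,222,402; ties at the yearly cutoff are broken by ascending
   beneficiary id (configurable). For each anchor month the index-1
   membership is isolated and its private spend/count grids computed; the
   M occupancy grids sum cell-wise to the full grids, exactly, in cents.

All aggregation is integer arithmetic on cents (`np.add.at` /
`np.bincount` on int64), so the conservation identities — grid column
sums vs. baseline monthly totals, occupancy sums vs. full grids, matrix
total vs. claim total — hold bit-exactly, not to a tolerance. Currency
becomes dollars only at reporting, rounded half-away-from-zero to the
nearest million; shares are reported at integer precision (yearly
concentration) or one decimal (segment and subgroup shares).

The method is retrospective by construction: an index is undefined until
the full year has elapsed, so the grids describe realized concentration
and migration, not a prospective risk score.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `top_fraction` | 0.10 | cohort cut, proportion of the ranked population |
| `months` (M) | 12 | study period length; grids are M×M |
| `tie_rule` | chronological | which tied month gets the smaller index |
| selection tie rule | ascending id | ordering of equal yearly totals at the cutoff |
| `sd_convention` | population | divisor (M vs M−1) for monthly-series SDs |

The SD convention is configurable because published figures of this kind
rarely state theirs; with M = 12 the two differ by a factor of
√(12/11) ≈ 1.04, which matters only at the reporting margin.

## The synthetic generator

`GeneratorConfig` draws, per beneficiary, a chronic monthly spending level
from a log-normal (`chronic_log_mean` 6.2, `chronic_log_sd` 1.8 — median
≈ $490/month with a heavy right tail), multiplies it by month-to-month
log-normal noise (`month_noise_log_sd` 0.6), zeroes a month entirely with
`zero_month_prob` 0.35 (a zero month has no utilization at all, episodes
included), and adds an acute episode with `spike_prob` 0.07 per month
drawn log-normal (`spike_log_mean` 9.2 ≈ $9,900 median, `spike_log_sd`
1.2). With `death_prob` 0.04 a beneficiary dies in a uniformly random
month and spends zero strictly afterwards. Claim-level output splits each
positive month cent-exactly into 1 + Poisson(`claims_per_positive_month`
− 1) claims with through-dates inside the month.

Defaults were fixed once by the sweep in
`scripts/calibrate_generator.py`, choosing the parameterisation whose
top-decile yearly share at n = 20,000 (five seeds) lands nearest the
≈58% concentration characteristic of fee-for-service Medicare while
keeping the top segment's share of monthly cohort spending far above the
uniform 1/12 (it averages ≈40%, with the published analysis reporting
"almost half"). The zero-month and death rates are plausibility choices
for an elderly insured population rather than fitted quantities.

What the generator does *not* emulate: serial correlation of episodes
(an inpatient stay followed by post-acute care), seasonality, negative
monthly totals from adjustment claims, end-of-life cost ramps, or any
clinical structure. Passing tests therefore demonstrate the method's
algebraic correctness and its qualitative behaviour on heavy-tailed
episodic panels — not that real claims data would reproduce any
particular printed magnitude.

## Numerical and design choices

- **Integer cents everywhere.** Parsing uses `Decimal`, rejecting
  sub-cent amounts; negative amounts (adjustments) are legal and net
  against monthly totals. Aggregates are int64; overflow would require
  > $9 × 10¹⁶ in one cell.
- **Cohort sizing epsilon.** `cohort_size` computes
  `ceil(fraction · N − 1e−9)`: the epsilon absorbs float artifacts like
  `0.3 · 10 = 2.9999999999999996` without changing any exact case, and
  the result is clamped to [1, N].
- **Degenerate inputs.** All-zero spending vectors are legal (indices
  follow the tie rule alone); empty cohorts yield all-zero grids; empty
  anchor subgroups are legal outputs of tiny cohorts. An empty study
  population, or a zero population yearly total, is an error rather than
  a NaN.
- **Determinism.** Grid aggregation is defined set-wise and is invariant
  to claim row order and beneficiary iteration order; pipeline outputs
  are byte-identical across reruns (JSON is written with sorted keys, no
  timestamps), and the manifest carries SHA-256 checksums of every
  artifact.
- **Problem sizes.** The test suite exercises the invariants at n = 1,000
  beneficiaries and the generator's statistical shape at n = 20,000 over
  five seeds; the brute-force oracle comparison enumerates cohorts of ≤ 5
  beneficiaries over ≤ 4 months for 100 random tables. These sizes give
  sampling error comfortably inside the asserted bands while keeping the
  suite fast.

## Known limitations

- Month attribution by claim-through date assigns a claim spanning a
  month boundary wholly to its final month.
- The eligibility schema is criterion-level booleans, not monthly
  enrollment flag strings; enrollment logic must be resolved upstream.
- Fixed-width Medicare research file layouts are not parsed; inputs are
  generic delimited text with a configurable column map.
- With `months` > 12 the matrix pipeline generalises but claim-level
  generation (which needs real calendar months) does not.
- The reported SD of segment counts/spends depends mildly on the SD
  convention; comparisons against published SDs are order-of-magnitude
  checks only.
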