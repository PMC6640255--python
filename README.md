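# spendgrid

Month-by-rank segmentation of high-cost health-insurance expenditures.

Yearly spending in insured populations is famously concentrated: the top
decile of beneficiaries, ranked by yearly totals, accounts for well over
half of all expenditure. `spendgrid` implements a segmentation that looks
*inside* that high-cost cohort's year. For each cohort member the twelve
monthly totals are ranked highest-to-lowest into a unique **spending-order
index** (1 = that person's most expensive month; ties — including
zero-spend months — are broken deterministically, so the month→index map is
always a permutation). Aggregating cohort spend and headcounts over
(calendar month, index) produces two 12×12 **segment grids** (144 cells
each), and isolating each month's index-1 membership — its **anchor
subgroup** — tracks how small groups of beneficiaries migrate into and out
of the top spending segment from month to month.

The headline phenomenon the method exposes: each month, roughly 1/12
(≈ 8.3%) of the high-cost cohort occupies the highest segment and carries
close to half of that month's cohort spending, yet the membership of that
segment turns over almost completely every month — a dynamic equilibrium
invisible to plain yearly concentration analysis. The package is intended
for health-services researchers and actuaries working with claim-level
extracts (beneficiary id, claim-through date, paid amount) plus a
denominator/eligibility table.

Because real Medicare research files are access-restricted, the package
ships a seeded synthetic claims generator producing panels with the
relevant statistical structure: log-normal heavy-tailed chronic spending,
zero-utilization months, episodic acute cost spikes, and decedents
truncated to zero but kept in the denominator.

## Method

For beneficiary *b* with monthly totals *x<sub>b,1..M</sub>* (integer
cents, zero-filled), the order assignment is the permutation
σ<sub>b</sub> of 1..M with
*x*<sub>b,σ⁻¹(1)</sub> ≥ *x*<sub>b,σ⁻¹(2)</sub> ≥ … ≥
*x*<sub>b,σ⁻¹(M)</sub>, ties broken chronologically by default. The grids
are

- spend: S(m,k) = Σ<sub>b: σ<sub>b</sub>(m)=k</sub> *x*<sub>b,m</sub>
- count: C(m,k) = |{b : σ<sub>b</sub>(m) = k}|

with exact identities Σ<sub>k</sub> S(m,k) = baseline monthly total and
Σ<sub>k</sub> C(m,k) = cohort size for every m. The anchor subgroup of
month a is {b : σ<sub>b</sub>(a) = 1}; the M subgroups partition the
cohort, and their per-subgroup occupancy grids sum cell-wise to the full
grids.

## Worked example

Simulate a 20,000-beneficiary panel, run the full pipeline, and print the
summary:

```bash
spendgrid segment --simulate --n 20000 --seed 1 --out-dir demo
spendgrid report demo
```

```
Population: 19,960 beneficiaries
High-cost cohort: 1,996 beneficiaries (top 10%)
Cohort yearly spending: $395M of $671M total (59% concentration)
Baseline monthly spending: mean $33M, SD $1M
Top segment share of monthly spending: 42.0%
Top two segments share of monthly spending: 58.0%
All segment shares (%): 42.0, 15.9, 11.3, 9.0, 7.2, 5.6, 4.2, 2.6, 1.4, 0.6, 0.2, 0.0 (sum 100.0)
Anchor subgroups (index-1 membership per month):
  month  1: n=185 (9.3% of cohort), 45.2% of that month's spending
  month  2: n=183 (9.2% of cohort), 43.1% of that month's spending
  ...
```

Reading: 40 of the 20,000 simulated beneficiaries had no claims and drop
out of the denominator. The top decile of the remainder (1,996 people)
accounts for 59% of yearly spending. Within that cohort, the highest
spending-order segment — a different ≈8–9% of the cohort each month —
carries ≈42% of monthly cohort spending, and the top two segments together
carry ≈58%. The artifact directory contains the monthly matrix, both
144-cell grids, per-index summaries, the per-anchor occupancy
decomposition in long format, and a checksummed `manifest.json`; every
table round-trips through the package's own readers.

The same pipeline runs on real extracts via `--input-claims` /
`--input-eligibility` (delimited text; column names configurable through
the reader API's `dialect` mapping).

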