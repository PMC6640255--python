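"""End-to-end orchestration: claims -> population -> cohort -> grids ->
migration, with every artifact written to delimited text or JSON plus a
checksummed manifest.  The command-line entry points in :mod:`spendgrid.cli`
are thin wrappers over :func:`run_segment` and :func:`run_report`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from . import claims as claims_mod
from .claims import (
    build_monthly_matrix,
    filter_initial_population,
    read_claims,
    read_eligibility,
)
from .concentration import (
    baseline_monthly,
    concentration_share,
    select_top_fraction,
    yearly_totals,
)
from .migration import all_subgroup_occupancy, migration_summary, occupancy_to_long
from .rounding import cents_to_millions, round_half_away
from .segmentation import (
    OrderAssignment,
    SegmentGrid,
    grids_to_long,
    segment_counts,
    segment_spend,
    segment_summary,
    write_grid_metadata,
)
from .synthetic import GeneratorConfig, generate_claims

logger = logging.getLogger(__name__)

MANIFEST_NAME = "manifest.json"


@dataclass(frozen=True)
class RunConfig:
    """One analysis run, from claim files or a simulated panel."""

    out_dir: Path
    input_claims: Optional[Path] = None
    input_eligibility: Optional[Path] = None
    simulate: Optional[GeneratorConfig] = None
    year: Optional[int] = None
    months: int = 12
    top_fraction: float = 0.10
    tie_rule: str = "chronological"
    sd_convention: str = "population"

    def __post_init__(self) -> None:
        if not (0.0 < self.top_fraction <= 1.0):
            raise ValueError("top_fraction must be in (0, 1]")
        if self.months < 1:
            raise ValueError("months must be >= 1")
        if self.simulate is None and (
            self.input_claims is None or self.input_eligibility is None
        ):
            raise ValueError(
                "provide either a generator config or both claim and eligibility files"
            )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n")


def run_segment(config: RunConfig) -> dict:
    """Run the full segmentation pipeline and write all artifacts.

    Returns the manifest: file names mapped to SHA-256 checksums, alongside
    the run configuration.  Outputs are deterministic for fixed inputs and
    config, so repeated runs are byte-identical.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        gen = dataclasses.replace(config.simulate, months=config.months)
        claims, eligibility = generate_claims(gen)
        claims_mod.write_claims(claims, out / "claims.csv")
        claims_mod.write_eligibility(eligibility, out / "eligibility.csv")
        year = gen.year
        logger.info("simulated %d claims for %d beneficiaries", len(claims), gen.n_beneficiaries)
    else:
        claims = read_claims(config.input_claims)
        eligibility = read_eligibility(config.input_eligibility)
        year = config.year
        logger.info("read %d claims, %d eligibility rows", len(claims), len(eligibility))

    population = filter_initial_population(claims, eligibility)
    matrix = build_monthly_matrix(claims, population, months=config.months, year=year)
    matrix.write(out / "matrix.csv")

    totals = yearly_totals(matrix)
    _write_json(
        out / "population.json",
        {
            "n_claims": len(claims),
            "n_eligibility_rows": len(eligibility),
            "n_population": matrix.n_beneficiaries,
            "year": matrix.year,
            "months": matrix.months,
            "total_cents": matrix.total_cents,
        },
    )

    if not totals:
        raise ValueError("invariant violated: initial population is empty")

    selection = select_top_fraction(totals, config.top_fraction)
    share = concentration_share(selection)
    _write_json(
        out / "cohort.json",
        {
            "n_population": len(totals),
            "n_cohort": selection.cutoff_rank,
            "fraction": selection.fraction,
            "cohort_total_cents": selection.cohort_yearly_total,
            "population_total_cents": selection.population_yearly_total,
            "share_pct": share,
            "cohort_ids": list(selection.cohort_ids),
        },
    )

    baseline = baseline_monthly(matrix, selection.cohort_ids, config.sd_convention)
    _write_json(
        out / "baseline.json",
        {
            "monthly_totals_cents": list(baseline.monthly_totals),
            "mean_monthly_cents": baseline.mean_monthly,
            "sd_monthly_cents": baseline.sd_monthly,
            "sd_convention": baseline.sd_convention,
        },
    )

    orders = OrderAssignment.from_matrix(matrix, selection.cohort_ids, config.tie_rule)
    spend_grid = segment_spend(matrix, orders, selection.cohort_ids)
    count_grid = segment_counts(orders, selection.cohort_ids)

    # pipeline-level invariant checks: conservation and partition
    if tuple(int(v) for v in spend_grid.month_totals()) != baseline.monthly_totals:
        raise AssertionError(
            "invariant violated: spend-grid column sums != baseline monthly totals"
        )
    if not all(int(c) == selection.cutoff_rank for c in count_grid.month_totals()):
        raise AssertionError(
            "invariant violated: count-grid columns do not sum to cohort size"
        )

    spend_grid.write(out / "spend_grid.csv")
    count_grid.write(out / "count_grid.csv")
    write_grid_metadata(
        out / "grids.meta.json", orders.tie_rule, matrix.months, selection.cutoff_rank
    )
    grids_to_long(spend_grid, count_grid).to_csv(out / "segments_long.csv", index=False)

    spend_summary = segment_summary(spend_grid, config.sd_convention)
    count_summary = segment_summary(count_grid, config.sd_convention)
    spend_summary.to_csv(out / "spend_summary.csv", index=False)
    count_summary.to_csv(out / "count_summary.csv", index=False)

    occupancies = all_subgroup_occupancy(matrix.subset(selection.cohort_ids), orders)
    occupancy_to_long(occupancies).to_csv(out / "occupancy_long.csv", index=False)
    _write_json(
        out / "migration.json", migration_summary(spend_grid, count_grid, occupancies)
    )

    files = sorted(
        p.name for p in out.iterdir() if p.is_file() and p.name != MANIFEST_NAME
    )
    manifest = {
        "files": {name: _sha256(out / name) for name in files},
        "config": {
            "months": config.months,
            "top_fraction": config.top_fraction,
            "tie_rule": config.tie_rule,
            "sd_convention": config.sd_convention,
            "year": matrix.year,
            "simulated": config.simulate is not None,
        },
    }
    _write_json(out / MANIFEST_NAME, manifest)
    return manifest


def run_report(artifact_dir: str | Path) -> str:
    """Render the headline quantities of a finished run as readable text.

    Currency is reported in millions of dollars and shares in percent at the
    conventional reporting precisions (integer percent for the yearly
    concentration, one decimal for segment shares).
    """
    out = Path(artifact_dir)
    manifest_path = out / MANIFEST_NAME
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest found in {out}")
    for name in ("cohort.json", "baseline.json", "migration.json"):
        if not (out / name).exists():
            raise FileNotFoundError(f"missing artifact {name} in {out}")

    cohort = json.loads((out / "cohort.json").read_text())
    baseline = json.loads((out / "baseline.json").read_text())
    migration = json.loads((out / "migration.json").read_text())
    spend_grid = SegmentGrid.read(out / "spend_grid.csv", "spend")
    summary = segment_summary(spend_grid)

    lines = []
    lines.append("Population: {:,} beneficiaries".format(cohort["n_population"]))
    lines.append(
        "High-cost cohort: {:,} beneficiaries (top {:.0f}%)".format(
            cohort["n_cohort"], 100 * cohort["fraction"]
        )
    )
    if cohort["n_cohort"] == 0 or cohort["cohort_total_cents"] == 0:
        lines.append("Empty cohort: no spending to segment.")
        return "\n".join(lines) + "\n"

    lines.append(
        "Cohort yearly spending: ${:,.0f}M of ${:,.0f}M total ({:.0f}% concentration)".format(
            cents_to_millions(cohort["cohort_total_cents"]),
            cents_to_millions(cohort["population_total_cents"]),
            round_half_away(cohort["share_pct"], 0),
        )
    )
    lines.append(
        "Baseline monthly spending: mean ${:,.0f}M, SD ${:,.0f}M".format(
            cents_to_millions(baseline["mean_monthly_cents"]),
            cents_to_millions(baseline["sd_monthly_cents"]),
        )
    )

    shares = summary["share_pct"].to_numpy()
    top1 = round_half_away(shares[0], 1)
    top2 = round_half_away(shares[0] + shares[1], 1) if len(shares) > 1 else top1
    lines.append(f"Top segment share of monthly spending: {top1}%")
    lines.append(f"Top two segments share of monthly spending: {top2}%")
    rounded = [round_half_away(s, 1) for s in shares]
    lines.append(
        "All segment shares (%): "
        + ", ".join(f"{s}" for s in rounded)
        + f" (sum {round_half_away(sum(rounded), 1)})"
    )

    lines.append("Anchor subgroups (index-1 membership per month):")
    for rec in migration:
        lines.append(
            "  month {:>2}: n={:,} ({}% of cohort), {}% of that month's spending".format(
                rec["anchor_month"],
                rec["subgroup_size"],
                round_half_away(rec["share_of_cohort_pct"], 1),
                round_half_away(rec["share_of_anchor_month_spend_pct"], 1),
            )
        )
    return "\n".join(lines) + "\n"
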