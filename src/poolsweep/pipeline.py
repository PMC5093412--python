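"""End-to-end orchestration: filter -> window stats -> CDRs -> CSGs -> ranking.

The pipeline consumes an allele-count table (sync or pooled VCF), chromosome
sizes and gene models, and writes per-population window-statistic TSVs,
per-population CDR BEDs, the shared CDR BED, a CSG table, a ranked
domestication-gene table and a machine-readable JSON run summary.  All
outputs are deterministic given fixed inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import io as pio
from .identity import rank_domestication_genes, snp_freq_diffs, top_genes
from .model import (
    DEFAULT_CHROM_BLACKLIST,
    AlleleCountTable,
    ChromSizes,
    GeneModel,
    Region,
)
from .regions import call_cdrs, genes_in_regions, intersect_region_sets, total_region_span
from .windows import compute_all_window_stats, make_windows

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of a sweep scan in one place.

    ``domestic_pools`` / ``wild_pool`` assign roles to the table's pools;
    window geometry, Z thresholds and filter parameters default to the
    standard 100 kb / 50 kb, |Z| > 2 scan with depth 4-1000 and 5 bp
    adjacent-SNP spacing.
    """

    domestic_pools: list[str]
    wild_pool: str
    window_bp: int = 100_000
    step_bp: int = 50_000
    min_snps_per_window: int = 10
    z_hp_max: float = -2.0
    z_fst_min: float = 2.0
    outlier_mode: str = "both"
    min_populations: int | None = None  # None = all domestic pools
    overlap_rule: str = "any"
    fst_mode: str = "mean"
    min_depth: int = 4
    max_depth: int = 1000
    min_spacing_bp: int = 5
    apply_site_filter: bool = True
    chrom_blacklist: tuple[str, ...] = DEFAULT_CHROM_BLACKLIST
    top_k: int = 10
    flank_bp: int = 5000  # flank for the SNP frequency report only
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.domestic_pools:
            raise ValueError("need at least one domestic pool")
        if self.wild_pool in self.domestic_pools:
            raise ValueError("wild pool cannot also be domestic")


@dataclass
class SweepScanResult:
    """In-memory result of :func:`run_sweep_scan`."""

    stats: "pd.DataFrame"  # type: ignore[name-defined]
    per_population: dict[str, dict[str, list[Region]]]
    shared_cdrs: list[Region]
    csgs: list[tuple[GeneModel, list[Region]]]
    summary: dict = field(default_factory=dict)


def run_sweep_scan(
    config: PipelineConfig,
    table: AlleleCountTable,
    chrom_sizes: ChromSizes,
    genes: Sequence[GeneModel] = (),
    out_dir: str | Path | None = None,
) -> SweepScanResult:
    """Run the windowed sweep scan and (optionally) write all outputs."""
    import pandas as pd

    for pool in [*config.domestic_pools, config.wild_pool]:
        table.pool_index(pool)  # fail fast on unknown pools

    if config.apply_site_filter:
        table, fstats = pio.filter_sites(
            table, config.min_depth, config.max_depth, config.min_spacing_bp
        )
        logger.info(
            "site filter: %d in, %d removed by depth, %d by spacing",
            fstats.input_sites, fstats.removed_depth, fstats.removed_spacing,
        )
    else:
        fstats = pio.FilterStats(table.n_sites, 0, 0)

    windows = make_windows(chrom_sizes, config.window_bp, config.step_bp)
    stats = compute_all_window_stats(
        table,
        config.domestic_pools,
        config.wild_pool,
        windows,
        config.min_snps_per_window,
        config.chrom_blacklist,
        config.fst_mode,
    )

    per_pop = call_cdrs(stats, config.z_hp_max, config.z_fst_min, config.outlier_mode)
    cdr_sets = {pop: calls["cdr"] for pop, calls in per_pop.items()}
    shared = intersect_region_sets(cdr_sets, config.min_populations)
    csgs = genes_in_regions(shared, list(genes), config.overlap_rule)

    summary = {
        "n_sites_input": fstats.input_sites,
        "n_sites_removed_depth": fstats.removed_depth,
        "n_sites_removed_spacing": fstats.removed_spacing,
        "n_sites_used": table.n_sites,
        "n_windows": len(windows),
        "genome_bp": chrom_sizes.total_bp,
        "per_population": {
            pop: {
                "n_low_hp_regions": len(calls["low_hp"]),
                "n_high_fst_regions": len(calls["high_fst"]),
                "n_cdrs": len(calls["cdr"]),
                "n_cdr_windows": sum(r.n_windows for r in calls["cdr"]),
                "cdr_span_bp": total_region_span(calls["cdr"]),
            }
            for pop, calls in per_pop.items()
        },
        "n_shared_cdrs": len(shared),
        "shared_cdr_span_bp": total_region_span(shared),
        "n_genes": len(list(genes)),
        "n_csgs": len(csgs),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for pop in config.domestic_pools:
            pio.write_tsv(
                stats[stats["population"] == pop], out / f"windows_{pop}.tsv"
            )
            pio.write_bed(per_pop[pop]["cdr"], out / f"cdr_{pop}.bed", bed6=True)
            pio.write_bed(per_pop[pop]["low_hp"], out / f"low_hp_{pop}.bed", bed6=True)
            pio.write_bed(
                per_pop[pop]["high_fst"], out / f"high_fst_{pop}.bed", bed6=True
            )
        pio.write_bed(shared, out / "shared_cdr.bed", bed6=True)
        csg_rows = [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "regions": ";".join(f"{r.chrom}:{r.start}-{r.end}" for r in regs),
            }
            for g, regs in csgs
        ]
        pio.write_tsv(
            pd.DataFrame(csg_rows, columns=["gene_id", "chrom", "start", "end", "regions"]),
            out / "csg.tsv",
        )
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")

    return SweepScanResult(stats, per_pop, shared, csgs, summary)


def run_gene_ranking(
    config: PipelineConfig,
    table: AlleleCountTable,
    csg_genes: Sequence[GeneModel],
    out_dir: str | Path | None = None,
):
    """Rank candidate selected genes by the two-condition IS t-test.

    Returns (ranking frame, top-k frame, SNP frequency report).  An empty
    gene list is an explicit no-op.
    """
    import pandas as pd

    if not csg_genes:
        logger.warning("run_gene_ranking: empty gene list, nothing to do")
        empty = pd.DataFrame()
        return empty, empty, empty

    if config.apply_site_filter:
        table, _ = pio.filter_sites(
            table, config.min_depth, config.max_depth, config.min_spacing_bp
        )

    ranking = rank_domestication_genes(
        list(csg_genes), table, config.domestic_pools, config.wild_pool
    )
    top = top_genes(ranking, config.top_k)

    # SNPs in and around the top genes (gene body + report flank)
    snp_keys: list[tuple[str, int]] = []
    top_ids = set(top["gene_id"]) if len(top) else set()
    for gene in csg_genes:
        if gene.gene_id in top_ids:
            mask = (
                (table.chrom.astype(str) == gene.chrom)
                & (table.pos >= gene.start - config.flank_bp)
                & (table.pos < gene.end + config.flank_bp)
            )
            snp_keys.extend(
                (c, int(p)) for c, p in zip(table.chrom[mask], table.pos[mask])
            )
    freq_report = snp_freq_diffs(
        snp_keys, table, config.domestic_pools, config.wild_pool
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pio.write_tsv(ranking, out / "gene_ranking.tsv")
        pio.write_tsv(top, out / "top_genes.tsv")
        pio.write_tsv(freq_report, out / "snp_freq_diffs.tsv")
    return ranking, top, freq_report


__all__ = ["PipelineConfig", "SweepScanResult", "run_sweep_scan", "run_gene_ranking"]
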