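"""Readers and writers for the formats a pool-seq sweep scan touches.

Primary interchange is the PoPoolation2 "sync" format: one line per site,
``chrom  pos  ref  A:T:C:G:N:del`` with one colon-separated count column per
pool.  A multi-sample VCF carrying per-pool allelic depths (AD) is accepted
as an alternative.  Regions go out as BED (0-based half-open), tabular
results as TSV with an ``NA`` missing-value convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    NUC_INDEX,
    AlleleCountTable,
    ChromSizes,
    FormatError,
    GeneModel,
    Region,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# sync format
# ---------------------------------------------------------------------------

def read_sync(path: str | Path, pool_names: Sequence[str]) -> AlleleCountTable:
    """Read a PoPoolation2 sync file into an :class:`AlleleCountTable`.

    ``pool_names`` must match the number of count columns.  Positions are
    converted from the file's 1-based convention to internal 0-based.  Sites
    are re-sorted by (chrom, pos) if the file is unsorted; N and deletion
    counts are parsed but not retained.
    """
    pool_names = list(pool_names)
    n_pools = len(pool_names)
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    counts: list[list[list[int]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3 + n_pools:
                raise FormatError(
                    f"{path}:{lineno}: expected {3 + n_pools} columns "
                    f"({n_pools} pools), found {len(fields)}"
                )
            chrom, pos_s, ref = fields[:3]
            try:
                pos = int(pos_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer position {pos_s!r}")
            site_counts = []
            for col in fields[3:]:
                parts = col.split(":")
                if len(parts) != 6:
                    raise FormatError(
                        f"{path}:{lineno}: malformed count field {col!r} "
                        "(expected A:T:C:G:N:del)"
                    )
                try:
                    vals = [int(p) for p in parts]
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-integer count in field {col!r}"
                    )
                site_counts.append(vals[:4])  # drop N and deletion counts
            chroms.append(chrom)
            positions.append(pos - 1)
            refs.append(ref.upper())
            counts.append(site_counts)
    if not positions:
        return AlleleCountTable.empty(pool_names)
    return AlleleCountTable(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        counts=np.array(counts, dtype=np.int64),
        pool_names=pool_names,
    )


def write_sync(table: AlleleCountTable, path: str | Path) -> None:
    """Write a table as sync; N and deletion counts are emitted as zero."""
    with open(path, "w") as fh:
        for i in range(table.n_sites):
            cols = [
                ":".join(str(int(c)) for c in table.counts[i, p]) + ":0:0"
                for p in range(table.n_pools)
            ]
            fh.write(
                f"{table.chrom[i]}\t{int(table.pos[i]) + 1}\t{table.ref[i]}\t"
                + "\t".join(cols)
                + "\n"
            )


# ---------------------------------------------------------------------------
# VCF ingestion
# ---------------------------------------------------------------------------

def read_vcf_pooled(
    path: str | Path, pool_sample_ids: Sequence[str]
) -> tuple[AlleleCountTable, int]:
    """Read biallelic SNPs with per-sample allelic depth (AD) from a VCF.

    Each VCF sample is treated as one pool; REF/ALT depths are mapped onto
    the four-nucleotide count model.  Multi-allelic records, indels and
    records whose alleles are not single nucleotides are skipped; the count
    of skipped records is returned alongside the table.
    """
    from cyvcf2 import VCF

    pool_sample_ids = list(pool_sample_ids)
    vcf = VCF(str(path))
    sample_pos = []
    for s in pool_sample_ids:
        if s not in vcf.samples:
            raise KeyError(f"sample {s!r} not in VCF (has {vcf.samples})")
        sample_pos.append(vcf.samples.index(s))

    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    counts: list[np.ndarray] = []
    skipped = 0
    for rec in vcf:
        if (
            len(rec.ALT) != 1
            or len(rec.REF) != 1
            or len(rec.ALT[0]) != 1
            or rec.REF.upper() not in NUC_INDEX
            or rec.ALT[0].upper() not in NUC_INDEX
        ):
            skipped += 1
            continue
        ad = rec.format("AD")
        if ad is None:
            raise FormatError(
                f"{path}: record {rec.CHROM}:{rec.POS} lacks the AD "
                "(allelic depth) FORMAT field required for pooled input"
            )
        ref_i = NUC_INDEX[rec.REF.upper()]
        alt_i = NUC_INDEX[rec.ALT[0].upper()]
        site = np.zeros((len(pool_sample_ids), 4), dtype=np.int64)
        for out_p, vcf_p in enumerate(sample_pos):
            depths = np.asarray(ad[vcf_p], dtype=np.int64)
            depths = np.where(depths < 0, 0, depths)  # missing AD encoded negative
            site[out_p, ref_i] = depths[0]
            site[out_p, alt_i] = depths[1] if len(depths) > 1 else 0
        chroms.append(rec.CHROM)
        positions.append(rec.POS - 1)
        refs.append(rec.REF.upper())
        counts.append(site)
    if skipped:
        logger.info("read_vcf_pooled: skipped %d non-biallelic/indel records", skipped)
    if not positions:
        return AlleleCountTable.empty(pool_sample_ids), skipped
    table = AlleleCountTable(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        counts=np.stack(counts),
        pool_names=pool_sample_ids,
    )
    return table, skipped


# ---------------------------------------------------------------------------
# site filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterStats:
    """Counts of sites removed by each rule of :func:`filter_sites`."""

    input_sites: int
    removed_depth: int
    removed_spacing: int

    @property
    def output_sites(self) -> int:
        return self.input_sites - self.removed_depth - self.removed_spacing


def filter_sites(
    table: AlleleCountTable,
    min_depth: int = 4,
    max_depth: int = 1000,
    min_spacing_bp: int = 5,
) -> tuple[AlleleCountTable, FilterStats]:
    """Apply count-level site filters: depth range, then adjacent-SNP spacing.

    A site passes the depth rule only if every pool's total read count lies
    within [min_depth, max_depth].  The spacing rule then walks each
    chromosome left to right, keeping the first site and dropping any site
    closer than ``min_spacing_bp`` to the last kept site (greedy keep-first).
    Mapping-quality filters are assumed applied upstream of the count table.
    """
    if min_depth < 0 or max_depth < min_depth or min_spacing_bp < 0:
        raise ValueError("invalid filter parameters")
    depth = table.depth()
    depth_ok = (
        np.ones(table.n_sites, dtype=bool)
        if table.n_sites == 0
        else ((depth >= min_depth) & (depth <= max_depth)).all(axis=1)
    )
    removed_depth = int((~depth_ok).sum())
    kept = table.subset(depth_ok)

    keep = np.ones(kept.n_sites, dtype=bool)
    if min_spacing_bp > 0 and kept.n_sites:
        last_chrom = None
        last_pos = 0
        for i in range(kept.n_sites):
            c, p = kept.chrom[i], int(kept.pos[i])
            if c != last_chrom or p - last_pos >= min_spacing_bp:
                last_chrom, last_pos = c, p
            else:
                keep[i] = False
    removed_spacing = int((~keep).sum())
    out = kept.subset(keep)
    return out, FilterStats(table.n_sites, removed_depth, removed_spacing)


# ---------------------------------------------------------------------------
# shared-SNP ratio
# ---------------------------------------------------------------------------

def shared_snp_ratio(
    table_a: AlleleCountTable,
    table_b: AlleleCountTable,
    mode: str = "jaccard",
    restrict_to_snps: bool = True,
) -> float:
    """Fraction of SNP sites shared between two tables, by (chrom, pos).

    ``mode='jaccard'`` (default) returns |A∩B| / |A∪B|; ``mode='fraction_of_a'``
    returns |A∩B| / |A|.  With ``restrict_to_snps`` each table is first
    reduced to its segregating sites.
    """
    if mode not in ("jaccard", "fraction_of_a"):
        raise ValueError(f"unknown mode {mode!r}")
    sites_a = set(
        table_a.subset(table_a.is_snp()).site_keys()
        if restrict_to_snps
        else table_a.site_keys()
    )
    sites_b = set(
        table_b.subset(table_b.is_snp()).site_keys()
        if restrict_to_snps
        else table_b.site_keys()
    )
    inter = len(sites_a & sites_b)
    if mode == "fraction_of_a":
        if not sites_a:
            raise ValueError("shared_snp_ratio: table A has no SNP sites")
        return inter / len(sites_a)
    union = len(sites_a | sites_b)
    if union == 0:
        raise ValueError("shared_snp_ratio undefined: both site sets empty")
    return inter / union


# ---------------------------------------------------------------------------
# BED / TSV / chrom sizes / gene models
# ---------------------------------------------------------------------------

def write_bed(regions: Iterable[Region], path: str | Path, bed6: bool = False) -> None:
    """Write regions as sorted BED3 (or BED6 with support/score columns)."""
    regions = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    with open(path, "w") as fh:
        for r in regions:
            if bed6:
                name = ",".join(sorted(str(s) for s in r.support)) or "."
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{r.n_windows}\t.\n"
                )
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def read_bed(path: str | Path) -> list[Region]:
    """Read BED3+ into a list of Regions (extra columns ignored)."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                regions.append(Region(fields[0], int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}")
    return regions


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as TSV with header and ``NA`` for missing values."""
    frame.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    """Read a two-column (name, length) chromosome-sizes text file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'name length'")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer length {fields[1]!r}")
    return ChromSizes(sizes)


def write_chrom_sizes(sizes: ChromSizes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def read_genes_bed(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED4+ (name column required, strand optional)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: gene BED needs >=4 columns")
            strand = fields[5] if len(fields) >= 6 else "."
            genes.append(
                GeneModel(fields[3], fields[0], int(fields[1]), int(fields[2]), strand)
            )
    return genes


def write_genes_bed(genes: Iterable[GeneModel], path: str | Path) -> None:
    genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.end))
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_genes_gff3(path: str | Path) -> list[GeneModel]:
    """Extract gene features from GFF3 (1-based closed -> 0-based half-open)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gene_id = (
            feat.attributes.get("ID", [feat.id])[0]
            if feat.attributes.get("ID")
            else feat.id
        )
        genes.append(
            GeneModel(
                gene_id,
                feat.seqid,
                feat.start - 1,
                feat.end,
                feat.strand if feat.strand in ("+", "-") else ".",
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.end))
    return genes


def read_genes(path: str | Path) -> list[GeneModel]:
    """Dispatch on extension: .gff/.gff3 -> GFF3, otherwise BED."""
    suffix = Path(path).suffix.lower()
    if suffix in (".gff", ".gff3"):
        return read_genes_gff3(path)
    return read_genes_bed(path)


__all__ = [
    "read_sync",
    "write_sync",
    "read_vcf_pooled",
    "filter_sites",
    "FilterStats",
    "shared_snp_ratio",
    "write_bed",
    "read_bed",
    "write_tsv",
    "read_tsv",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_genes_bed",
    "write_genes_bed",
    "read_genes_gff3",
    "read_genes",
]
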