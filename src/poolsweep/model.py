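"""Core in-memory data model for pooled-sequencing sweep scans.

The central container is :class:`AlleleCountTable`: per-site, per-pool read
counts of the four nucleotides, as produced by pooled resequencing of a
population (pool-seq).  All downstream statistics (pooled heterozygosity,
F_ST, identity scores) are computed from these counts; no individual
genotypes are ever required.

Coordinates are 0-based half-open internally.  File formats that use 1-based
positions (sync, VCF) are converted on read and reconverted on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

NUCLEOTIDES = "ATCG"
NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

#: Chromosome names excluded from Z-score standardisation by default.  The
#: X chromosome shows suppressed recombination and introgression signals
#: that mimic sweeps, so selection scans conventionally drop it.
DEFAULT_CHROM_BLACKLIST = ("X", "chrX")


class PoolSweepError(Exception):
    """Base class for errors raised by poolsweep."""


class FormatError(PoolSweepError):
    """A file did not conform to its declared format."""


@dataclass(frozen=True)
class GeneModel:
    """A gene as a 0-based half-open interval with an identifier."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")


@dataclass(frozen=True)
class Region:
    """A 0-based half-open genomic interval with provenance.

    ``support`` records which (population, statistic) pairs contributed
    windows to the region; ``n_windows`` how many windows were merged into
    it.  Planted truth intervals and candidate domestication regions are both
    represented this way.
    """

    chrom: str
    start: int
    end: int
    support: frozenset = field(default_factory=frozenset)
    n_windows: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class ChromSizes(dict):
    """Mapping chromosome name -> length in bp."""

    def __init__(self, mapping: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        super().__init__(mapping)
        for name, length in self.items():
            if int(length) <= 0:
                raise ValueError(f"chromosome {name}: non-positive length {length}")

    @property
    def total_bp(self) -> int:
        return int(sum(self.values()))


@dataclass
class AlleleCountTable:
    """Per-site, per-pool nucleotide read counts.

    Attributes
    ----------
    chrom, pos, ref
        Parallel per-site arrays; ``pos`` is 0-based.  Sites are strictly
        sorted by (chrom, pos) with no duplicates.
    counts
        Integer array of shape (n_sites, n_pools, 4), columns in A,T,C,G
        order.  N and deletion counts from sync files are not retained.
    pool_names
        Ordered pool labels, one per pool axis entry.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    counts: np.ndarray
    pool_names: list[str]

    # -- construction -------------------------------------------------

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.size == 0:
            self.counts = self.counts.reshape(0, len(self.pool_names), 4)
        n = len(self.pos)
        if not (len(self.chrom) == len(self.ref) == n):
            raise ValueError("site arrays have inconsistent lengths")
        if self.counts.shape != (n, len(self.pool_names), 4):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{n} sites x {len(self.pool_names)} pools x 4 nucleotides"
            )
        if n and self.counts.min() < 0:
            raise ValueError("negative read count")
        self._sort_and_check()

    def _sort_and_check(self) -> None:
        if self.n_sites == 0:
            return
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        if not np.array_equal(order, np.arange(self.n_sites)):
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
            self.ref = self.ref[order]
            self.counts = self.counts[order]
        same = (self.chrom[1:] == self.chrom[:-1]) & (self.pos[1:] == self.pos[:-1])
        if same.any():
            i = int(np.flatnonzero(same)[0])
            raise ValueError(
                f"duplicate site {self.chrom[i]}:{int(self.pos[i]) + 1}"
            )

    @classmethod
    def empty(cls, pool_names: Sequence[str]) -> "AlleleCountTable":
        return cls(
            chrom=np.empty(0, dtype=object),
            pos=np.empty(0, dtype=np.int64),
            ref=np.empty(0, dtype=object),
            counts=np.zeros((0, len(pool_names), 4), dtype=np.int64),
            pool_names=list(pool_names),
        )

    # -- basic views --------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_pools(self) -> int:
        return len(self.pool_names)

    def pool_index(self, name: str) -> int:
        try:
            return self.pool_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown pool {name!r}; available: {self.pool_names}"
            ) from None

    def depth(self) -> np.ndarray:
        """Total reads per site per pool, shape (n_sites, n_pools)."""
        return self.counts.sum(axis=2)

    def subset(self, mask: np.ndarray) -> "AlleleCountTable":
        mask = np.asarray(mask)
        return AlleleCountTable(
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            counts=self.counts[mask],
            pool_names=list(self.pool_names),
        )

    def site_keys(self) -> list[tuple[str, int]]:
        return list(zip(self.chrom.tolist(), self.pos.tolist()))

    # -- allele structure ---------------------------------------------

    def segregating_in_pool(self) -> np.ndarray:
        """Boolean (n_sites, n_pools): >=2 nucleotides with count > 0."""
        return (self.counts > 0).sum(axis=2) >= 2

    def is_snp(self) -> np.ndarray:
        """Table-level SNP status: segregating in at least one pool."""
        return self.segregating_in_pool().any(axis=1)

    def site_alleles(self) -> np.ndarray:
        """The two alleles of each site, shape (n_sites, 2), as A/T/C/G indices.

        Alleles are the two nucleotides with the highest read count summed
        over all pools; ties break toward the reference nucleotide, then
        alphabet order.  At monomorphic sites the second allele is a
        zero-count placeholder, so its minor count is simply 0.
        """
        total = self.counts.sum(axis=1)  # (n_sites, 4)
        ref_idx = np.array([NUC_INDEX.get(r, -1) for r in self.ref], dtype=np.int64)
        is_ref = np.zeros_like(total)
        rows = np.flatnonzero(ref_idx >= 0)
        is_ref[rows, ref_idx[rows]] = 1
        # rank key: count first, then ref preference, then A>T>C>G order
        score = total * 8 + is_ref * 4 + (3 - np.arange(4))
        order = np.argsort(-score, axis=1, kind="stable")
        return order[:, :2]

    def major_minor_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-pool read counts of each site's major and minor allele.

        Returns two (n_sites, n_pools) arrays.  "Major"/"minor" are decided
        per pool from that pool's own counts of the site's two alleles.
        """
        alleles = self.site_alleles()
        idx = np.arange(self.n_sites)
        c1 = self.counts[idx[:, None], np.arange(self.n_pools)[None, :], alleles[:, 0:1]]
        c2 = self.counts[idx[:, None], np.arange(self.n_pools)[None, :], alleles[:, 1:2]]
        return np.maximum(c1, c2), np.minimum(c1, c2)

    def allele1_frequency(self) -> np.ndarray:
        """Per-pool frequency of the site-level first allele, NaN if no reads.

        Frequencies are computed over the site's two alleles only, so they
        are directly comparable between pools at the same site.
        """
        alleles = self.site_alleles()
        idx = np.arange(self.n_sites)
        c1 = self.counts[idx[:, None], np.arange(self.n_pools)[None, :], alleles[:, 0:1]]
        c2 = self.counts[idx[:, None], np.arange(self.n_pools)[None, :], alleles[:, 1:2]]
        tot = c1 + c2
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, c1 / np.maximum(tot, 1), np.nan)

    def ref_fraction(self) -> np.ndarray:
        """F: fraction of reads matching the reference allele, per pool.

        Shape (n_sites, n_pools); NaN where a pool has zero reads.  This is
        the quantity entering the identity score IS = 1 - |F1 - F2|.
        """
        ref_idx = np.array([NUC_INDEX.get(r, -1) for r in self.ref], dtype=np.int64)
        ref_counts = np.zeros((self.n_sites, self.n_pools), dtype=np.int64)
        rows = np.flatnonzero(ref_idx >= 0)
        ref_counts[rows] = self.counts[rows, :, ref_idx[rows]]
        tot = self.depth()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, ref_counts / np.maximum(tot, 1), np.nan)

    # -- misc ----------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleCountTable):
            return NotImplemented
        return (
            self.pool_names == other.pool_names
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:
        return (
            f"AlleleCountTable({self.n_sites} sites, "
            f"{self.n_pools} pools: {self.pool_names})"
        )


__all__ = [
    "AlleleCountTable",
    "ChromSizes",
    "GeneModel",
    "Region",
    "PoolSweepError",
    "FormatError",
    "NUCLEOTIDES",
    "NUC_INDEX",
    "DEFAULT_CHROM_BLACKLIST",
]
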