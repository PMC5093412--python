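"""Identity-score (IS) haplotype sharing and domestication-gene ranking.

At each SNP the fraction of reads matching the reference allele, F, is taken
per pool; the identity score between two pools is ``IS = 1 - |F1 - F2|``,
and a gene's IS for a pool pair is the unweighted mean over the gene's SNPs
that have at least one read in both pools.  A gene swept during
domestication shows high IS among domestic pools (shared haplotype) but low
IS against the wild pool.

Genes are ranked by a two-sample Student's t-test contrasting the
within-domestic pairwise gene-IS values against the domestic-vs-wild ones;
the genes with the lowest P are the strongest domestication candidates.
With three domestic pools each group holds three pairwise comparisons
(df = 4), so the test acts as a ranking device rather than a calibrated
inference.
"""

from __future__ import annotations

import itertools
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import AlleleCountTable, GeneModel

logger = logging.getLogger(__name__)

#: smallest positive double, assigned to zero-pooled-variance (degenerate)
#: contrasts so that perfect-separation genes rank first
MIN_P = float(np.nextafter(0, 1))


def ref_allele_fraction(counts: np.ndarray, ref_index: int) -> float:
    """F for one pool at one site: reference reads / total reads.

    ``counts`` is the pool's A/T/C/G count vector.  NaN when the pool has no
    reads at the site.
    """
    counts = np.asarray(counts)
    total = counts.sum()
    if total == 0:
        return float("nan")
    return float(counts[ref_index] / total)


def snp_is(f1: float, f2: float) -> float:
    """Identity score of one SNP between two pools: 1 - |F1 - F2|."""
    return 1.0 - abs(f1 - f2)


class _SnpView:
    """Pre-indexed reference-allele fractions of a table's SNP sites.

    Avoids re-deriving SNP status and F for every gene/pool-pair lookup when
    ranking many genes.
    """

    def __init__(self, table: AlleleCountTable):
        snps = table.subset(table.is_snp())
        self.pool_names = list(snps.pool_names)
        self.chrom = snps.chrom.astype(str)
        self.pos = snps.pos
        self.F = snps.ref_fraction()
        self.bounds: dict[str, tuple[int, int]] = {}
        if len(self.pos):
            uniq, starts = np.unique(self.chrom, return_index=True)
            order = np.argsort(starts)
            uniq, starts = uniq[order], starts[order]
            ends = np.append(starts[1:], len(self.pos))
            self.bounds = {c: (int(s), int(e)) for c, s, e in zip(uniq, starts, ends)}

    def pool_index(self, name: str) -> int:
        try:
            return self.pool_names.index(name)
        except ValueError:
            raise KeyError(f"unknown pool {name!r}") from None

    def gene_F(self, gene: GeneModel, flank_bp: int = 0) -> np.ndarray:
        lo, hi = self.bounds.get(gene.chrom, (0, 0))
        pos_c = self.pos[lo:hi]
        i0 = lo + int(np.searchsorted(pos_c, max(gene.start - flank_bp, 0), "left"))
        i1 = lo + int(np.searchsorted(pos_c, gene.end + flank_bp, "left"))
        return self.F[i0:i1]

    def gene_is(
        self, gene: GeneModel, pool_a: str, pool_b: str, flank_bp: int = 0
    ) -> tuple[float, int]:
        f = self.gene_F(gene, flank_bp)
        a = self.pool_index(pool_a)
        b = self.pool_index(pool_b)
        ok = ~(np.isnan(f[:, a]) | np.isnan(f[:, b]))
        n = int(ok.sum())
        if n == 0:
            return float("nan"), 0
        is_vals = 1.0 - np.abs(f[ok, a] - f[ok, b])
        return float(is_vals.mean()), n


def gene_is(
    gene: GeneModel,
    table: AlleleCountTable,
    pool_a: str,
    pool_b: str,
    flank_bp: int = 0,
) -> tuple[float, int]:
    """Mean identity score of a gene for one pool pair.

    SNPs inside the (half-open) gene interval, optionally extended by
    ``flank_bp`` on both sides, enter the mean when both pools have at least
    one read.  Returns (mean IS, number of SNPs used); the mean is NaN when
    no SNP qualifies.
    """
    return _SnpView(table).gene_is(gene, pool_a, pool_b, flank_bp)


def _t_test(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float, bool]:
    """Equal-variance two-sample t-test with the degenerate case resolved.

    Zero pooled variance with unequal means gets p = MIN_P (flagged
    degenerate); with equal means, t = 0 and p = 1.
    """
    var_a = np.var(group_a, ddof=1) if len(group_a) > 1 else 0.0
    var_b = np.var(group_b, ddof=1) if len(group_b) > 1 else 0.0
    if var_a == 0.0 and var_b == 0.0:
        if np.mean(group_a) == np.mean(group_b):
            return 0.0, 1.0, True
        sign = 1.0 if np.mean(group_a) > np.mean(group_b) else -1.0
        return sign * np.inf, MIN_P, True
    t, p = sps.ttest_ind(group_a, group_b, equal_var=True)
    return float(t), float(p), False


def rank_domestication_genes(
    genes: Sequence[GeneModel],
    table: AlleleCountTable,
    domestic_pools: Sequence[str],
    wild_pool: str,
    equal_var: bool = True,
    flank_bp: int = 0,
) -> pd.DataFrame:
    """Rank genes by the two-condition IS t-test.

    For each gene, group A holds the gene-IS values of all within-domestic
    pool pairs and group B those of all domestic-vs-wild pairs; a two-sided
    two-sample t-test (Student by default, Welch with ``equal_var=False``)
    contrasts them.  Genes are sorted by ascending P, ties broken by |t|
    descending then gene id.  Genes with any missing group value or a group
    smaller than two comparisons are excluded (logged and counted in the
    ``excluded`` frame attribute).

    Returns a DataFrame with one row per retained gene: per-comparison mean
    IS and SNP counts, t, p, Benjamini-Hochberg adjusted p (reported for
    transparency, not used in ranking) and a ``degenerate`` flag for
    zero-pooled-variance contrasts.
    """
    domestic_pools = list(domestic_pools)
    if len(domestic_pools) < 2:
        raise ValueError("need >=2 domestic pools for within-domestic comparisons")
    within_pairs = list(itertools.combinations(domestic_pools, 2))
    cross_pairs = [(d, wild_pool) for d in domestic_pools]
    view = _SnpView(table)

    rows = []
    excluded = 0
    for gene in genes:
        rec: dict[str, object] = {"gene_id": gene.gene_id, "chrom": gene.chrom,
                                  "start": gene.start, "end": gene.end}
        group_a, group_b = [], []
        valid = True
        for pair_list, group in ((within_pairs, group_a), (cross_pairs, group_b)):
            for pa, pb in pair_list:
                mean_is, n_used = view.gene_is(gene, pa, pb, flank_bp)
                rec[f"is_{pa}-{pb}"] = mean_is
                rec[f"n_{pa}-{pb}"] = n_used
                if np.isnan(mean_is):
                    valid = False
                else:
                    group.append(mean_is)
        if not valid or len(group_a) < 2 or len(group_b) < 2:
            excluded += 1
            continue
        if equal_var:
            t, p, degenerate = _t_test(np.array(group_a), np.array(group_b))
        else:
            t, p = sps.ttest_ind(group_a, group_b, equal_var=False)
            t, p, degenerate = float(t), float(p), False
            if np.isnan(t):  # zero variance in both groups
                t, p, degenerate = _t_test(np.array(group_a), np.array(group_b))
        rec["mean_is_within"] = float(np.mean(group_a))
        rec["mean_is_cross"] = float(np.mean(group_b))
        rec["t_stat"] = t
        rec["p_value"] = p
        rec["degenerate"] = degenerate
        rows.append(rec)

    if excluded:
        logger.info("rank_domestication_genes: excluded %d genes", excluded)
    frame = pd.DataFrame(rows)
    if len(frame):
        from statsmodels.stats.multitest import multipletests

        frame["p_adj"] = multipletests(frame["p_value"], method="fdr_bh")[1]
        frame["abs_t"] = frame["t_stat"].abs().replace(np.inf, np.finfo(float).max)
        frame = frame.sort_values(
            ["p_value", "abs_t", "gene_id"], ascending=[True, False, True]
        ).drop(columns="abs_t").reset_index(drop=True)
    frame.attrs["excluded"] = excluded
    return frame


def top_genes(ranking: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """The ``k`` genes with the lowest P; warns when fewer are available."""
    if k > len(ranking):
        logger.warning("requested top %d genes but only %d ranked", k, len(ranking))
    return ranking.head(k).copy()


def snp_freq_diffs(
    snps: Sequence[tuple[str, int]] | None,
    table: AlleleCountTable,
    domestic_pools: Sequence[str],
    wild_pool: str,
) -> pd.DataFrame:
    """Per-SNP mutation-frequency differences, domestic average vs wild.

    Mutation (non-reference) frequency per pool is 1 - F; the domestic value
    is the unweighted mean over domestic pools with at least one read, and
    ``delta`` is its absolute difference from the wild pool.  Sites where the
    wild pool has no reads are skipped (counted in ``attrs['skipped']``).
    ``snps=None`` reports every SNP in the table; otherwise only the listed
    (chrom, 0-based pos) sites.  Sorted by delta descending.
    """
    tab = table.subset(table.is_snp())
    if snps is not None:
        wanted = set(snps)
        mask = np.array(
            [(c, int(p)) in wanted for c, p in zip(tab.chrom, tab.pos)], dtype=bool
        )
        tab = tab.subset(mask)
    f = tab.ref_fraction()
    dom_idx = [tab.pool_index(p) for p in domestic_pools]
    w = tab.pool_index(wild_pool)

    rows = []
    skipped = 0
    for i in range(tab.n_sites):
        if np.isnan(f[i, w]):
            skipped += 1
            continue
        dom_f = np.array([f[i, d] for d in dom_idx])
        dom_f = dom_f[~np.isnan(dom_f)]
        if len(dom_f) == 0:
            skipped += 1
            continue
        es_mut = float(np.mean(1.0 - dom_f))
        wb_mut = float(1.0 - f[i, w])
        row = {
            "chrom": tab.chrom[i],
            "pos": int(tab.pos[i]),
            "ref": tab.ref[i],
            "dom_mean_mut_freq": es_mut,
            "wild_mut_freq": wb_mut,
            "delta": abs(es_mut - wb_mut),
        }
        for name, d in zip(domestic_pools, dom_idx):
            row[f"F_{name}"] = float(f[i, d]) if not np.isnan(f[i, d]) else np.nan
        row[f"F_{wild_pool}"] = float(f[i, w])
        rows.append(row)
    frame = pd.DataFrame(rows)
    if len(frame):
        frame = frame.sort_values("delta", ascending=False).reset_index(drop=True)
    frame.attrs["skipped"] = skipped
    return frame


def pairwise_is_matrix(
    gene: GeneModel, table: AlleleCountTable, pools: Sequence[str] | None = None
) -> pd.DataFrame:
    """Symmetric pool-by-pool mean-IS matrix for one gene (heatmap-ready)."""
    pools = list(pools) if pools is not None else list(table.pool_names)
    mat = pd.DataFrame(np.ones((len(pools), len(pools))), index=pools, columns=pools)
    for a, b in itertools.combinations(pools, 2):
        val, _ = gene_is(gene, table, a, b)
        mat.loc[a, b] = mat.loc[b, a] = val
    return mat


__all__ = [
    "ref_allele_fraction",
    "snp_is",
    "gene_is",
    "rank_domestication_genes",
    "top_genes",
    "snp_freq_diffs",
    "pairwise_is_matrix",
    "MIN_P",
]
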