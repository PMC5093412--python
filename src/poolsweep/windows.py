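"""Windowed pooled heterozygosity, F_ST and genome-wide Z-scores.

For each sliding window (100 kb, 50 kb step by default) and each domestic
pool, two statistics are computed from read counts at SNPs:

* pooled heterozygosity
  ``H_P = 2 * sum(n_MAJ) * sum(n_MIN) / (sum(n_MAJ) + sum(n_MIN))**2``
  where n_MAJ / n_MIN are the per-site read counts of the pool's major and
  minor allele (of the site's two segregating alleles).  H_P lies in
  [0, 0.5]; swept regions approach 0.

* the average per-SNP fixation index between the domestic and the wild pool,
  ``F_ST = (pi_total - pi_within) / pi_total`` with pi = 2p(1-p), pi_within
  the mean of the two pools' pi and pi_total computed from the mean
  frequency.  Domestication sweeps elevate F_ST against the wild pool.

Both statistics are then Z-standardised genome-wide per pool (excluding a
chromosome blacklist, by default the X chromosome), so a two-standard-
deviation threshold (Z(H_P) < -2 together with Z(F_ST) > 2) extracts
putatively selected windows.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .model import DEFAULT_CHROM_BLACKLIST, AlleleCountTable, ChromSizes

logger = logging.getLogger(__name__)

WINDOW_COLUMNS = [
    "chrom", "start", "end", "n_snps", "h_p", "f_st", "z_hp", "z_fst", "population",
]


class DegenerateDistributionError(ValueError):
    """Z-transformation of a constant (zero-variance) statistic."""


def make_windows(
    chrom_sizes: ChromSizes, window_bp: int = 100_000, step_bp: int = 50_000
) -> list[tuple[str, int, int]]:
    """Tile each chromosome with sliding windows [k*step, k*step + window).

    Windows are clipped at the chromosome end; a clipped window is kept only
    if it is at least ``step_bp`` long, so chromosomes shorter than the step
    produce no windows.
    """
    if not (window_bp >= step_bp > 0):
        raise ValueError("require window_bp >= step_bp > 0")
    windows: list[tuple[str, int, int]] = []
    for chrom in sorted(chrom_sizes):
        length = int(chrom_sizes[chrom])
        k = 0
        while k * step_bp < length:
            start = k * step_bp
            end = min(start + window_bp, length)
            if end - start >= step_bp:
                windows.append((chrom, start, end))
            k += 1
    return windows


def window_hp(n_maj: np.ndarray, n_min: np.ndarray) -> float:
    """Pooled heterozygosity of one window from per-SNP major/minor counts.

    Returns NaN when the window has no reads at all (both sums zero); sites
    with zero reads contribute nothing to either sum.
    """
    s_maj = float(np.sum(n_maj))
    s_min = float(np.sum(n_min))
    tot = s_maj + s_min
    if tot == 0:
        return float("nan")
    return 2.0 * s_maj * s_min / (tot * tot)


def snp_fst(p1, p2):
    """Per-SNP pooled F_ST from two allele frequencies (vectorised).

    ``(pi_total - pi_within) / pi_total`` with pi = 2p(1-p).  NaN where both
    pools are fixed for the same allele (pi_total = 0) or a frequency is
    missing.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    pi1 = 2.0 * p1 * (1.0 - p1)
    pi2 = 2.0 * p2 * (1.0 - p2)
    pi_within = 0.5 * (pi1 + pi2)
    p_bar = 0.5 * (p1 + p2)
    pi_total = 2.0 * p_bar * (1.0 - p_bar)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(pi_total > 0, (pi_total - pi_within) / np.maximum(pi_total, 1e-300), np.nan)
    if fst.ndim == 0:
        return float(fst)
    return fst


def window_fst(per_snp_fst: np.ndarray, mode: str = "mean") -> float:
    """Aggregate per-SNP F_ST values of one window.

    ``mode='mean'`` (default) averages the defined per-SNP ratios, matching
    per-SNP F_ST output averaged over a window; ``mode='ratio_of_sums'``
    aggregates numerators and denominators first and is less sensitive to
    low-frequency SNPs.  For ratio_of_sums pass (pi_total, pi_within) via
    :func:`window_fst_ratio_of_sums` instead.
    """
    if mode != "mean":
        raise ValueError("use window_fst_ratio_of_sums for ratio-of-sums mode")
    vals = per_snp_fst[~np.isnan(per_snp_fst)]
    if len(vals) == 0:
        return float("nan")
    return float(np.mean(vals))


def window_fst_ratio_of_sums(pi_total: np.ndarray, pi_within: np.ndarray) -> float:
    """Ratio-of-sums window F_ST: sum(pi_T - pi_W) / sum(pi_T)."""
    ok = ~(np.isnan(pi_total) | np.isnan(pi_within))
    denom = float(np.sum(pi_total[ok]))
    if denom == 0:
        return float("nan")
    return float(np.sum(pi_total[ok] - pi_within[ok]) / denom)


def z_transform(values: np.ndarray) -> np.ndarray:
    """Genome-wide Z-scores: (x - mean) / sample sd over non-missing values.

    Missing (NaN) entries stay missing.  Raises
    :class:`DegenerateDistributionError` when fewer than two values are
    defined or the sample standard deviation is zero.
    """
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    if ok.sum() < 2:
        raise DegenerateDistributionError(
            f"need >=2 non-missing values to Z-transform, got {int(ok.sum())}"
        )
    mean = values[ok].mean()
    sd = values[ok].std(ddof=1)
    if sd == 0:
        raise DegenerateDistributionError("constant statistic: sd = 0")
    z = np.full_like(values, np.nan)
    z[ok] = (values[ok] - mean) / sd
    return z


def compute_window_stats(
    table: AlleleCountTable,
    domestic_pool: str,
    wild_pool: str,
    windows: Sequence[tuple[str, int, int]],
    min_snps_per_window: int = 10,
    chrom_blacklist: Sequence[str] = DEFAULT_CHROM_BLACKLIST,
    fst_mode: str = "mean",
) -> pd.DataFrame:
    """Per-window H_P, F_ST and Z-scores for one domestic/wild contrast.

    SNPs (sites segregating in at least one pool) are assigned to every
    window containing their position, so with overlapping windows a SNP
    contributes to up to window/step windows.  Windows with fewer than
    ``min_snps_per_window`` SNPs get missing statistics; Z-scores are
    standardised over defined windows outside ``chrom_blacklist``.
    """
    d = table.pool_index(domestic_pool)
    w = table.pool_index(wild_pool)
    snp_mask = table.is_snp()
    snps = table.subset(snp_mask)

    n_maj, n_min = snps.major_minor_counts()
    maj_d = n_maj[:, d].astype(float)
    min_d = n_min[:, d].astype(float)
    freq = snps.allele1_frequency()
    fst_site = snp_fst(freq[:, d], freq[:, w]) if snps.n_sites else np.empty(0)

    # per-chromosome index ranges over the (sorted) SNP positions
    chrom_arr = snps.chrom.astype(str)
    pos_arr = snps.pos
    chrom_bounds: dict[str, tuple[int, int]] = {}
    if snps.n_sites:
        uniq, starts = np.unique(chrom_arr, return_index=True)
        order = np.argsort(starts)
        uniq, starts = uniq[order], starts[order]
        ends = np.append(starts[1:], snps.n_sites)
        chrom_bounds = {c: (int(s), int(e)) for c, s, e in zip(uniq, starts, ends)}

    rows = []
    for chrom, start, end in windows:
        lo, hi = chrom_bounds.get(chrom, (0, 0))
        pos_c = pos_arr[lo:hi]
        i0 = lo + int(np.searchsorted(pos_c, start, side="left"))
        i1 = lo + int(np.searchsorted(pos_c, end, side="left"))
        n_snps = i1 - i0
        if n_snps < min_snps_per_window:
            hp = np.nan
            fst = np.nan
        else:
            hp = window_hp(maj_d[i0:i1], min_d[i0:i1])
            if fst_mode == "ratio_of_sums":
                p1, p2 = freq[i0:i1, d], freq[i0:i1, w]
                pb = 0.5 * (p1 + p2)
                fst = window_fst_ratio_of_sums(
                    2 * pb * (1 - pb),
                    0.5 * (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)),
                )
            else:
                fst = window_fst(fst_site[i0:i1])
        rows.append((chrom, start, end, n_snps, hp, fst))

    stats = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_snps", "h_p", "f_st"]
    )
    stats["z_hp"] = np.nan
    stats["z_fst"] = np.nan
    stats["population"] = domestic_pool
    add_z_scores(stats, chrom_blacklist)
    return stats[WINDOW_COLUMNS]


def add_z_scores(
    stats: pd.DataFrame, chrom_blacklist: Sequence[str] = DEFAULT_CHROM_BLACKLIST
) -> pd.DataFrame:
    """Fill z_hp / z_fst in place, standardising outside the blacklist.

    Blacklisted chromosomes keep missing Z-scores and do not influence the
    genome-wide mean and standard deviation.
    """
    blacklist = set(chrom_blacklist)
    use = ~stats["chrom"].astype(str).isin(blacklist)
    for col, zcol in (("h_p", "z_hp"), ("f_st", "z_fst")):
        vals = stats.loc[use, col].to_numpy(dtype=float)
        if (~np.isnan(vals)).sum() < 2:
            logger.warning("too few defined windows to Z-transform %s", col)
            continue
        stats.loc[use, zcol] = z_transform(vals)
    return stats


def compute_all_window_stats(
    table: AlleleCountTable,
    domestic_pools: Sequence[str],
    wild_pool: str,
    windows: Sequence[tuple[str, int, int]],
    min_snps_per_window: int = 10,
    chrom_blacklist: Sequence[str] = DEFAULT_CHROM_BLACKLIST,
    fst_mode: str = "mean",
) -> pd.DataFrame:
    """Window statistics for every domestic pool, concatenated.

    Z-scores are standardised within each population separately.
    """
    frames = [
        compute_window_stats(
            table, pop, wild_pool, windows, min_snps_per_window,
            chrom_blacklist, fst_mode,
        )
        for pop in domestic_pools
    ]
    return pd.concat(frames, ignore_index=True)


__all__ = [
    "make_windows",
    "window_hp",
    "snp_fst",
    "window_fst",
    "window_fst_ratio_of_sums",
    "z_transform",
    "add_z_scores",
    "compute_window_stats",
    "compute_all_window_stats",
    "DegenerateDistributionError",
    "WINDOW_COLUMNS",
]
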