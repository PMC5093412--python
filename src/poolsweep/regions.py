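"""Candidate-region calling from Z-score outlier windows.

Windows in the extreme tails of the Z-transformed statistics (low pooled
heterozygosity, high F_ST against the wild pool) are selected per
population with strict two-standard-deviation thresholds, merged into
maximal candidate domestication regions (CDRs), intersected base-wise
across populations (shared CDRs), and finally overlapped with gene models
to yield candidate selected genes (CSGs).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import GeneModel, Region


def select_outlier_windows(
    stats: pd.DataFrame,
    z_hp_max: float = -2.0,
    z_fst_min: float = 2.0,
    mode: str = "both",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Extract outlier windows from Z-scored window statistics.

    Returns (low-H_P windows, high-F_ST windows, combined windows).  The
    inequalities are strict: a window at exactly Z(H_P) = -2 is not an
    outlier.  ``mode='both'`` requires a combined window to pass both
    thresholds; ``mode='either'`` accepts either.
    """
    if mode not in ("both", "either"):
        raise ValueError(f"unknown mode {mode!r}")
    low_hp = stats[stats["z_hp"] < z_hp_max]
    high_fst = stats[stats["z_fst"] > z_fst_min]
    if mode == "both":
        combined = stats[(stats["z_hp"] < z_hp_max) & (stats["z_fst"] > z_fst_min)]
    else:
        combined = stats[(stats["z_hp"] < z_hp_max) | (stats["z_fst"] > z_fst_min)]
    return low_hp, high_fst, combined


def merge_windows(
    windows: Iterable[tuple[str, int, int]] | pd.DataFrame,
    support: frozenset = frozenset(),
) -> list[Region]:
    """Merge overlapping or book-ended windows into maximal Regions.

    Touching windows merge: with a 50 kb step, adjacent passing windows tile
    one sweep signal.  ``n_windows`` records how many windows each merged
    region absorbed.
    """
    if isinstance(windows, pd.DataFrame):
        items = list(zip(windows["chrom"], windows["start"], windows["end"]))
    else:
        items = [(c, int(s), int(e)) for c, s, e in windows]
    items.sort(key=lambda w: (str(w[0]), w[1], w[2]))
    merged: list[Region] = []
    cur = None  # [chrom, start, end, n]
    for chrom, start, end in items:
        if cur is not None and chrom == cur[0] and start <= cur[2]:
            cur[2] = max(cur[2], end)
            cur[3] += 1
        else:
            if cur is not None:
                merged.append(Region(cur[0], cur[1], cur[2], support, cur[3]))
            cur = [chrom, start, end, 1]
    if cur is not None:
        merged.append(Region(cur[0], cur[1], cur[2], support, cur[3]))
    return merged


def intersect_region_sets(
    per_population_regions: Mapping[str, Sequence[Region]],
    min_populations: int | None = None,
) -> list[Region]:
    """Genomic intervals covered by at least ``min_populations`` populations.

    Sharing is base-wise: a base belongs to the shared set when it lies in a
    merged region of enough populations, and maximal runs of such bases form
    the output regions.  Defaults to requiring every population.  Support
    records the populations covering (any part of) each shared region.
    """
    pops = list(per_population_regions)
    if not pops:
        return []
    if min_populations is None:
        min_populations = len(pops)
    if not (1 <= min_populations <= len(pops)):
        raise ValueError("min_populations out of range")

    # sweep line over region endpoints, counting population coverage
    events: dict[str, list[tuple[int, int, str]]] = {}
    for pop, regions in per_population_regions.items():
        for r in merge_windows([(r.chrom, r.start, r.end) for r in regions]):
            events.setdefault(r.chrom, []).append((r.start, +1, pop))
            events.setdefault(r.chrom, []).append((r.end, -1, pop))
    out: list[Region] = []
    for chrom in sorted(events):
        evs = sorted(events[chrom], key=lambda e: (e[0], -e[1]))
        cov = 0
        open_start = None
        i = 0
        while i < len(evs):
            pos = evs[i][0]
            while i < len(evs) and evs[i][0] == pos:
                cov += evs[i][1]
                i += 1
            if cov >= min_populations and open_start is None:
                open_start = pos
            elif cov < min_populations and open_start is not None:
                out.append(Region(chrom, open_start, pos))
                open_start = None
    # book-ended shared intervals can arise when coverage dips exactly at a
    # boundary; re-merge for canonical maximal regions, then attach support
    merged = merge_windows([(r.chrom, r.start, r.end) for r in out])
    final = []
    for r in merged:
        sup = frozenset(
            pop
            for pop, regions in per_population_regions.items()
            if any(r.overlaps(q) for q in regions)
        )
        final.append(Region(r.chrom, r.start, r.end, sup, r.n_windows))
    return final


def genes_in_regions(
    regions: Sequence[Region],
    gene_models: Sequence[GeneModel],
    overlap_rule: str = "any",
) -> list[tuple[GeneModel, list[Region]]]:
    """Genes overlapping candidate regions, deduplicated by gene id.

    Rules: ``any`` — >=1 bp overlap (default); ``contained`` — the gene lies
    entirely inside a region; ``midpoint`` — the gene midpoint falls in a
    region.  Returns (gene, overlapping regions) pairs in gene order.
    """
    if overlap_rule not in ("any", "contained", "midpoint"):
        raise ValueError(f"unknown overlap rule {overlap_rule!r}")
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)

    seen: set[str] = set()
    out: list[tuple[GeneModel, list[Region]]] = []
    for gene in gene_models:
        if gene.gene_id in seen:
            continue
        tree = trees.get(gene.chrom)
        if tree is None:
            continue
        if overlap_rule == "midpoint":
            mid = (gene.start + gene.end) // 2
            hits = tree.at(mid)
        else:
            hits = tree.overlap(gene.start, gene.end)
            if overlap_rule == "contained":
                hits = {
                    iv for iv in hits if iv.begin <= gene.start and gene.end <= iv.end
                }
        if hits:
            seen.add(gene.gene_id)
            out.append(
                (gene, sorted((iv.data for iv in hits), key=lambda r: (r.chrom, r.start)))
            )
    return out


def total_region_span(regions: Sequence[Region]) -> int:
    """Total bp covered by a region set; overlaps are merged first so no
    base is double-counted."""
    merged = merge_windows([(r.chrom, r.start, r.end) for r in regions])
    return sum(r.length for r in merged)


def call_cdrs(
    stats: pd.DataFrame,
    z_hp_max: float = -2.0,
    z_fst_min: float = 2.0,
    mode: str = "both",
) -> dict[str, dict[str, list[Region]]]:
    """Per-population region calls from a multi-population stats frame.

    Returns, for each population, merged regions for three window sets:
    ``low_hp`` (Z(H_P) outliers), ``high_fst`` (Z(F_ST) outliers) and ``cdr``
    (windows passing both thresholds — the candidate domestication regions).
    """
    result: dict[str, dict[str, list[Region]]] = {}
    for pop, pop_stats in stats.groupby("population", sort=True):
        low_hp, high_fst, combined = select_outlier_windows(
            pop_stats, z_hp_max, z_fst_min, mode
        )
        result[str(pop)] = {
            "low_hp": merge_windows(low_hp, frozenset({(str(pop), "h_p")})),
            "high_fst": merge_windows(high_fst, frozenset({(str(pop), "f_st")})),
            "cdr": merge_windows(combined, frozenset({(str(pop), "cdr")})),
        }
    return result


__all__ = [
    "select_outlier_windows",
    "merge_windows",
    "intersect_region_sets",
    "genes_in_regions",
    "total_region_span",
    "call_cdrs",
]
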