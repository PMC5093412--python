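"""Shared fixtures: hand-built toy tables and session-scoped simulations."""

from __future__ import annotations

import numpy as np
import pytest

from poolsweep.model import AlleleCountTable, ChromSizes
from poolsweep.simulate import SweepSimConfig, SweepSpec, simulate_pools
from poolsweep.windows import compute_all_window_stats, make_windows


def build_table(sites, pool_names):
    """Build an AlleleCountTable from (chrom, pos0, ref, {pool: (A,T,C,G)}) rows."""
    chroms, poss, refs, counts = [], [], [], []
    for chrom, pos, ref, per_pool in sites:
        chroms.append(chrom)
        poss.append(pos)
        refs.append(ref)
        counts.append([list(per_pool[p]) for p in pool_names])
    if not sites:
        return AlleleCountTable.empty(pool_names)
    return AlleleCountTable(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        counts=np.array(counts, dtype=np.int64),
        pool_names=list(pool_names),
    )


def random_table(rng, n_sites=50, n_pools=2, chroms=("chr1", "chr2"), max_pos=100_000):
    """A random multi-pool table for round-trip and property tests."""
    keys = set()
    while len(keys) < n_sites:
        keys.add((str(rng.choice(chroms)), int(rng.integers(0, max_pos))))
    keys = sorted(keys)
    pool_names = [f"p{i}" for i in range(n_pools)]
    counts = rng.integers(0, 40, size=(n_sites, n_pools, 4))
    return AlleleCountTable(
        chrom=np.array([c for c, _ in keys], dtype=object),
        pos=np.array([p for _, p in keys], dtype=np.int64),
        ref=np.array([str(rng.choice(list("ATCG"))) for _ in keys], dtype=object),
        counts=counts,
        pool_names=pool_names,
    )


# -- study-scale simulations (20 Mb genome, 1 SNP/kb, 30x, 3 domestic pools) --

GENOME_20MB = {"chr1": 10_000_000, "chr2": 10_000_000}

FIVE_SWEEPS = [
    SweepSpec("chr1", 1_000_000, 1_300_000, 0.95),
    SweepSpec("chr1", 5_000_000, 5_300_000, 0.95),
    SweepSpec("chr2", 2_000_000, 2_300_000, 0.95),
    SweepSpec("chr2", 6_000_000, 6_300_000, 0.95),
    SweepSpec("chr2", 8_500_000, 8_800_000, 0.95),
]


@pytest.fixture(scope="session")
def null_sim():
    """Neutral 20 Mb simulation (no sweeps), fixed seed."""
    cfg = SweepSimConfig(chrom_lengths=ChromSizes(GENOME_20MB), seed=0)
    table, truth = simulate_pools(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def sweep_sim():
    """20 Mb simulation with five 300 kb shared sweeps at strength 0.95."""
    cfg = SweepSimConfig(
        chrom_lengths=ChromSizes(GENOME_20MB),
        sweep_specs=list(FIVE_SWEEPS),
        seed=0,
    )
    table, truth = simulate_pools(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def null_stats(null_sim):
    cfg, table, _ = null_sim
    windows = make_windows(cfg.chrom_lengths)
    return compute_all_window_stats(table, cfg.domestic_names, cfg.wild_name, windows)


@pytest.fixture(scope="session")
def sweep_stats(sweep_sim):
    cfg, table, _ = sweep_sim
    windows = make_windows(cfg.chrom_lengths)
    return compute_all_window_stats(table, cfg.domestic_names, cfg.wild_name, windows)
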