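"""Multi-pool allele-count simulator with planted selective sweeps.

The generator emulates the data a pooled-resequencing study of a domestication
contrast produces: several domestic pools and one wild pool genotyped at SNPs
scattered over a genome at a fixed density.  Every site carries a shared
ancestral reference-allele frequency p0 drawn from a Beta distribution (a
U-shaped site-frequency-spectrum proxy).  The wild pool sits at p0; domestic
pools drift slightly around it — except inside planted sweep intervals, where
their frequency is pulled toward the allele opposite the wild major allele:

    p_dom = (1 - s) * p0 + s * target,   target = 1 if p0 < 0.5 else 0

with sweep strength s in [0, 1].  A sweep is shared (identical underlying
frequency) across all pools it is planted in, modelling a sweep that predates
the split of the domestic populations.  Read counts are then drawn per pool
as Binomial(Poisson(depth_mean), p), giving realistic pool-seq sampling noise.

Everything is deterministic under a fixed seed, so downstream detection can
be scored against the exact planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import AlleleCountTable, ChromSizes, Region

#: transition partner used as the fixed alternative allele per reference base
ALT_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class SweepSpec:
    """One planted sweep: interval, strength, and the pools it affects.

    ``pools=None`` plants the sweep in every domestic pool (a shared sweep);
    an explicit tuple of pool names plants a population-private sweep.
    """

    chrom: str
    start: int
    end: int
    strength: float = 1.0
    pools: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid sweep interval [{self.start}, {self.end})")
        if not (0.0 <= self.strength <= 1.0):
            raise ValueError(f"sweep strength {self.strength} outside [0, 1]")


@dataclass
class SweepSimConfig:
    """Parameters of the pool-seq simulator.

    Defaults model a modest desk-scale study: 3 domestic pools plus one wild
    pool, 1 SNP per kb, 30x expected depth per pool, Beta(0.8, 0.8)
    background frequencies and per-pool drift noise of sd 0.03.
    """

    chrom_lengths: ChromSizes
    snp_density: float = 0.001
    n_domestic_pools: int = 3
    depth_mean: float = 30.0
    sweep_specs: list[SweepSpec] = field(default_factory=list)
    background_freq_alpha: float = 0.8
    background_freq_beta: float = 0.8
    drift_sd: float = 0.03
    seed: int = 0
    domestic_names: list[str] | None = None
    wild_name: str = "wild"

    def __post_init__(self) -> None:
        if self.snp_density <= 0:
            raise ValueError("snp_density must be > 0")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if self.n_domestic_pools < 1:
            raise ValueError("need at least one domestic pool")
        if self.domestic_names is None:
            self.domestic_names = [f"dom{i + 1}" for i in range(self.n_domestic_pools)]
        if len(self.domestic_names) != self.n_domestic_pools:
            raise ValueError("domestic_names length != n_domestic_pools")
        self._validate_sweeps()

    def _validate_sweeps(self) -> None:
        by_chrom: dict[str, list[SweepSpec]] = {}
        for sw in self.sweep_specs:
            if sw.chrom not in self.chrom_lengths:
                raise ValueError(f"sweep on unknown chromosome {sw.chrom!r}")
            if sw.end > self.chrom_lengths[sw.chrom]:
                raise ValueError(
                    f"sweep [{sw.start},{sw.end}) exceeds {sw.chrom} length"
                )
            if sw.pools is not None:
                unknown = set(sw.pools) - set(self.domestic_names)
                if unknown:
                    raise ValueError(f"sweep names unknown pools {sorted(unknown)}")
            by_chrom.setdefault(sw.chrom, []).append(sw)
        for chrom, sweeps in by_chrom.items():
            sweeps = sorted(sweeps, key=lambda s: s.start)
            for a, b in zip(sweeps, sweeps[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping sweeps on {chrom}: "
                        f"[{a.start},{a.end}) and [{b.start},{b.end})"
                    )

    @property
    def pool_names(self) -> list[str]:
        return list(self.domestic_names) + [self.wild_name]


@dataclass
class TruthSet:
    """Ground truth of one simulation: planted regions and true frequencies.

    ``true_freq`` rows align with the sites of the returned table; values are
    the per-pool reference-allele frequencies the reads were sampled from.
    """

    regions: list[Region]
    chrom: np.ndarray
    pos: np.ndarray
    true_freq: np.ndarray  # (n_sites, n_pools), ref-allele frequency
    pool_names: list[str]


def simulate_pools(config: SweepSimConfig) -> tuple[AlleleCountTable, TruthSet]:
    """Simulate a multi-pool allele-count table with planted sweeps."""
    rng = np.random.default_rng(config.seed)
    dom_names = list(config.domestic_names)
    pool_names = config.pool_names
    n_dom = len(dom_names)
    n_pools = n_dom + 1

    all_chrom: list[np.ndarray] = []
    all_pos: list[np.ndarray] = []
    all_ref: list[str] = []
    all_freq: list[np.ndarray] = []

    for chrom in sorted(config.chrom_lengths):
        length = int(config.chrom_lengths[chrom])
        n_draw = int(round(config.snp_density * length))
        if n_draw == 0:
            continue
        pos = np.unique(rng.integers(0, length, size=n_draw))
        n = len(pos)

        ref = rng.choice(list("ATCG"), size=n)
        p0 = rng.beta(config.background_freq_alpha, config.background_freq_beta, size=n)

        # wild pool sits at the ancestral frequency; domestic pools drift
        freq = np.empty((n, n_pools))
        freq[:, -1] = p0
        for d in range(n_dom):
            noise = rng.normal(0.0, config.drift_sd, size=n)
            freq[:, d] = np.clip(p0 + noise, 0.0, 1.0)

        # plant sweeps: shared near-fixation at the anti-wild allele
        target = np.where(p0 < 0.5, 1.0, 0.0)
        for sw in config.sweep_specs:
            if sw.chrom != chrom:
                continue
            in_sweep = (pos >= sw.start) & (pos < sw.end)
            swept = (1.0 - sw.strength) * p0[in_sweep] + sw.strength * target[in_sweep]
            affected = dom_names if sw.pools is None else list(sw.pools)
            for name in affected:
                freq[in_sweep, dom_names.index(name)] = swept

        all_chrom.append(np.full(n, chrom, dtype=object))
        all_pos.append(pos)
        all_ref.extend(ref.tolist())
        all_freq.append(freq)

    if all_pos:
        chrom_arr = np.concatenate(all_chrom)
        pos_arr = np.concatenate(all_pos).astype(np.int64)
        ref_arr = np.array(all_ref, dtype=object)
        freq_arr = np.concatenate(all_freq)
    else:
        chrom_arr = np.empty(0, dtype=object)
        pos_arr = np.empty(0, dtype=np.int64)
        ref_arr = np.empty(0, dtype=object)
        freq_arr = np.zeros((0, n_pools))

    n_sites = len(pos_arr)
    counts = np.zeros((n_sites, n_pools, 4), dtype=np.int64)
    if n_sites:
        ref_idx = np.array([{"A": 0, "T": 1, "C": 2, "G": 3}[r] for r in ref_arr])
        alt_idx = np.array(
            [{"A": 0, "T": 1, "C": 2, "G": 3}[ALT_OF[r]] for r in ref_arr]
        )
        depth = rng.poisson(config.depth_mean, size=(n_sites, n_pools))
        ref_reads = rng.binomial(depth, freq_arr)
        alt_reads = depth - ref_reads
        rows = np.arange(n_sites)
        for p in range(n_pools):
            counts[rows, p, ref_idx] = ref_reads[:, p]
            counts[rows, p, alt_idx] = alt_reads[:, p]

    table = AlleleCountTable(
        chrom=chrom_arr, pos=pos_arr, ref=ref_arr, counts=counts,
        pool_names=pool_names,
    )
    truth = TruthSet(
        regions=truth_regions_from_specs(config.sweep_specs),
        chrom=chrom_arr.copy(),
        pos=pos_arr.copy(),
        true_freq=freq_arr,
        pool_names=pool_names,
    )
    return table, truth


def truth_regions_from_specs(sweep_specs: Sequence[SweepSpec]) -> list[Region]:
    return sorted(
        (
            Region(sw.chrom, sw.start, sw.end, support=frozenset({"truth"}))
            for sw in sweep_specs
        ),
        key=lambda r: (r.chrom, r.start),
    )


def truth_regions(truth: TruthSet) -> list[Region]:
    """Planted sweep intervals, sorted; ready for BED export."""
    return sorted(truth.regions, key=lambda r: (r.chrom, r.start))


# ---------------------------------------------------------------------------
# config file support
# ---------------------------------------------------------------------------

def load_sim_config(path: str | Path) -> SweepSimConfig:
    """Load a simulator configuration from a YAML file.

    Keys mirror :class:`SweepSimConfig`; sweeps are a list of mappings with
    chrom/start/end/strength and an optional pools list.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sweeps = [
        SweepSpec(
            chrom=s["chrom"],
            start=int(s["start"]),
            end=int(s["end"]),
            strength=float(s.get("strength", 1.0)),
            pools=tuple(s["pools"]) if s.get("pools") else None,
        )
        for s in raw.get("sweeps", [])
    ]
    return SweepSimConfig(
        chrom_lengths=ChromSizes(
            {str(k): int(v) for k, v in raw["chrom_lengths"].items()}
        ),
        snp_density=float(raw.get("snp_density", 0.001)),
        n_domestic_pools=int(
            raw.get(
                "n_domestic_pools",
                len(raw["domestic_names"]) if raw.get("domestic_names") else 3,
            )
        ),
        depth_mean=float(raw.get("depth_mean", 30.0)),
        sweep_specs=sweeps,
        background_freq_alpha=float(raw.get("background_freq_alpha", 0.8)),
        background_freq_beta=float(raw.get("background_freq_beta", 0.8)),
        drift_sd=float(raw.get("drift_sd", 0.03)),
        seed=int(raw.get("seed", 0)),
        domestic_names=raw.get("domestic_names"),
        wild_name=raw.get("wild_name", "wild"),
    )


__all__ = [
    "SweepSpec",
    "SweepSimConfig",
    "TruthSet",
    "simulate_pools",
    "truth_regions",
    "load_sim_config",
]
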