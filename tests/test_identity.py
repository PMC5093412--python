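"""Identity score, gene-level IS, and the two-condition t-test ranking."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolsweep.identity import (
    MIN_P,
    gene_is,
    pairwise_is_matrix,
    rank_domestication_genes,
    ref_allele_fraction,
    snp_freq_diffs,
    snp_is,
    top_genes,
)
from poolsweep.model import GeneModel

from conftest import build_table


class TestRefAlleleFraction:
    def test_hand_arithmetic(self):
        assert ref_allele_fraction([6, 0, 0, 2], 0) == pytest.approx(0.75)

    def test_zero_reads_missing(self):
        assert math.isnan(ref_allele_fraction([0, 0, 0, 0], 0))

    def test_all_reference_reads(self):
        assert ref_allele_fraction([9, 0, 0, 0], 0) == 1.0

    def test_table_level_fraction(self):
        t = build_table(
            [("chr1", 10, "A", {"p": (6, 0, 2, 0)})], ["p"]
        )
        assert t.ref_fraction()[0, 0] == pytest.approx(0.75)


class TestSnpIs:
    def test_identical_fractions(self):
        assert snp_is(0.4, 0.4) == 1.0

    def test_maximal_divergence(self):
        assert snp_is(1.0, 0.0) == 0.0

    def test_hand_arithmetic(self):
        assert snp_is(0.7, 0.3) == pytest.approx(0.6)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=200, derandomize=True)
    def test_symmetric_and_bounded(self, f1, f2):
        assert snp_is(f1, f2) == snp_is(f2, f1)
        assert 0.0 <= snp_is(f1, f2) <= 1.0


class TestGeneIs:
    POOLS = ["a", "b"]

    def _table(self):
        # two SNPs inside [0, 100): IS = 1.0 and 0.6; one outside
        return build_table(
            [
                ("chr1", 10, "A", {"a": (4, 4, 0, 0), "b": (5, 5, 0, 0)}),  # F .5/.5
                ("chr1", 50, "A", {"a": (8, 2, 0, 0), "b": (4, 6, 0, 0)}),  # F .8/.4
                ("chr1", 500, "A", {"a": (0, 9, 0, 0), "b": (9, 0, 0, 0)}),
            ],
            self.POOLS,
        )

    def test_mean_of_snp_is(self):
        gene = GeneModel("g", "chr1", 0, 100)
        mean_is, n = gene_is(gene, self._table(), "a", "b")
        assert n == 2
        assert mean_is == pytest.approx((1.0 + 0.6) / 2)

    def test_no_qualifying_snps_missing(self):
        gene = GeneModel("g", "chr1", 1000, 2000)
        mean_is, n = gene_is(gene, self._table(), "a", "b")
        assert n == 0 and math.isnan(mean_is)

    def test_min_one_read_rule(self):
        table = build_table(
            [
                ("chr1", 10, "A", {"a": (4, 4, 0, 0), "b": (0, 0, 0, 0)}),
                ("chr1", 20, "A", {"a": (3, 3, 0, 0), "b": (1, 0, 0, 0)}),
            ],
            self.POOLS,
        )
        mean_is, n = gene_is(GeneModel("g", "chr1", 0, 100), table, "a", "b")
        assert n == 1  # the zero-read SNP is skipped
        assert mean_is == pytest.approx(1.0 - abs(0.5 - 1.0))

    def test_symmetric_in_pools(self):
        gene = GeneModel("g", "chr1", 0, 100)
        t = self._table()
        assert gene_is(gene, t, "a", "b") == gene_is(gene, t, "b", "a")

    def test_pool_with_itself_is_one(self):
        gene = GeneModel("g", "chr1", 0, 100)
        mean_is, _ = gene_is(gene, self._table(), "a", "a")
        assert mean_is == 1.0

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(21)
        sites = []
        for pos in sorted(rng.choice(5000, size=80, replace=False)):
            sites.append(
                (
                    "chr1",
                    int(pos),
                    "A",
                    {
                        "a": tuple(rng.integers(0, 12, 4)),
                        "b": tuple(rng.integers(0, 12, 4)),
                    },
                )
            )
        table = build_table(sites, self.POOLS)
        gene = GeneModel("g", "chr1", 1000, 4000)
        got, n_got = gene_is(gene, table, "a", "b")
        vals = []
        for chrom, pos, ref, cp in sites:
            if not (1000 <= pos < 4000):
                continue
            ca, cb = cp["a"], cp["b"]
            if sum(ca) == 0 or sum(cb) == 0:
                continue
            seg_any = any(
                sum(c > 0 for c in cts) >= 2 for cts in (ca, cb)
            )
            if not seg_any:
                continue
            fa = ca[0] / sum(ca)
            fb = cb[0] / sum(cb)
            vals.append(1 - abs(fa - fb))
        assert n_got == len(vals)
        assert got == pytest.approx(float(np.mean(vals)), abs=1e-12)


def students_t_oracle(a, b):
    """Textbook equal-variance two-sample t with df = n1 + n2 - 2."""
    from scipy.stats import t as tdist

    n1, n2 = len(a), len(b)
    s2 = (
        (n1 - 1) * np.var(a, ddof=1) + (n2 - 1) * np.var(b, ddof=1)
    ) / (n1 + n2 - 2)
    t = (np.mean(a) - np.mean(b)) / math.sqrt(s2 * (1 / n1 + 1 / n2))
    p = 2 * tdist.sf(abs(t), n1 + n2 - 2)
    return t, p


class TestRankDomesticationGenes:
    POOLS = ["d1", "d2", "d3", "w"]

    def _table_for_groups(self, gene_spans, per_gene_F):
        """Build sites so every gene has one SNP per pool with chosen F."""
        sites = []
        for (start, end), fvals in zip(gene_spans, per_gene_F):
            pos = (start + end) // 2
            counts = {}
            for pool, f in zip(self.POOLS, fvals):
                ref_reads = int(round(f * 20))
                counts[pool] = (ref_reads, 20 - ref_reads, 0, 0)
            sites.append(("chr1", pos, "A", counts))
        return build_table(sites, self.POOLS)

    def test_identical_groups_give_t_zero_p_one(self):
        # domestic pools differ slightly among themselves exactly as much as
        # they differ from wild -> within and cross IS coincide
        table = self._table_for_groups(
            [(0, 100)], [(0.5, 0.5, 0.5, 0.5)]
        )
        ranking = rank_domestication_genes(
            [GeneModel("g", "chr1", 0, 100)], table, ["d1", "d2", "d3"], "w"
        )
        assert ranking.loc[0, "t_stat"] == 0.0
        assert ranking.loc[0, "p_value"] == 1.0

    def test_degenerate_perfect_contrast_ranks_first(self):
        # within-IS all exactly 1, cross-IS all exactly 0.5: zero pooled
        # variance with separated means
        table = self._table_for_groups([(0, 100)], [(1.0, 1.0, 1.0, 0.5)])
        ranking = rank_domestication_genes(
            [GeneModel("g", "chr1", 0, 100)], table, ["d1", "d2", "d3"], "w"
        )
        assert bool(ranking.loc[0, "degenerate"])
        assert ranking.loc[0, "p_value"] == MIN_P
        assert np.isinf(ranking.loc[0, "t_stat"])

    def test_matches_textbook_t_oracle(self):
        # F values chosen to give distinct within-domestic and domestic-wild
        # IS groups; expected t and p from the closed-form df = 4 formula
        table = self._table_for_groups(
            [(0, 100)], [(0.95, 1.0, 0.9, 0.4)]
        )
        ranking = rank_domestication_genes(
            [GeneModel("g", "chr1", 0, 100)], table, ["d1", "d2", "d3"], "w"
        )
        a = [1 - 0.05, 1 - 0.05, 1 - 0.1]  # d1-d2, d1-d3, d2-d3
        b = [1 - 0.55, 1 - 0.6, 1 - 0.5]   # d1-w, d2-w, d3-w
        t, p = students_t_oracle(a, b)
        assert ranking.loc[0, "t_stat"] == pytest.approx(t, abs=1e-12)
        assert ranking.loc[0, "p_value"] == pytest.approx(p, abs=1e-12)

    def test_gene_without_snps_excluded_and_counted(self):
        table = self._table_for_groups([(0, 100)], [(1.0, 1.0, 1.0, 0.5)])
        genes = [
            GeneModel("has_snp", "chr1", 0, 100),
            GeneModel("empty", "chr1", 5000, 6000),
        ]
        ranking = rank_domestication_genes(genes, table, ["d1", "d2", "d3"], "w")
        assert list(ranking["gene_id"]) == ["has_snp"]
        assert ranking.attrs["excluded"] == 1

    def test_needs_two_domestic_pools(self):
        table = self._table_for_groups([(0, 100)], [(1.0, 1.0, 1.0, 0.5)])
        with pytest.raises(ValueError):
            rank_domestication_genes(
                [GeneModel("g", "chr1", 0, 100)], table, ["d1"], "w"
            )

    def test_top_k_larger_than_gene_count(self):
        table = self._table_for_groups([(0, 100)], [(1.0, 1.0, 1.0, 0.5)])
        ranking = rank_domestication_genes(
            [GeneModel("g", "chr1", 0, 100)], table, ["d1", "d2", "d3"], "w"
        )
        assert len(top_genes(ranking, 10)) == 1


class TestSnpFreqDiffs:
    POOLS = ["d1", "d2", "d3", "w"]

    def test_all_fixed_reference_delta_zero(self):
        table = build_table(
            [("chr1", 10, "A", {p: (9, 0, 0, 0) for p in self.POOLS}),
             ("chr1", 20, "A", {**{p: (9, 0, 0, 0) for p in self.POOLS[:3]},
                                "w": (4, 5, 0, 0)})],
            self.POOLS,
        )
        report = snp_freq_diffs(None, table, ["d1", "d2", "d3"], "w")
        row = report[report["pos"] == 10]
        assert len(row) == 0 or row["delta"].iloc[0] == 0.0  # monomorphic site is no SNP

    def test_near_fixed_contrast(self):
        # domestic pools fixed for the mutation, wild at 10% mutation
        table = build_table(
            [("chr1", 10, "A",
              {"d1": (0, 10, 0, 0), "d2": (0, 10, 0, 0), "d3": (0, 10, 0, 0),
               "w": (9, 1, 0, 0)})],
            self.POOLS,
        )
        report = snp_freq_diffs(None, table, ["d1", "d2", "d3"], "w")
        assert report["delta"].iloc[0] == pytest.approx(0.9)

    def test_hand_arithmetic(self):
        # F_dom = 0.2, 0.3, 0.4 and F_wild = 0.9 at depth 10
        table = build_table(
            [("chr1", 10, "A",
              {"d1": (2, 8, 0, 0), "d2": (3, 7, 0, 0), "d3": (4, 6, 0, 0),
               "w": (9, 1, 0, 0)})],
            self.POOLS,
        )
        report = snp_freq_diffs(None, table, ["d1", "d2", "d3"], "w")
        assert report["dom_mean_mut_freq"].iloc[0] == pytest.approx(0.7)
        assert report["wild_mut_freq"].iloc[0] == pytest.approx(0.1)
        assert report["delta"].iloc[0] == pytest.approx(0.6)

    def test_wild_zero_reads_skipped(self):
        table = build_table(
            [("chr1", 10, "A",
              {"d1": (2, 8, 0, 0), "d2": (3, 7, 0, 0), "d3": (4, 6, 0, 0),
               "w": (0, 0, 0, 0)})],
            self.POOLS,
        )
        report = snp_freq_diffs(None, table, ["d1", "d2", "d3"], "w")
        assert len(report) == 0 and report.attrs["skipped"] == 1

    def test_sorted_by_delta_descending(self):
        table = build_table(
            [
                ("chr1", 10, "A",
                 {"d1": (5, 5, 0, 0), "d2": (5, 5, 0, 0), "d3": (5, 5, 0, 0),
                  "w": (5, 5, 0, 0)}),
                ("chr1", 20, "A",
                 {"d1": (1, 9, 0, 0), "d2": (1, 9, 0, 0), "d3": (1, 9, 0, 0),
                  "w": (9, 1, 0, 0)}),
            ],
            self.POOLS,
        )
        report = snp_freq_diffs(None, table, ["d1", "d2", "d3"], "w")
        assert list(report["pos"]) == [20, 10]


class TestPairwiseIsMatrix:
    def test_symmetric_unit_diagonal(self):
        table = build_table(
            [("chr1", 10, "A", {"a": (8, 2, 0, 0), "b": (2, 8, 0, 0)})],
            ["a", "b"],
        )
        mat = pairwise_is_matrix(GeneModel("g", "chr1", 0, 100), table)
        assert mat.loc["a", "a"] == mat.loc["b", "b"] == 1.0
        assert mat.loc["a", "b"] == mat.loc["b", "a"] == pytest.approx(0.4)
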