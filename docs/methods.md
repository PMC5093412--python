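# Methods

This note documents the statistical model behind `poolsweep`, the design
choices made where conventions diverge, and what the built-in simulator
does and does not emulate.

## Data model

All statistics are computed from an allele-count table: for every site and
every pool, integer read counts of A, T, C and G (sync-format N and
deletion counts are parsed but discarded). Coordinates are 0-based
half-open internally; sync and VCF positions are converted on read and
reconverted on write, so interval algebra is uniform throughout.

A site is *segregating in a pool* when at least two nucleotides have a
positive count there, and counts as a SNP when it segregates in at least
one pool. Real studies obtain their SNP list from external variant
callers on alignments; this count-level proxy keeps the pipeline
self-contained and is applied consistently to windowed statistics, the
shared-SNP ratio and identity scores. A consequence worth knowing: a site
fixed for different alleles in different pools (monomorphic within every
pool) does not qualify — with realistic sequencing error and pool sizes
such perfectly clean fixed differences are rare, but on noiseless toy data
the rule is visible.

Each SNP's two alleles are the two nucleotides with the highest read count
summed over pools, ties broken toward the reference nucleotide and then
alphabet order. Major/minor status within a pool is decided from that
pool's own counts of those two alleles, which matches the pooled-
heterozygosity formulation below; allele frequencies for F_ST are computed
over the two site alleles so both pools describe the same axis.

## Site filter

The count-level filter retains sites where **every** pool's total depth
lies in [`min_depth`, `max_depth`] (defaults 4 and 1000), then enforces a
minimum distance between adjacent SNPs (default 5 bp) by a greedy
left-to-right rule: keep the first site per chromosome, drop any site
closer than the spacing to the last *kept* site. Greedy keep-first is the
rule thinning tools implement and is deterministic. Mapping-quality
filters need alignments and are assumed applied upstream of the count
table.

## Window statistics

Windows are 100 kb with a 50 kb step. Enumeration starts at every
multiple of the step while the start lies inside the chromosome, clips the
window at the chromosome end, and keeps a clipped window only if it is at
least one step long. Chromosomes shorter than the step yield no windows.
A SNP belongs to every window containing its position (so typically two).

Per window and domestic pool:

* `H_P = 2 ΣnMAJ ΣnMIN / (ΣnMAJ + ΣnMIN)²`, sums of per-SNP major/minor
  read counts. Reads, not frequencies, are summed, so deep sites weigh
  more; the statistic is invariant to scaling all counts.
* `F_ST` per SNP is the classical pooled estimator
  `(π_T − π_W)/π_T`, `π = 2p(1−p)`, undefined when both pools are fixed
  for the same allele. The window value is the unweighted mean of defined
  per-SNP values (an averaged per-SNP output); a ratio-of-sums
  aggregation, which damps low-frequency SNPs, is available via
  `fst_mode="ratio_of_sums"`. No pool-size/coverage bias correction is
  applied by default — with one statistic Z-standardised genome-wide, a
  multiplicative bias largely cancels.

Windows with fewer than `min_snps_per_window` SNPs (default 10) get
missing statistics: near-empty windows otherwise produce degenerate H_P
values that would distort the Z distribution.

Z-scores are `(x − mean)/sd` with the sample (n−1) standard deviation,
computed **genome-wide per population per statistic** over defined
windows, excluding a chromosome blacklist (default `X`/`chrX`, whose
suppressed recombination and history of introgression mimic sweep
signals). Standardising per chromosome instead would let sweep-dense
chromosomes hide their own signal. A constant statistic raises an
explicit degenerate-distribution error rather than emitting infinities.

## Region calling

Outlier windows satisfy `Z(H_P) < −2` and `Z(F_ST) > 2` (strict; a window
at exactly −2 is not an outlier). Both single-statistic window sets are
also reported, but a candidate domestication region (CDR) requires both —
the conjunction is what distinguishes a sweep from mere drift-driven
differentiation or low diversity.

Overlapping **or book-ended** outlier windows merge into maximal regions:
with a 50 kb step, touching windows tile one signal. Sharing across
populations is **base-wise**: a base belongs to the shared set when
covered by (by default) every population's CDRs; maximal runs form the
shared CDRs. Base-wise intersection is the simplest rule consistent with
"shared" and never extends beyond any population's own call; a
reciprocal-overlap criterion on whole regions would need an arbitrary
fraction parameter.

Genes overlap regions under a ≥1 bp rule by default (`contained` and
`midpoint` alternatives provided), deduplicated by gene id.

## Identity score and gene ranking

At each SNP, `F` = fraction of reads matching the reference allele in a
pool; `IS = 1 − |F₁ − F₂|` between two pools, with the SNP used only when
both pools have at least one read. Gene IS per pool pair is the
unweighted mean over the gene body's SNPs (no flanks; the per-SNP
frequency report around top genes uses a separate, configurable 5 kb
flank).

With three domestic pools, the ranking test contrasts group A = the three
within-domestic pairwise gene-IS values with group B = the three
domestic-vs-wild values, by a two-sided equal-variance Student's t-test
(df = 4; a Welch variant is behind `equal_var=False`). Power at df = 4 is
minimal — the test is a ranking device, not calibrated inference, which
is also why no multiple-testing correction enters the ranking (a
Benjamini–Hochberg column is emitted for transparency). Zero
pooled-variance genes (e.g. perfect sharing within, constant divergence
from wild) are flagged `degenerate` and assigned the smallest positive
double rather than dropped: they are the strongest possible contrasts and
must rank first. Ties on P break by |t| descending, then gene id, making
the ranking fully deterministic.

Genes with any missing pairwise IS or fewer than two comparisons per
group are excluded and counted. Note this makes a two-domestic-pool
design unusable for the t-test (one within-pair only); three domestic
pools is the minimum.

## Simulator

`simulate_pools` emulates the allele-count tables such a study produces:

* SNP positions uniform at `snp_density` (default 0.001/bp),
  deduplicated; each site biallelic — the reference base plus its
  transition partner.
* Ancestral reference-allele frequency `p0 ~ Beta(0.8, 0.8)`, a U-shaped
  site-frequency-spectrum proxy with mean heterozygosity
  2E[p(1−p)] ≈ 0.31.
* Wild pool sits at `p0`; each domestic pool adds independent truncated
  Gaussian drift noise (sd 0.03 — small enough that neutral Z
  distributions stay well-behaved, large enough that pools are
  distinguishable).
* Inside a planted sweep of strength `s`,
  `p_dom = (1−s)·p0 + s·target` with `target` the allele opposite the
  wild major allele — identical across the swept pools, modelling a
  sweep that predates the population split. Private sweeps can be
  planted via the per-sweep `pools` field for negative controls.
* Reads: depth `~ Poisson(depth_mean)` (default 30) per pool and site,
  reference reads `~ Binomial(depth, p)`.

Everything derives from one `numpy` generator seeded from the config, so
a seed reproduces byte-identical sync output.

Deliberately **not** modelled: linkage disequilibrium and recombination
(sites are independent), demography, sequencing error, mapping artefacts,
multi-allelic sites. Passing recovery tests therefore demonstrates that
the statistics, thresholds and region algebra behave as designed under
the stated sampling model — not that the scan is robust to LD-induced
autocorrelation or reference bias in real alignments.

## Validation problem sizes

The test-suite and acceptance-script simulations use a 20 Mb two-
chromosome genome at 1 SNP/kb and 30× depth with three domestic pools
(≈20,000 sites, 1,200 window statistics), and five 300 kb sweeps at
strength 0.95 for recovery runs — a scale at which the neutral Z(H_P)
lower tail is estimated from >10³ windows while everything runs in
seconds. Statistic oracles use 10³ random inputs at 10⁻¹² tolerance.

## Known limitations

* The neutral fraction of `Z(H_P) < −2` windows sits near the Gaussian
  2.3% but is seed-dependent at a few hundred windows per population;
  calibration claims use ≥1,000 pooled windows.
* Window H_P weights sites by depth; under strongly variable coverage
  the mean-of-ratios F_ST and read-sum H_P respond differently to the
  same sweep.
* Shared-CDR support lists populations covering any part of a region,
  not necessarily every base.
* The shared-SNP ratio depends on the segregating-site proxy above, so
  monomorphic-in-all-pools sites never enter either side of the Jaccard
  ratio.
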