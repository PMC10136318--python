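# Methods

## Scope and model

sweepscan detects candidate selective sweeps by contrasting two population
groups (wild vs. domestic, or broody vs. non-broody — any binary contrast
supplied through the population map) across a grid of overlapping genomic
windows, then interrogates candidate variants inside the selected regions.
It assumes unphased diploid genotypes at biallelic SNPs; phase is
discarded on input and every statistic is defined on allele dosages.

## Window statistics

**F_ST.** Per site we compute the Weir & Cockerham (1984) variance
components for r = 2 populations from each group's called-diploid count
n_i, alt-allele frequency p_i and observed heterozygote frequency h_i:
with n̄, n_c, p̄, s², h̄ as defined there,

- a = (n̄/n_c)·[s² − (p̄(1−p̄) − s²/2 − h̄/4)/(n̄−1)]
- b = (n̄/(n̄−1))·[p̄(1−p̄) − s²/2 − h̄(2n̄−1)/(4n̄)]
- c = h̄/2

and θ̂ = a/(a+b+c), undefined when the site is monomorphic overall or a
group has < 2 called diploids. The window F_ST is the arithmetic mean of
defined per-site θ̂. Negative per-site values are kept in the mean
(clamping them individually would bias the mean upward); only the final
reported window value is clamped at 0. A `weighted` switch instead uses
the ratio of summed components Σa/Σ(a+b+c); the default is the per-site
mean because the windowed quantity being averaged is "the SNPs in each
window", and the two variants rank windows nearly identically on data of
this type.

**π and the π ratio.** Per-site diversity in a group is the unbiased
expected heterozygosity 2p̂(1−p̂)·2n/(2n−1), identical to the mean pairwise
difference among the 2n sampled alleles. Window π is the sum of per-site
π over SNPs in the window divided by the window *span* in bp (so sparse
windows are not inflated), and the ratio is computed from the two
window-level π values, not as an average of per-site ratios — per-site
ratios are numerically unstable and undefined at sites monomorphic in one
group. Windows where the domestic-side π is exactly 0 while the wild side
is polymorphic get an infinite ratio and rank above every finite value in
outlier calling (total loss of domestic diversity is maximal evidence);
windows with zero diversity on both sides are excluded.

## Scan grid and outlier calling

Windows are 40 kb advancing by 10 kb (defaults; both are flags). Windows
start at 1, 1+step, …; the last start is the final one admitting a
full-length window; contigs shorter than one window contribute a single
truncated window whose actual span is the π denominator. Windows with
fewer than `min_snps` SNPs (default 10 — variance control at the 40-kb
scale) are flagged and excluded from thresholding.

The top-5% threshold for each statistic is the smallest observed value
with ≥ 95% of retained windows strictly below it; windows *equal* to the
threshold are selected. This order-statistic rule is exactly reproducible,
tie-stable, and invariant under monotone transforms of either statistic.
A window must meet both thresholds jointly. Selected windows merge when
they overlap or are book-ended (end+1 = start); merged regions carry the
max of member-window statistics and the genes they overlap by ≥ 1 bp.

The 100-gene ranking takes each gene's best (max) statistics over the
selected windows overlapping it, picks the top 50 by F_ST, then the top 50
by π ratio among genes not already picked, breaking ties by genomic
position. Shortfalls (fewer genes than requested) are returned in full and
logged.

## Follow-up stage

Stages run in a fixed order, each consuming the previous stage's
survivors: (1) per-SNP two-sided Fisher exact test on the 2×2 group ×
allele-count table; "significant" means raw p < 0.05 by default since this
mirrors the simple frequency-screen convention, but Benjamini–Hochberg
adjusted p-values are always written so users can tighten; (2) genotype
differentiation: each group's modal genotype frequency ≥ 0.8 (flag
`--fix-threshold`) and modal genotypes differing; (3) segregation: an
individual scores "yes" iff its genotype lies in the set expected for its
phenotype class, with the expected set defaulting to the discovery groups'
modal genotypes (heterozygotes mismatch unless the modal genotype is
heterozygous); tallies are reported per population with column-sum totals;
(4) LD: composite r² = squared Pearson correlation of dosage vectors over
pairwise-complete individuals — the phase-free definition — with
complete-LD groups assembled greedily in site order, a site joining the
first group to which all its pairwise r² ≥ 1 − 1e-9 (the tolerance absorbs
floating-point noise; exact duplicates give exactly 1).

## Simulator

The generator produces the statistical structure the scan assumes, with
analytic control rather than coalescent machinery:

- SNP counts per contig are Poisson at 2.2 SNPs/kb (default), positions
  uniform; ancestral frequencies p0 ~ Beta(0.8, 0.8) truncated to
  [0.05, 0.95] so every site is polymorphic somewhere.
- Group frequencies follow the Balding–Nichols model,
  p_g ~ Beta(p0(1−F)/F, (1−p0)(1−F)/F) with F = 0.1 by default, which puts
  the genome-wide mean window F_ST near F (measured ≈ 0.079 at 20+20
  diploids — estimator bias and binomial sampling pull it slightly below
  the nominal parameter, comfortably inside [0.05, 0.15]).
- Sweeps (default 20 window-sized intervals spread evenly over 10 Mb)
  push the domestic group's major allele to frequency
  max(0.95, f*), where 2f*(1−f*) equals the site's neutral expected
  diversity 2p0(1−p0)(1−F) divided by the configured reduction factor
  (default 10×). Solving for f* is what guarantees both stated contracts —
  the ≥ 0.95 frequency shift and the ≥ 10-fold expected diversity loss —
  simultaneously; the shift alone would only give ~3-fold under this
  frequency law.
- Causal phenotype SNPs sit inside the first sweep interval; cases (the
  domestic group) carry the homozygous reference dosage and controls the
  homozygous alternate, perfectly segregating at penetrance 1. At
  penetrance q, exactly round((1−q)·n) individuals are flipped to a
  contradicting genotype, so segregation no-counts are deterministic given
  the seed. Additional causal SNPs are exact dosage copies of the first,
  giving complete-LD partners (r² = 1) for the follow-up fixtures.
- Genes tile each contig deterministically (default 200 × 15 kb over
  10 Mb).

One `numpy` Generator seeded from `SimConfig.seed` drives all draws; a
config is echoed into the VCF header, and identical configs yield
byte-identical files.

**What the simulator does not emulate:** linkage between neutral sites
(independent draws — fine for window statistics, unrealistic for
haplotype methods), missing genotypes, genotyping error, demographic
history, recombination-rate variation, or soft sweeps. Passing tests
therefore show the scan machinery is correct and calibrated under the
assumed model, not that real data meet those assumptions.

## Numerical and I/O choices

Coordinates are 1-based inclusive in memory (VCF convention); BED output
is 0-based half-open. Missing genotypes are excluded per site per
statistic (not per sample); sites below a 0.5 per-group call-rate default
are dropped at load. Multiallelic and non-SNP records are skipped with a
logged count. Window tables round-trip through TSV at 6 significant
digits. The genotype PCA (mean-centred, 1/sqrt(p(1−p))-scaled dosages,
monomorphic sites dropped, missing imputed to the site mean) exists only
as a sanity check that simulated populations separate; published-tool PCA
runs are out of scope.

## Problem sizes

Default validation runs use 10 Mb of genome (5 × 2-Mb contigs, ~22,000
SNPs) with 20 + 20 diploids — large enough for ~1,000 scan windows and
stable top-5% thresholds, small enough that the full simulate–scan–
follow-up cycle completes in about a second.

## Known limitations

- With two populations the Weir–Cockerham estimator is noisy at sites with
  few called diploids; the window mean and `min_snps` mitigate but do not
  remove this.
- The joint top-5% rule fixes the *fraction* of windows called, not an
  error rate; on a genome with no sweeps it still selects up to the joint
  tail (typically far fewer, since the two statistics' tails need not
  coincide).
- Complete-LD grouping is greedy; for the exact-duplicate structure it is
  equivalent to maximal cliques, but near-threshold r² values could in
  principle depend on site order.
- The segregation rule treats the phenotype as fully penetrant and binary;
  dominance models are not fitted.
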