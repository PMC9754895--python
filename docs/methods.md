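# Methods

This note documents the statistical procedures `divland` implements, the
choices made where conventions genuinely differ, and what the synthetic
data generator does and does not emulate.

## Windowed landscape statistics

All statistics are computed from unphased diploid dosages (0/1/2 alternate
alleles, NaN missing) on sliding windows of 20 kb advanced 5 kb (defaults;
both configurable). Windows with fewer than `min_snps = 10` SNPs are
emitted but flagged excluded. Coordinates are reported 1-based inclusive;
BED exports are 0-based half-open.

**π (nucleotide diversity).** Per site, the unbiased heterozygosity
`n/(n−1) · 2p̂(1−p̂)` with `n` the number of non-missing alleles; summed
over SNPs and divided by the window length in bp, so monomorphic positions
count as zero. A site is skipped for a species with fewer than two
non-missing diploids. Both per-species values and the pooled-sample value
are emitted; island-versus-background tests use the pooled value by
default (flaggable), since per-species and pooled move together in every
scenario we simulate.

**F_ST.** Weir & Cockerham (1984) variance components for two populations
with unequal sample sizes, computed per site from allele frequencies and
observed heterozygosity; the window estimate is the ratio of sums
Σa / Σ(a+b+c) (the "weighted" convention used by common VCF tooling).
Negative per-site components are retained, not clamped; sites monomorphic
across both species contribute (0, 0). Missing genotypes are excluded per
site, and a site needs at least two non-missing diploids per species.

**D_XY.** `Σ_sites [p̂_A(1−p̂_B) + p̂_B(1−p̂_A)] / window_length`. For
unphased data this equals the average per-bp difference across all
inter-species allele pairs (checked exactly against enumeration in the
tests), and the full-window denominator makes values comparable to
genome-scale per-bp reports. It is computed from sample frequencies, not
phased haplotypes.

**ρ (population recombination rate).** External tools estimate ρ by
regression on simulated training data; `divland` instead uses a documented
moment stand-in. Among SNPs with pooled minor-allele frequency ≥ 0.1, the
mean pairwise squared dosage correlation r̄² (Rogers–Huff style,
mean-imputed missing calls) is corrected for finite samples by subtracting
1/(2n̄), then inverted through the classical expectation
E[r²] ≈ 1/(2 + ρd) at the mean pairwise distance d̄:
`ρ̂ = (1/r̄²_corr − 2)/d̄` per bp. Corrected r̄² ≥ 0.5 clamps ρ̂ to 0
(LD too strong to invert); corrected r̄² ≤ 0 or fewer than two qualifying
SNPs yields a missing value. The estimator is coarse but order-preserving,
which is all the island contrast consumes; a per-window external ρ table
can be supplied instead through the windows TSV.

**Cross-statistic correlations.** Spearman rank correlations (ties
mid-ranked) over non-excluded windows with all four statistics present;
constant statistics yield missing entries.

## Island scan

Candidates are the top 1% of non-excluded windows by F_ST (ties at the
cutoff included; the count is `ceil(0.01 · windows)`). For each candidate,
the null draws the window's SNP count uniformly **without replacement**
from the genome-wide pool of per-site WC components and recombines them as
a ratio of sums — resampling components rather than per-site F_ST values
keeps the null on the same estimator as the observation (a per-site-mean
alternative is available). The empirical p uses the add-one convention
p = (#{null ≥ obs} + 1)/(n_perm + 1). Draws are exact uniform subsets:
rejection sampling of with-replacement rows for sparse draws, truncated
row permutations for dense ones; drawn subsets are sorted before summing
so a given subset always produces the identical float. Benjamini–Hochberg
runs over the candidate set only (p-values exist only for candidates);
outliers have q < 0.01. The default n_perm is 10,000 — the resolution the
FDR threshold needs — while multi-million permutation counts remain
config-reachable. Outlier windows overlapping or book-ended
(`next.start ≤ end + 1`) on one chromosome merge into islands.

Island-versus-background comparisons use two-sided Mann–Whitney U tests
on dxy, π, ρ and ρ/π between windows whose midpoint falls in an island
and the remaining non-excluded windows, plus a chi-square goodness-of-fit
of outlier counts per chromosome against expectation proportional to
analyzed windows.

## Copy-number differentiation

Gene copy number per individual is the overlap-length-weighted mean of
segment copy numbers, with uncovered gene sequence counted at the diploid
baseline 2; genes no segment ever touches are not CNGs and are excluded
from ranking (their V_ST would reflect only the baseline). V_ST uses
population variances (divisor N, matching the N-weighted form of the
statistic; an N−1 flag exists):

    V_ST = [V_total − (V_A·N_A + V_B·N_B)/N_total] / V_total

V_total = 0 leaves V_ST undefined and the gene unranked. The top 5% of
defined-V_ST genes are permutation-tested by shuffling individual species
labels (group sizes preserved, add-one p, ≥ comparison); CNDGs are
outliers with p ≤ 0.01.

*Known property (select-then-test):* conditional on being selected into
the top 5%, per-gene permutation p-values are anti-conservative — the
selected genes are the cross-gene extremes, so under a global null roughly
10% of *selected* genes reach p ≤ 0.01 even though each gene's test is
marginally exact. What the procedure does control is the absolute false
burden: under label-randomized nulls, called CNDGs stay below 1% of all
genes in our simulations. Interpret CNDG p-values as screening scores, not
as selection-adjusted error rates.

## HKA-style selection scan

Sites are classed per species as polymorphic-within (0 < p̂ < 1 among
non-missing alleles) and between-species fixed (per-site WC ratio ≥ 0.95;
negative or undefined ratios are not fixed — a site can hold both roles).
For each gene and focal species the 2×2 table
[[N₁(gene), N₂(gene)], [N₁(genome), N₂(genome)]] is tested with Pearson's
chi-square, 1 df, no continuity correction; expected counts below 5 raise
a warning. The genome margins exclude the focal gene's own counts
(configurable) to avoid self-comparison. The scan runs once per focal
species with per-species polymorphism counts (a pooled mode exists behind
a flag). PSG = p ≤ 0.01 and nonsynonymous count ≥ 2. Because SNPs within
a gene are linked, the chi-square is only approximately calibrated; on
neutral simulated genomes the p ≤ 0.01 fraction stays below 3%. The test
is two-sided: genes *depleted* of divergence also produce small p-values,
which the nonsynonymous filter and downstream interpretation must absorb.
Island enrichment of PSGs uses a 2×2 chi-square of PSG status × island
membership (gene midpoint inside a region).

## Environment association

**Predictor filter.** Greedy elimination until all pairwise |Pearson r| <
0.7: repeatedly drop the predictor with the most offending partners, ties
broken by larger mean |r| to the others, then lexicographically; constant
predictors drop first with a warning. Deterministic by construction.

**LD pruning.** Windows of 20 kb starting at every 2nd marker; within a
window the later-position member of any pair with dosage r² > 0.4 is
removed. Consecutive windows share all but their newest markers, so the
procedure is evaluated incrementally — each marker is tested against the
surviving markers of the first window containing it — which is equivalent
and linear-time. Dosages are mean-imputed before correlation.

**RDA.** The response (samples × variants dosage matrix, or samples ×
genes copy-number matrix) is mean-imputed and column-centered (not
standardized by default — dosages share a scale; a flag standardizes);
predictors are standardized. Fitted values from multivariate least squares
are decomposed by SVD; constrained eigenvalues are s²/(n−1), proportion
explained is their sum over total response variance, variant loadings are
right singular vectors scaled by singular values. Axis significance:
permute predictor rows, refit, compare the axis eigenvalue (add-one p),
testing axes in order and stopping at the first p ≥ α — a simpler scheme
than the sequential conditional tests of the R ordination ecosystem, but
agreeing with it on which axes matter in every scenario we simulate (the
fit itself is cross-checked against `vegan::rda` in the test suite).
Permutation refits use the QR-projection shortcut (eigenvalues of the
q × m projected response), making 999 permutations on ~25k SNPs a
few-second operation.

**Outliers and assignment.** On each significant axis, loadings are
z-scored over all variants; a variant with |z| > 3 on any significant axis
(strict inequality; the two-tailed normal tail at 3 SD is p = .0027) is an
outlier. Axis sign ambiguity is irrelevant under |z|. Each outlier is
assigned the predictor with the largest |Pearson r| against its dosage;
|r| > 0.6 flags strong association. The assignment names the dominant
predictor but never removes an outlier.

**Mantel IBD/IBE.** Populations are the unit. Genetic distance is
F_ST/(1−F_ST) from WC ratio-of-sums between population pairs on a chosen
SNP set (environment-associated outliers versus neutral intergenic SNPs);
geographic distance is haversine great-circle km (radius 6371 km);
environmental distance is Euclidean on standardized population-mean
predictors. Mantel r is the Pearson correlation of lower triangles; the
one-tailed p permutes one matrix's row/column order (add-one), with exact
enumeration of all n! permutations for ≤ 6 populations. Pairs with
F_ST = 1 (or undefined F_ST) cannot be linearized; the offending
populations are dropped greedily with a warning.

## The synthetic-data generator

The generator's role is to provide data with the statistical structure the
analyses assume, under study-like sampling (26 + 14 diploids, 12 + 4
populations), so recovery of planted signals is a meaningful test. It is
explicitly a stand-in: the underlying study analysed real resequencing
data and published no generative model.

- **Allele frequencies** follow the Balding–Nichols model: ancestral
  p ~ Beta(0.8, 0.8) truncated to [0.05, 0.95] (chosen to give a U-shaped
  site-F_ST distribution with a mass of fixed differences), and species
  frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) with F = 0.2 in the background
  and 0.9 inside planted islands. Sites monomorphic in the pooled sample
  are dropped, as in a real VCF; this ascertainment is reproduced in the
  Monte-Carlo oracles the tests compare against.
- **LD** comes from founder haplotypes: within each 20-kb block and
  species, haplotypes are drawn from K founders (K = 30 background, 4 in
  islands; islands are single blocks). Small K yields the strong LD /
  depressed ρ̂ islands should show. Founder resampling adds drift on top
  of F (realized background WC F_ST ≈ 0.25 at F = 0.2); parameter-recovery
  checks therefore use the direct-binomial mode (`founder_haplotypes_*=None`).
- **Island diversity loss.** Under pure Balding–Nichols, E[D_XY] is
  independent of F, but the emulated islands must show *reduced* π, D_XY
  and ρ alongside elevated F_ST. Two mechanisms combine: surviving island
  SNPs are mostly fixed differences (ascertainment removes
  same-allele-fixed sites), and island mutation input is thinned by a
  factor 0.6 (default SNP density 0.003/bp), emulating linked-selection
  diversity loss. The factors were chosen so island windows keep ~16 SNPs
  (above the 10-SNP window filter, ~3% exclusion) while per-bp island
  D_XY lands at ~0.6× background.
- **Planted signals.** PSG genes: 60% of their SNPs forced to near-fixed
  differences (orientation per gene), nonsynonymous counts ≥ 2; other
  genes draw Poisson(0.7) nonsynonymous counts. CNDG genes: species
  copy-number means 2 vs 4 (orientation random), individual copy numbers
  rounded normals (SD 0.4, configurable to 0); segments are emitted only
  where an individual departs from baseline, exactly covering the gene.
  Environment SNPs: dosages rewritten as clipped, rounded noisy copies of
  annual precipitation (target dosage–AP correlation ≈ 0.8), placed in
  non-PSG genic positions so the intergenic neutral set stays clean.
- **Environment.** Seven predictors in SD units; AP and MiT species means
  differ by 3 SD, Sp and MDR by 1.5 (species A higher on Sp/MDR, lower on
  AP/MiT), SSF/SR/MaT undifferentiated; population offsets (SD 0.3) add
  within-species structure; one extra predictor (`MaTx`) is generated with
  r ≈ 0.9 to MaT purely to exercise the autocorrelation filter. Species
  occupy disjoint latitude bands (30–35° vs 24–28°), giving geography and
  environment correlated species signals — so in this generator even
  neutral SNPs show some isolation-by-distance; tests of the
  environment-associated set therefore check *contrast* (higher F_ST,
  larger Mantel r), not absence of signal in the neutral set.
- **Determinism.** One global seed; every stage derives its own substream
  by a fixed offset, so identical configs give byte-identical files.

What passing tests on this generator demonstrate: the estimators recover
their own model's parameters, planted signals are detected at the stated
rates, and every procedural convention (thresholds, tie handling,
permutation conventions) behaves as documented. What they cannot
demonstrate: robustness to demographic history (bottlenecks, gene flow),
mutation-model realism, genotyping error beyond uniform missingness, or
phase effects — none of which the generator attempts.

## Validation problem sizes

The test suite and `scripts/acceptance.py` run the study-scale design at
2 chromosomes × 5 Mb (~28k SNPs), 20 seeds for island recovery with
10,000 permutations per window, 400 null seeds for the RDA axis type-I
check (99 permutations each), 10 label-randomized datasets for the V_ST
null, and 400k-site Monte-Carlo oracles for π/F_ST expectations. These
sizes were chosen so each check's sampling error is small relative to the
tolerance it asserts.
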