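# Methods

This note records the models, estimators, parameter choices and known
limitations behind `sweepscan`.  It is written for an analyst who wants
to know exactly what each number means and what the synthetic-data tests
do and do not demonstrate about real data.

## Data model and conventions

Genotypes are phased biallelic SNPs on one contig per object.  Positions
are 1-based inclusive (as in VCF); window indices into the site axis are
half-open.  Haplotype matrices are `n_sites x 2·n_samples` in {0,1} with
a sample's two haplotypes in adjacent columns; diplotype matrices are
`n_sites x n_samples` in {0,1,2} with −1 marking missing calls.
Multiallelic and non-SNP records are dropped at ingest with a logged
count.  Summing a sample's haplotype pair always reproduces its
diplotype row; this identity is asserted in the test suite.

Missing-data policy: haplotype-based statistics assume complete data
(the simulator emits none; VCF ingest flags missingness on the diplotype
side so callers can drop incomplete sites first).  Diplotype clustering
uses pairwise-complete sites and imputes nothing.  The per-SNP
association test uses only SNPs with no missing calls.

## Windows

Scans use windows of a fixed number of SNPs (default 500, contiguous,
trailing partial window dropped; both width and step are configurable,
so moving windows are available).  SNP-count windows keep the haplotype
space per window comparable across the genome, which the H statistics
require; base-pair bounds are reported for every window so tracks export
as BED.  Analyses of the desk-scale simulated cohorts in the examples,
tests and the acceptance script use 50-SNP windows (20-25 in the
permutation-calibration tests): the simulated site density is roughly
two orders of magnitude below a sequenced cohort's, and the window size
is scaled accordingly so that a sweep spans a handful of windows, as it
would at full density.

## Diversity statistics

Per site with alternate-allele frequency p among n haplotypes, the
unbiased pairwise diversity is 2p(1−p)·n/(n−1); window θπ divides the
sum over sites by the total site count of the window (monomorphic sites
included), the usual per-site convention — the source analyses do not
state a denominator.  Watterson's θW = S/a₁ per window (a₁ = Σ 1/i).
Tajima's D uses the 1989 constants computed from n, with π and θW on the
whole-window scale; windows with S = 0 yield NaN rather than an error so
scans stay aligned.  D is computed on haplotype allele counts
(equivalent to genotype counts for phased data).  The implementation is
tested to 1e-10 against an independently coded constants implementation,
and π against all-pairs Hamming counting.

## F_ST

Two moment estimators are provided.  Hudson:
N = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1),
D = p₁(1−p₂) + p₂(1−p₁).  Patterson, with unbiased heterozygosity
ĥ = p(1−p)·n/(n−1): N = (p₁−p₂)² − ĥ₁/n₁ − ĥ₂/n₂, D = N + ĥ₁ + ĥ₂.
Aggregation is ratio-of-averages (ΣN/ΣD), which avoids the bias of
averaging per-site ratios; sites with D = 0 (monomorphic in both
cohorts) are excluded.  Estimates are reported signed — small negative
values are ordinary sampling noise under panmixia and clamping them
would bias window means upward.

The resampling null treats each randomly chosen individual as a
population of two alleles, so Patterson's estimator (which needs
within-population heterozygosity) applies to a single diploid.  Every
iteration redraws both the pair and the SNP set.  A caveat the test
suite works around deliberately: iterations share one finite dataset, so
the within/between null distributions are not i.i.d. samples, and the
Mann-Whitney comparison is only approximately calibrated.  The
calibration test therefore uses a site pool and cohort large relative to
the per-iteration draw (3,000 sites, 250-SNP draws, 48 individuals per
region, 100 iterations), where the residual dependence is negligible;
with aggressive reuse (e.g. drawing a third of all sites per iteration
from a small cohort) the test becomes anticonservative, which users
should keep in mind when running it on small cohorts.

## Neighbour joining and PCA

NJ is the Saitou-Nei algorithm with standard Q-matrix selection and
branch-length formulas, ties broken on the smallest pair index so output
is reproducible.  Negative branch lengths are clamped to zero with the
excess moved to the sibling branch, preserving the joined pair's path
length.  On additive matrices NJ is exact; the tests verify exact
recovery of topology and branch lengths from random additive trees
(4-12 taxa) and cross-check topologies against an independent NJ
implementation.  PCA mean-centres each site and, by default, scales by
√(p(1−p)) (Patterson scaling); components come from an SVD and are
deterministic up to sign.

## H statistics, peaks, and the temporal contrast

H1, H12, H123 and H2/H1 are computed from exact full-window haplotype
counts (no similarity threshold); H12 pools the top two frequencies and
detects both hard and soft sweeps.  H1X(A,B) = Σ_h f_A(h)·f_B(h) over
jointly keyed haplotypes measures sweep sharing between cohorts; the
suite asserts H1X(A,A) = H1(A) and the Cauchy-Schwarz bound
H1X ≤ √(H1(A)·H1(B)).

Genome-wide thresholding takes the top-1% empirical quantile of all
window values pooled across contigs (linear interpolation).  Peaks are
maximal runs of above-threshold windows, merging runs separated by at
most `max_gap_windows` (default 0) below-threshold windows, never across
contigs; the summit is the argmax window.  This run-merging rule is a
deliberately simple, reproducible stand-in for model-based peak
delineation.  Note a small-track effect: with a few hundred windows the
top-1% rule admits only a handful of windows, so when sweeps of unequal
strength coexist the threshold is set by the strongest sweeps and weaker
ones can fall below it; the acceptance script reports the recovered
count as computed.

ΔH12 = H12(post) − H12(pre) per window, so positive values mean reduced
haplotype diversity after the intervention; a `signed` flag flips the
exceedance rule for callers who prefer the opposite convention.  The
peak rule flags |Δ| > 3 × (P98 − median) of the genome-wide Δ
distribution, positive and negative excursions separately.  Significance
comes from permuting individual (not haplotype) pre/post labels —
both haplotypes of a mosquito move together, respecting within-individual
dependence — with one shared label shuffle per permutation across all
windows and the two-sided add-one estimator
p = (1 + #{|Δperm| ≥ |Δobs|}) / (1 + n_perm), so p ∈ (0,1] and p-values
are exactly reproducible under the seed.  No multiple-testing correction
is applied to permutation p-values; the working threshold is raw
p < 0.01, with 0.05 available as a "marginal" tier.

## Diplotype clustering

Distances between samples are city-block sums Σ|gᵢ−gⱼ| over
pairwise-complete sites.  Complete linkage is implemented directly — at
each step the pair of clusters with the smallest maximum inter-member
distance merges, ties broken on the smallest cluster indices — because
genotype distances are integers and tie behaviour must be deterministic
for reproducible dendrograms.  The merge table follows the scipy
convention, so scipy's cutting and dendrogram utilities apply; tests
verify agreement with both a naive O(n³) reference and scipy's
implementation on continuous matrices.  Cluster summaries report size,
tag-SNP allele frequencies, metadata composition and mean
heterozygosity; a swept cluster shows high tag frequency and depressed
heterozygosity.  The flat-cut criterion (height or k) is left to the
user, as no principled default exists.

## Per-SNP association

Each SNP's per-sample alternate-allele count (0-2 of 2 trials) is
modelled as binomial with logit link and survey round as the only
covariate.  Household dependence is absorbed by a cluster-robust
sandwich variance over households rather than an explicit random effect:
at per-SNP scale the robust Wald test is numerically stable, has no
convergence failures, and is asymptotically equivalent for testing the
round effect; the calibration test shows it holds ~5% type-I error under
strong household effects where the naive binomial test exceeds 15%.
Two caveats: with few households the normal reference for the sandwich
statistic is anticonservative (a cluster count of ~40+ behaves well),
and the robust variance correctly discounts the perfect correlation of a
homozygote's two alleles, so homozygote-heavy sites get larger p-values
than an allele-counting test would give.  Under complete separation
(one round monomorphic) the Wald statistic degenerates and the p-value
falls back to a likelihood-ratio test, flagged per row.  BH step-up FDR
is applied over all tested SNPs genome-wide.

## Synthetic cohorts

The generator emulates a two-region (East/West), two-round
(baseline/round 5), two-arm (PBO/nonPBO) cluster-randomised trial.
Defaults: 25 samples per (region, round, arm) cell (200 total);
three contigs of 90/80/18 Mb carrying 9,000/8,000/6,000 uniformly placed
sites; households of mean size 3 with a logit-normal allele-frequency
effect of scale σ_h = 0.25; regional differentiation as independent
logit-scale perturbations with variance d = 0.01, chosen to put windowed
Hudson F_ST on the ≤0.003 scale observed between weakly differentiated
field populations (d = 0 gives exact panmixia).  Site frequencies follow
the standard neutral SFS, P(i) ∝ 1/i over derived-allele counts
i = 1..2n−1.

Five default sweeps sit at the resistance-locus geometry from East
African surveillance — RP1 (2RL ~8.7 Mb), Gste2 (2RL ~76.4 Mb), TMC
(3RL ~67.9 Mb), Cyp9k1 (X ~8.4 Mb), Dgk (X ~13.6 Mb) — with
per-(round, arm) frequencies that shift over the trial: RP1 up in the
nonPBO arm but down under PBO, Cyp9k1 and TMC up under PBO, Dgk down in
both arms, Gste2 up in both.  A sweep replaces a fraction f of cohort
haplotypes with copies of 1 (hard) or ≥2 (soft) core haplotypes across
its window; per-site reversion probability grows linearly with distance
from the centre (edge rate 0.2 by default), producing peak-shaped
signals that exercise peak calling; the site nearest the centre is a tag
SNP fixed alternate on every core.  Default half-widths (600 kb on the
autosome-scale contigs, 250 kb on X) are set so a sweep spans at least
one full 50-SNP window at the default site density.  Everything is
deterministic under the design seed.

What the generator does **not** emulate — and hence what passing tests
cannot show about real data: background linkage disequilibrium (sites
are in linkage equilibrium, the simplest null under which window H12 is
exchangeable; real LD widens H12 nulls), recombination gradients around
sweeps, inversion polymorphism, sequencing/phasing error, and realistic
SFS distortion from demography.  Power and calibration results transfer
to field data only qualitatively.

## Problem sizes in tests and the acceptance script

The suite runs the full ladder at desk scale: H and diversity oracles on
~1,000 random windows; F_ST null calibration over 200 replicate
simulations; ΔH12 calibration over 200 windows × 20 seeds (n_perm 400);
sweep recovery over 50 seeds (n_perm 200, 50 samples per round); GWAS
null over 20 seeds of 800 sites and power on 5,000 sites with 100
samples per round.  The acceptance script runs the default 200-sample,
23,000-site cohort with 1,000 F_ST iterations and 1,000 ΔH12
permutations per arm.
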