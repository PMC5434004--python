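# Methods

This note documents the statistical models behind popstrata, the defaults
that matter, what the synthetic-data generator does and does not emulate, and
the numerical choices made where conventions were genuinely open.

## Genotype model and QC

Genotypes are diploid dosages of `allele_b` (0/1/2, −1 missing) over
biallelic autosomal SNPs with both physical (bp) and genetic (cM) positions.
QC applies, in a fixed order, (1) a per-variant call-rate filter (keep iff
call rate **strictly above** 0.90), then (2) a per-individual missingness
filter judged on the surviving variants (keep iff missingness strictly below
0.01). The variant filter runs first so individual missingness is measured on
usable sites; the fixed order makes results deterministic, and the filter is
idempotent.

Relatedness uses the Purcell-style method-of-moments estimator: per-pair
observed IBS-state counts are combined with per-site expected IBS
probabilities given IBD state (computed from sample allele frequencies under
Hardy–Weinberg) to solve for P(IBD=0/1/2), clamped to the simplex;
PiHat = P(IBD=1)/2 + P(IBD=2). Pairs with PiHat > 0.125 (third-degree
relatives) lose one member — the one with more missing data, ties broken by
removing the lexicographically larger id; removal iterates until no retained
pair offends. PiHat is computed on the full QC'd SNP set by default (pruning
first is possible but not the default, since the estimator is frequency-aware
and the test scenarios carry little LD).

Merging matches variants by id (position disagreements warn only), and
harmonizes allele encodings by direct, swapped, complemented or
swapped-complemented match — which is only safe because strand-ambiguous
A/T and C/G sites must be removed first. A swap recodes calls c → 2−c.

LD pruning is greedy left-to-right on genotype-dosage Pearson r² (phase-free)
in windows of 50 SNPs advanced by 10, never spanning chromosomes, removing
the right member of any pair with r² > 0.1. Missing calls are handled
pairwise-complete in frequencies, r² and IBS counts throughout.

## f-statistics

For target A and sources B, C the per-site term is
`(a−b)(a−c) − a(1−a)/(n_A−1)`, where n is the number of observed alleles; the
correction removes the sampling bias of â(1−â) and is applied to the target
only, so the reported f3 is unnormalized but unbiased under the null. Sites
need n ≥ 2 in A and a defined frequency in B and C; sites failing this are
dropped per statistic, not globally. D uses numerator `(w−x)(y−z)` and
denominator `(w+x−2wx)(y+z−2yz)` summed before dividing.

Uncertainty comes from a weighted delete-one-block jackknife (Busing's
formula) over contiguous, chromosome-respecting blocks of near-equal variant
count — 997 by default, apportioned to chromosomes by variant share, so the
realized count can deviate by at most one per chromosome. Block construction
is by variant count, not by cM. The admixture screen evaluates every ordered
target with every unordered source pair (g·C(g−1,2) trios) and flags Z < −2;
the threshold is a configuration default.

Exactness guarantees checked by the tests: vectorized f3/D equal a per-site
scalar reference to 1e−12; f3 is symmetric in its sources; D flips sign
exactly under swapping within either pair; everything is invariant under
global allele relabeling.

## Weighted-LD dating

An admixture pulse G generations ago induces covariance between linked sites
that decays as e^(−G·d) in genetic distance d (Morgans). For target
genotypes and two reference populations, each intra-chromosome site pair
contributes `w_s·w_t·C_st` with weights `w = p_ref1 − p_ref2` and `C` the
genotype covariance across target individuals divided by 2 — a phase-free
approximation to haplotype LD valid under random mating. Contributions are
averaged in distance bins (default width 0.1 cM) over d ∈ [0.5, 30] cM; the
lower cutoff suppresses background LD shared with the references. There is no
automated pre-test for ancestral LD shared with the references; users should
choose references they trust to be unadmixed relative to the target (a
documented limitation of this implementation).

The curve is fit by nonlinear least squares to `A·e^(−G·d) + c`
(log-linear initialization); the SE of G comes from a delete-one-chromosome
jackknife refit. Degenerate inputs — flat curves, amplitude indistinguishable
from residual noise, negative fitted A, non-convergence — are reported with
`converged = False` and a NaN date rather than a spurious finite estimate.
Dates convert to years at 28 years/generation (configurable), and estimates
beyond 100 generations are flagged as past the method's detection threshold.
Only the two-reference weighting mode is implemented; one-reference and
multiple-pulse models are out of scope.

## IBD sharing and ROH

Segment calls are inputs (cM coordinates, unordered pairs stored
canonically); the package never calls segments from genotypes. Processing is
stitch → filter, in that order: same-pair same-chromosome segments separated
by gaps ≤ 0.5 cM (default; the exact threshold of the upstream gap-closing
script is not standardized, so it is exposed as a parameter) are merged, then
only segments **strictly longer** than 1 cM are kept, reflecting the low
power of the upstream caller below that length. Stitching first can only
promote fragmented blocks past the filter, never lose length.

`W_AB` is total shared length divided by n_A·n_B between populations and by
n(n−1)/2 within one; each segment also lands in exactly one half-open length
class [1,2), [2,3), [3,4), [4,5), [5,∞) cM, so class values sum to the
total. Runs of homozygosity restate the PLINK defaults as explicit
parameters: scanning windows of 50 SNPs with ≤1 heterozygote and ≤5 missing,
a SNP joins a run when ≥5% of its covering windows are homozygous, and
candidate runs must have ≥100 SNPs, ≥1,000 kb, ≤50 kb/SNP density and no
internal gap >1,000 kb. Populations with n < 10 are flagged in the
within-population summary as pooling candidates.

## Differential sharing screen

Each focal population's sharing vector against a fixed comparison panel is
averaged within groups; group pairs are subtracted. The bounds are the
empirical 0.10 and 0.90 quantiles (linear interpolation between order
statistics) **of each difference vector itself** — per group pair, not pooled
across pairs — and entries strictly outside are flagged toward the group in
excess. Each flagged entry is tested with the two-sided single-outlier Grubbs
test, repeated per candidate rather than iteratively with removal, matching a
per-cell star annotation; stars at p < 0.05/0.01/0.001. The p-value inverts
the critical-value relation `G_crit = (n−1)/√n · √(t²/(n−2+t²))` with
`t = t_{α/(2n), n−2}`, i.e. `p = min(1, 2n·SF_t(t(G), n−2))`.

The screen is a pure function of the sharing matrix and group definitions and
is exactly antisymmetric under swapping the two groups. Under a null with
exchangeable values, the percentile construction flags ≈10% of entries per
tail by design; the Grubbs stars are what separate noise from signal.
Populations such as ethno-linguistic minorities can be excluded from group
averages and screened separately by simply defining them as their own group.

## PCA and supervised ancestry

PCA standardizes each variant by its mean genotype and √(p̄(1−p̄)) with
p̄ = mean/2, mean-imputes missing calls for fitting, and takes the top-k SVD.
New samples (ancient or low-coverage) are projected by least squares on each
sample's non-missing variants only — the two missing-data policies
(mean-impute to fit, subset-solve to project) intentionally differ, mirroring
how reference tools treat training versus projection data. With no
missingness, projection reproduces training scores exactly.

Component allele frequencies F come from pooled counts of labeled reference
populations, clamped to [1e−5, 1−1e−5]; unsupervised fitting of components
is out of scope, so the reference-population surrogate replaces an
unsupervised decomposition while preserving the projection logic. Simulated
100%-component individuals (100 per component, 400 for the four-component
design) anchor component interpretation. Per individual, ancestry proportions
maximize `Σ_s [g log(qᵀF) + (2−g) log(qᵀ(1−F))]` over the simplex by
multiplicative EM updates (monotone by construction); missing genotypes are
skipped per site, convergence is a log-likelihood gain below 1e−6.

## Synthetic data: what it emulates, and what it does not

Components drift independently from a single shared ancestral frequency pool
(star phylogeny) under Balding–Nichols: p′ ~ Beta(p(1−F)/F, (1−p)(1−F)/F).
Default FSTs (0.05–0.15) are calibration choices representative of
continental-scale structure, not measured values. Ancestral frequencies are
uniform on a folded MAF range (default 0.05–0.5). The genetic map is uniform
at 1 cM/Mb over 22 synthetic chromosomes of 100 cM (configurable) with
evenly spaced variants; real maps vary locally, which mainly affects
fine-scale LD, not the recovery properties tested here.

Admixed individuals are single-pulse Markov mosaics: breakpoints Poisson at
G per Morgan, tract ancestries i.i.d. categorical(α), alleles Bernoulli from
the tract component — per haplotype, tracts tile each chromosome exactly.
Isolates recombine a small founder haplotype pool (default 10 haplotypes,
founder switches at 1/Morgan), elevating ROH and within-group sharing.
Planted IBD segments are declared (segment lists with truncated-exponential
lengths, mean = min + scale by memorylessness, placed uniformly on the map)
rather than written into genotypes, since all downstream sharing statistics
consume segment lists. All generators are pure functions of (parameters,
seed), and all truth (α, G, per-individual ancestry, planted segments,
isolate flags) serializes alongside the data.

Not emulated: coalescent genealogies, mutation, selection, phasing error,
ascertainment bias, genotyping error, multi-pulse or continuous migration.
Passing recovery tests therefore demonstrates correctness of the estimators
under their own model assumptions, not robustness to every artifact of real
array data.

## Problem sizes and reproducibility

The test suite and acceptance script run the screen-recovery scenario at
50,000 variants with 50 individuals per population, dating at 20,000
variants with 100 target individuals (3–5 replicate seeds per planted date),
supervised-ancestry recovery at 10,000 variants, and the end-to-end pipeline
toy at 1,500 variants — sizes chosen so the full battery completes in a few
minutes on one CPU while leaving each statistic comfortably powered. Every
stochastic stage takes an explicit seed; rerunning any pipeline config
produces byte-identical tables.
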