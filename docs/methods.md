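# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic data does and does not emulate, and
the numerical conventions. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Genotype-likelihood model

All analyses start from per-site, per-individual likelihood triplets
L(g) = P(reads | g) for the three diploid genotypes at a biallelic site.
With a single error rate ε per read base, a read matches a homozygote's
allele with probability 1 − ε and is any specific other base with
probability ε/3; a heterozygote mixes its two alleles with weight ½ each.
Likelihoods are products over reads, so only base counts matter, and reads
of third/fourth bases multiply all three genotypes equally (they cancel
after normalization but are included so unnormalized values match the
direct product). Triplets are stored normalized to max 1; a zero-depth
site-individual is the uninformative triplet (1, 1, 1), which is also the
missing-data encoding — every algorithm treats flat triplets as "no
information" without special-casing. ε is bounded to [0, 0.25): beyond
that a "match" would be less likely than a specific mismatch and the
model's orientation breaks down. ε = 0 is allowed (exact zeros in the
triplets) using the 0·log 0 = 0 convention.

## Allele frequencies, SNP discovery and filters

Per-site frequencies come from the standard EM fixed point
f ← (1/2N)·Σᵢ E[gᵢ | Lᵢ, f] under a Hardy–Weinberg prior
((1−f)², 2f(1−f), f²), initialized at the naive normalized-triplet dosage
mean, converged at |Δf| < 1e-8 or 200 iterations. Individuals with no data
contribute exactly f to the mean, so they do not move the estimate. The
SNP statistic is Λ = 2[ℓ(f̂) − ℓ(0)] referred to χ² with 1 df. The 1-df
reference (rather than the ½χ²₀ + ½χ²₁ boundary mixture) matches common
practice in genotype-likelihood pipelines and is conservative at the
boundary; the type-I test in the suite confirms the empirical rejection
rate does not exceed nominal meaningfully.

The discovery filter stack is applied in a fixed order — total depth
minimum, total depth maximum, MAF, SNP p-value, triallelic — and the
filter report attributes each removed site to the first rule it fails.
Depth bounds are absolute read totals; with N individuals at ~1–2×, the
defaults are min = N and max = 2N (the per-study totals scale with panel
size, so they are parameters, not constants). An individual's reads count
toward the total only if its depth reaches `min_ind_depth` (default 1).
Triallelic detection estimates four allele frequencies by a read-level EM
(reads drawn from allele a with frequency φ_a, observed through the ε
error channel) on counts pooled across individuals; a site is purged when
the third-largest φ exceeds 0.05.

## Linkage disequilibrium

Two-locus haplotype frequencies (h_AB, h_Ab, h_aB, h_ab) are estimated by
EM treating each individual's two haplotypes as independent draws (random
mating) and summing the posterior over the 16 ordered haplotype pairs
weighted by the product of the two sites' likelihood triplets. D, D′ and
r² follow from the converged frequencies; monomorphic sites give NaN r²
with no exception. Pruning builds a graph over sites with edges where
r² > threshold within a distance window and repeatedly deletes the
highest-degree node; ties break by larger r²-weighted degree, then larger
position, so the kept set is reproducible. The default threshold 0.5 and
the 100-kb window are exposed parameters. Only within-chromosome pairs are
considered.

## PCA, admixture, selection scan

The covariance between individuals i and j is
(1/S)·Σ_s (E[g_is] − 2f̂_s)(E[g_js] − 2f̂_s) / (2f̂_s(1 − f̂_s)), with E[g]
the posterior-mean genotype (dosage) at the site's global EM frequency.
This is the single-pass variant: no iterated individual allele
frequencies. It is the main simplification relative to iterative
covariance estimators and is accurate when structure is moderate; the
suite verifies deme recovery at FST = 0.1. Monomorphic sites are skipped
with a warning; individuals with no data shrink to the prior mean and land
near the origin (warned).

Admixture uses the likelihood Πᵢ Π_s Σ_g L(g)·Binom(g; 2, π_is) with
π_is = Σ_k q_ik f_ks. The EM attributes expected derived/ancestral allele
copies to components (the usual block update), which keeps Q rows exactly
on the simplex and the log-likelihood non-decreasing. Each seeded run
stops when the per-iteration log-likelihood gain drops below 1e-4 units or
at 2000 iterations; the run is declared converged when the best and
third-best of ≥ 3 seeds agree within two log-likelihood units, and the
best seed is returned. Label switching across seeds is resolved by greedy
column correlation against the best seed (`align_admixture`).

The selection scan statistic for site s and axis k is
N·r²(standardized dosage, axis-k scores), referred to χ²₁, with
Benjamini–Hochberg q-values appended (the multiple-testing rule is a
package choice). Dosages are recomputed from the panel passed to the scan,
so the axis may come from a different (e.g. LD-pruned or held-out) panel.
The χ²₁ calibration is exact only for sites that did not shape the axis:
an axis fitted on the tested sites absorbs part of their noise and
inflates the mean statistic by a few percent at S/N ratios of ~100. The
acceptance calibration therefore fits the axis on one half of the sites
and scans the other half.

The missingness diagnostic regresses each axis's scores on per-individual
missing fraction (OLS) and reports R² and slope p-value; constant
missingness yields R² = 0 by convention.

## SAF, SFS and θ statistics

The deme-level SAF vector P(data | j minor copies among 2n) is the
polynomial product Πᵢ [Lᵢ(0) + 2Lᵢ(1)x + Lᵢ(2)x²] divided by C(2n, j),
computed by an in-place convolution with per-site rescaling for numerical
range. Missing individuals contribute the flat factor (1 + x)², i.e. a
binomial smearing that adds no information. The SFS EM is the classic
mixture update φ_j ← mean posterior, converged at max|Δφ| < 1e-8 or 500
iterations; the 2-D version uses the outer product of two SAF vectors.
Spectra are reported as expected site counts (φ times sites).

A caution established while validating: the unpenalized maximum-likelihood
spectrum is locally jagged when per-site information is limited (e.g. 4×
coverage of 10 diploids) — a generic property of ML mixing-distribution
estimates, not an implementation fault (the EM's likelihood exceeds the
true spectrum's). Recovery tests therefore measure total-variation
distance and shape correlation rather than per-bin χ² fit. Downstream θ
statistics are insensitive to the jaggedness because they are smooth
linear functionals of the spectrum.

θ_W = S/a₁, π = Σ i(2n−i)·sfs_i / C(2n, 2), and Tajima's D uses the
standard constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂) with the number of
sequences equal to 2 × diploids. Both S and the π weights are symmetric
under folding, so folded and unfolded representations agree; all analyses
use major/minor polarization and never assume ancestral states. Per-site
values divide by the total sites in the spectrum (bin 0 included).
Individual heterozygosity is the 3-bin SFS of a single diploid:
100 · het / total.

## FST and relatedness

The weighted FST is the Hudson/Bhatia ratio-of-sums estimator:
α_s = (p̂₁ − p̂₂)² − p̂₁(1−p̂₁)/(n₁−1) − p̂₂(1−p̂₂)/(n₂−1) and
β_s = p̂₁(1−p̂₂) + p̂₂(1−p̂₁), summed before dividing. The (n−1)
denominators use haploid sample sizes (2 × diploids), which makes α
unbiased for binomially sampled alleles. Frequencies are either plug-in
per-deme EM estimates (fast mode) or posterior means of allele counts
under the 2-D SFS prior (posterior mode); the two agree on high-certainty
data. Windows are fixed, non-overlapping, anchored at position 1, 1-based
inclusive, default 15 kb; empty windows are emitted with NaN. This
estimator is the recommended choice for unequal sample sizes; Nei's
(H_T − H_S)/H_T variant is provided separately in the SV module where the
inputs are arrangement frequencies rather than read data.

Relatedness is a three-state IBD-proportion EM: per site the pair
likelihood Σ_{g₁,g₂} L₁(g₁)L₂(g₂)·P(g₁, g₂ | IBD = m, f) with the standard
state tables, posterior-averaged to update (k₀, k₁, k₂) on the simplex;
r = k₂ + k₁/2. This is the generic genotype-likelihood IBD formulation;
whether the Hedrick–Lacy weighting of identity coefficients differs
materially from r = k₂ + k₁/2 on diploid biallelic data is left open and
not asserted.

## Geographic distance and Mantel tests

Distances are great-circle (haversine, Earth radius 6371 km) — not
least-cost-over-water paths, a known simplification for enclosed seas
where sea routes exceed great circles. GD = FST/(1 − FST) elementwise with
FST = 1 flagged NaN. The Mantel test correlates upper triangles and
permutes rows/columns of one matrix simultaneously; it is one-sided
(positive association), p = (1 + #{r_perm ≥ r_obs})/(n_perm + 1), default
n_perm = 9999. Permutations are drawn uniformly with the identity redrawn,
so the self-test p equals 1/(n_perm + 1) exactly.

## Local-PCA SV scan and genotyping

Windows hold a fixed number of SNPs (trailing short windows are flagged);
each window's structure is summarized by its top-k (default 2) PCA score
map. The dissimilarity between windows is 1 − (1/k)·Σ ρ_c², the mean
squared canonical correlation between the two score subspaces — symmetric,
in [0, 1], and invariant to sign flips and rotations of the window PCs.
(The normalization by k keeps the measure in [0, 1] for k > 1.) Classical
MDS embeds the windows; per axis, windows beyond z_cut (default 4) robust
standard deviations (1.4826·MAD) from the median are outliers, and runs of
at least min_run (default 3) consecutive outlier windows on the same
chromosome and the same side of the median merge into a candidate region
spanning the first window's first SNP to the last window's last SNP. The
cutoffs are exposed and recorded; breakpoints are limited to window-SNP
resolution by construction.

Genotyping clusters PC1 of the region's SNPs with 1-D k-means (k = 3,
centers seeded at min/median/max — deterministic). Clusters are ordered by
center; the middle cluster is the heterozygote; the α (more diverse)
arrangement is the homozygote cluster with the larger PC2 variance.
Genotyping is refused, with a diagnostic, when consecutive clusters are
not separated by an empty PC1 margin of at least 15% of the PC1 range — a
unimodal cloud split by k-means has near-touching boundaries, so this
rejects regions without three-cluster geometry (e.g. arrangement-
monomorphic samples). The exact Hardy–Weinberg test enumerates all
heterozygote counts compatible with the allele totals and sums
probabilities ≤ the observed one (no mid-p correction); probabilities are
computed in log space and normalized, which matches exact integer
enumeration to 1e-9 relative error for all n ≤ 50.

## Mitochondrial module

Consensus calling is per position: depth ≥ 4 and major-allele frequency
≥ 0.75, both inclusive; ties for the major allele give N (the tie count is
reported per sequence). Pairwise distances count differences over
positions where both bases are called, with the comparable-site count
reported alongside. The haplotype network collapses identical sequences
into weighted nodes and keeps every edge that belongs to some minimum
spanning tree (Kruskal processed by weight class), a minimum spanning
network; with clade labels, the clade separation is the minimum
inter-clade edge weight, and the raw consensus distances are available for
the same comparison. The minimum spanning network replaces heavier
tight-span constructions: it preserves the clade topology and inter-clade
edge weights that matter here at far lower implementation risk.

## The synthetic-data generator

Site positions are uniform without replacement on the chromosome;
ancestral frequencies are uniform on [0.05, 0.95] (every simulated site is
ancestrally polymorphic — diversity per simulated site is therefore far
above genome-wide per-bp values, which is intended: the generator emulates
a discovered SNP panel, not raw sequence). Deme frequencies follow the
Balding–Nichols beta law with parameter `fst_drift`; when
`migration_decay` > 0, a Gaussian copula imposes correlation
exp(−distance/`migration_decay`) between demes on a 1-D lattice while
preserving the beta marginals — adjacent demes are similar, distant demes
approach the independent-drift contrast, which is what produces the
isolation-by-distance signal. Genotypes are Hardy–Weinberg within demes.

Inversions are modelled as two haplotype-class frequency profiles with no
recombination between classes: per inversion site, |p_α − p_β| equals the
configured divergence d exactly (the common centre is uniform, the sign
random). Each individual draws arrangement copies from its deme's α
frequency and then haplotypes from the matching class profiles. The two
classes are statistically exchangeable, so the α/β labelling recovered by
PC2 diversity is arbitrary on these data; accuracy comparisons allow the
label swap. Reads are simulated per site: Poisson depth, a uniformly
chosen chromosome per read, error ε uniform over the three other bases —
no alignment stage, no base-quality variation, no batch effects, no
indels, no selection. Consequences: passing tests demonstrate estimator
correctness under the stated sampling models, not robustness to mapping
artefacts or quality heterogeneity.

The mitochondrial simulator writes two clade consensus sequences differing
at exactly `mito_clade_separation` positions, assigns individuals to
clades, adds private mutations at a configurable rate, and emits
fixed-depth base counts by default (Poisson optionally) so that full-depth
round trips are exact.

A separate generator draws independent segregating sites with derived
allele counts proportional to 1/i — the constant-size neutral expectation —
for calibrating Tajima's D and SFS recovery without coalescent machinery;
it has no linkage, so variance across replicates is smaller than a
coalescent would give, which is appropriate for mean-calibration checks.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed or Generator; identical
configs give bit-identical outputs. The validation suite uses scaled-down
problem sizes chosen so each check still has the power to detect the
failure it targets: 500 replicate sites for frequency recovery at 2×,
20,000 sites for FST recovery (binomial SE ≈ 0.003 on FST 0.1), a 10-Mb
chromosome with 20,000 sites and 250-SNP windows for the SV chain
(breakpoint resolution ~125 kb against a 3-Mb truth), 50,000 sites for
Tajima's D (SE well under the ±0.15 tolerance), and 2,000 replicates for
exact-test calibration.
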