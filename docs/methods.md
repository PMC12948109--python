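# Methods

`hegcor` estimates narrow-sense heritability (h²) and genetic correlations
(r_g) for complex traits measured across independent cohorts of a
multiparental outbred population (the motivating system is Diversity
Outbred mice, whose per-locus ancestry is expressed as 8-state founder
probabilities), then uses the resulting correlation atlas to build
meta-traits and map them with permutation-calibrated additive genome scans.
This note records the model, the numerical choices, and what the synthetic
data used by the test suite does and does not emulate.

## Haseman-Elston regression

For z-normalized traits M and N, the phenotypic-similarity score of a pair
of individuals (i, j) is the product M_i × N_j, regressed on the pair's
kinship r_ij:

    M_i × N_j = α + β r_ij + e

Kinship is the probability that an allele drawn from i matches one drawn
from j: from founder probabilities, K_ij = mean_m Σ_f p_imf p_jmf; from
biallelic dosages, the standardized cross-product Z Z′ / (2M) (the division
by 2 converts a genotype-correlation scale to an allele-sampling
probability, appropriate for a highly heterozygous outbred population).

Because traits are z-scored, the slope converts directly: h² = β/2 for a
trait against itself, and the cross-trait slope gives the genetic
covariance ρ = β/2 with

    r_g = ρ / (h_M h_N),  h_M = √(h²_M).

r_g is only estimable when both h² estimates are positive; the code returns
an explicit "not estimable" result rather than NaN in that case.

**Pair construction.** For same-trait/same-cohort h², pairs are the
unordered distinct pairs i < j — the diagonal of the outer product is not a
pair of individuals. For two traits on overlapping cohorts, each unordered
pair {i, j} contributes the symmetrized response (M_i N_j + M_j N_i)/2,
which makes r_g symmetric in its arguments; animals present in only one
cohort contribute single cross-products, and self-pairs (the same animal on
both sides) are dropped. Pairs containing a missing value are dropped
before the regression.

**Standard errors.** The raw SE is Fisher's regression-coefficient formula
with S_ε = √(Σê²/(n_pairs − 2)); p-values are two-sided t tests with
df = n_pairs − 2. Pairwise products are not independent, so both are
anti-conservative — increasingly so as h² and the cohort size grow. That
bias is exactly what the correction factor (next section) repairs at the SE
level; the p-values are reported as-is and should be read with that caveat.

## The SE correction factor

Calibration is assessed by a split-half experiment: simulate a cohort,
split it at random into two halves, estimate h² independently in each, and
form the standardized difference

    Δnorm = (h²₁ − h²₂) / √(σ²₁ + σ²₂).

If the SEs are calibrated, the SD of Δnorm over replicates (σ_Δnorm) is
approximately 1. With raw Fisher SEs, σ_Δnorm grows above 1 with h² and
with √n. The empirical correction factor

    F(h², n) = √n (0.020225 h² + 0.004225) + (−0.2352 h² + 0.9467)

multiplies the raw SE (SE_corrected = SE × F). F is evaluated at the
clipped point estimate of h² and at the number of **animals** n (not
pairs): the calibration regressions are parameterized by population size.
`derive_correction_coefficients` re-derives the four coefficients from any
σ_Δnorm table by the same two-stage OLS that produced them (per-h² fits of
σ on √n, then fits of those intercepts/slopes on h²); on a noiseless table
generated from the printed coefficients the round trip is exact to < 1e-8.

For the cross-trait slope, F needs an "h²-like" argument; we evaluate it at
|ρ| (clipped to [0, 1]) with n the smaller of the two cohort sizes. The
propagated SE of r_g is the delta-method form

    SE(r_g) = |r_g| √( (SE(ρ)/ρ)² + (SE(h²_M)/(2h²_M))² + (SE(h²_N)/(2h²_N))² ),

with the raw relative-variance sum kept on the result object for audit.

**Filters.** Traits are kept when h² ≥ 0.10 and h² ≤ 1 + SE; genetic
correlations are valid when −1 − SE ≤ r_g ≤ 1 + SE. Both rules use the
corrected SEs.

## Phenotype preparation

Per trait: values more than 5 SD from the mean are set missing in a single
pass (moments are not recomputed after exclusion); the trait is then
OLS-adjusted for age (days, numeric) plus sex, generation wave and
diet/treatment (indicator-coded; diet may instead be declared numeric, e.g.
days on a high-fat diet); residuals are z-scored with the sample (n−1) SD.
Single-level factors are dropped from the design; a rank-deficient design
raises an error naming the collinear columns. Individuals missing a
covariate are set missing for that trait. z-scoring is done within the
analyzed stratum, so diet-specific phenotypes are prepared separately from
aggregate ones.

## The r_pg atlas, clustering and meta-traits

Individual r_g estimates are noisy; the Pearson genetic correlation r_pg of
two traits correlates their z-scored vectors of r_g values across the whole
atlas. Each vector is z-scored over its finite, filter-passing entries; for
a pair (a, b) the entries involving a or b are dropped (standard practice
for correlation-of-correlations) and cells with fewer than 3 shared entries
are masked. Because positive and negative r_pg equally indicate shared
genetics, clustering uses

    d = √(2 n (1 − |r_pg|)),

the non-negative algebraic equivalent of √(−2n(|r_pg|−1)), with n the
number of shared r_g observations. Trees are built with the Ward-D2 update
(scipy's `linkage(method="ward")` on the precomputed condensed distances).

A cluster's meta-trait is the per-animal mean of its members' z-scored
values, sign-aligned first: the member with the highest h² is the focal
trait and members with negative r_pg against it are flipped. The mean is
re-z-scored so that h² = β/2 remains valid downstream; animals with no
member measurements stay missing. The cut level k is chosen to maximize the
mean heritability ratio

    h²_ratio = h²_meta / (0.5 (h²_sub1 + h²_sub2)),

where sub1/sub2 are the meta-traits of the cluster's two child
sub-dendrograms. Singleton clusters have no children and are skipped at
that k (logged); ties in the argmax go to the smaller k.

**A caveat on the ratio criterion.** For a panel of exchangeable traits
measured on the *same* animals with independent noise, the ratio rewards
any cohesive split: a pair-cluster gains more h² relative to its singleton
children (ratio ≈ h²_meta(2)/h² > both) than an intact block of five gains
over its two sub-clusters. The mean-ratio curve therefore keeps rising past
the true block count and the argmax drifts toward fine fragmentation. On
heterogeneous real data — where members of a candidate cluster are often
measured on partially disjoint animals, so averaging does not cancel noise
within an animal — the criterion is informative; on exchangeable synthetic
blocks it recovers the block *membership* (cutting at the true count
separates blocks exactly, and merging unrelated blocks is penalized) but
not reliably the block *count*. The test suite asserts exactly those two
properties, and the acceptance suite reports the block-count recovery rate
as measured.

## Genome scans

Meta-traits are scanned by Haley-Knott regression on the founder-probability
columns plus an intercept,

    LOD = (n/2) log10(RSS₀ / RSS₁),

with RSS₀ from the intercept-only model. The founder columns sum to one, so
the design is collinear with the intercept; least squares via an orthonormal
basis (equivalently, a pseudo-inverse) resolves this, and the LOD is
invariant to the choice of generalized inverse. The reference analysis uses
a kinship mixed model; on unlinked synthetic markers the kinship correction
is second-order, and the default scan here is the fixed-effect version
(testable to 1e-8 against a two-model OLS oracle). A kinship-corrected
variant — GLS whitening of phenotype and design by the eigendecomposition
of K + I — is available via the `kinship=` argument for parity checks.
The X chromosome is treated like an autosome.

Significance uses unrestricted permutations: the phenotype is shuffled
across all individuals, the genome rescanned, and the 95th percentile of
the per-permutation maximum LOD taken as the α = 0.05 threshold (1,000
permutations by default). The same permuted scans yield an FDR curve over a
LOD grid: at threshold t, with T observed peaks and F_p permuted peaks,
FDR(t) = mean_p[F_p/(F_p + T)] (0/0 → 0), regularized to be non-increasing
in t by a running maximum over decreasing t (raw values retained). Both the
expected number of false discoveries (FDR·T) and of true discoveries
((1−FDR)·T) are reported with explicit labels.

Peaks are called per chromosome above a threshold with drop = 2 /
peakdrop = 3 geometry: two local maxima are distinct peaks only if the
profile between them dips by at least peakdrop below the lower of the two;
the 2-LOD support interval is the contiguous span around the peak with
LOD ≥ peak − 2, truncated at chromosome ends. Variance explained is
1 − 10^(−(2/n)LOD). Founder effects at a locus are shrunken BLUP-style
under a single variance-component model (y = μ + Xa + e, a ~ N(0, σ²_a I)),
with the variance ratio chosen by a bounded 1-D maximum-likelihood search;
effects are reported as centered deviations with conditional-posterior SEs,
falling back to fixed-effect estimates (with a warning) if the optimizer
fails. Cross-locus founder-effect similarity is the Pearson correlation of
the two 8-vectors with a t test on founders − 2 degrees of freedom.

## Synthetic data

The generator emulates the statistical structure of the reference
simulation design: 1,000 unlinked diploid SNPs per cohort with minor allele
frequencies drawn from {0.05, 0.1, 0.3, 0.4}; 10 causal markers per trait
with i.i.d. normal effects on standardized dosages ((x − 2p)/√(2p(1−p)),
standardized at the seeded p for determinism); independent Gaussian noise
scaled so the realized variance split matches the target h² in-sample
(this keeps small-cohort ground truth tight — the alternative, theoretical
calibration, leaves the realized h² of each replicate noisy). Pleiotropic
pairs share one causal set with bivariate-normal effect pairs at the target
correlation; block panels extend this to several traits per shared signal.
Founder-haplotype probabilities are simulated as two uniform, independent
founder draws per individual per marker. Everything is reproducible bitwise
under a fixed seed.

Not emulated: linkage disequilibrium, realistic breeding pedigrees and the
resulting kinship structure, genotyping-array error modes, and
non-Gaussian trait distributions. Passing tests therefore demonstrate the
estimators' behavior under the idealized architecture they were calibrated
on, not robustness to those real-data features.

## Problem sizes used by the test and acceptance suites

Split-half SE calibration uses 500 replicates at h² = 0.4 with n = 1,000
per half (corrected SEs) and 40 replicates at h² = 0.8, n = 5,000 (raw
SEs, where the miscalibration is large: F ≈ 2.2). Parameter recovery runs
200 replicates per (h², n) cell over h² ∈ {0.1, 0.4, 0.8} × n ∈ {500,
2,000}, and 100 replicates for r_g at a target of 0.5 with 100 shared
causal loci — enough loci that the realized genetic correlation
concentrates on the target, so the check isolates estimator bias rather
than generator sampling. Scan type-I calibration uses 100 null cohorts of
200 animals × 200 pseudomarkers with 200 permutations each. The planted
clustering panel is 4 blocks × 5 traits at n = 500 with within-block
r_g = 0.9.

## Known limitations

* HE h² estimates carry a small O(1/n) attenuation (≈ −0.006 at n = 500,
  ≈ −0.002 at n = 2,000 at h² = 0.4), intrinsic to product regression with
  in-sample z-scoring; it is well inside sampling noise at the cohort sizes
  the method targets.
* p-values for slopes ignore pair non-independence (see above); rely on the
  corrected SEs, or on permutations for genome scans.
* The h²-ratio sweep does not identify the number of clusters on
  exchangeable same-cohort panels (see the caveat above).
* Founder-probability interpolation is linear per founder with
  end-clamping and renormalization — the simplest rule that preserves the
  probability simplex; no genetic-map-aware interpolation is attempted.
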