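# Methods

This note documents the models implemented in `drygene`, the defaults
they ship with, and the choices made where the underlying procedures
admit more than one reasonable implementation.

## Habitat drought indices

Thornthwaite's classic PET model is driven entirely by monthly mean air
temperature and day length:

* heat index `I = Σ_j (T_j/5)^1.514` over months with `T_j > 0`; an
  all-freezing year gives `I = 0` and zero PET everywhere;
* exponent `a = 6.75e-7·I³ − 7.71e-5·I² + 1.792e-2·I + 0.49239`;
* day length from the Forsythe model: the solar term
  `A_j = asin(0.39795·cos(0.2163108 + 2·atan(0.9671396·tan(0.00860·(J−186)))))`
  is evaluated at the ordinal day `J` of the 15th of each month on a
  fixed non-leap calendar (Jan 15 = 15 … Dec 15 = 349), and
  `D_j = 24 − (24/π)·acos[(sin 0.8333° + sin φ sin A_j)/(cos φ cos A_j)]`
  with the 0.8333° sun-altitude correction.  The arccos argument is
  clamped to [−1, 1] so polar day and polar night return 24 h and 0 h;
  the study region (22–32° N) never triggers the clamp;
* `PET_j = 1.6·(D_j/12)·(10·T_j/I)^a` cm/month for `T_j > 0`, else 0.

PET is converted to mm/month (×10) before the drought index so that it
shares units with WorldClim-style precipitation totals; the index is a
ratio, so only unit consistency matters.  `DI_j = 100·(PET_j − P_j)/PET_j`
is bounded above by 100 (rainless month) and unbounded below.  Months
with `PET_j = 0` are assigned `DI_j = 0` — no evaporative demand means
no drought stress — and each such month is logged, since the ratio is
undefined there.

Aggregates are plain means of `DI_j` over a window.  The accumulated
windows (m3, m6, m12) are anchored at January by default with a
configurable anchor month, because a 3- or 6-month "accumulated" period
does not pin down which months it covers; the trimesters T1–T4 are the
fixed calendar quarters.  Scaling uses the sample (n−1) standard
deviation; raw columns are always kept alongside the z-scores because
it is ambiguous which of the two a downstream consumer wants.

Group comparisons screen each taxon with Shapiro–Wilk at α = 0.05
(groups with n < 3 or zero variance are untestable and routed to the
nonparametric branch): all-normal groups get one-way ANOVA with Tukey
HSD, anything else gets Kruskal–Wallis with pairwise Wilcoxon rank-sum
tests under Bonferroni.  Groups with fewer than two members are dropped
with a warning.

## Variants and diversity

Accessions contribute one Sanger haplotype per gene (tepary bean is
autogamous), so genotypes are haploid 0/1 and H_e = 1 − Σp² is the
Hardy–Weinberg expectation implied by the allele frequencies, the DnaSP
convention.  The caller keeps biallelic A/C/G/T columns, treats gaps,
Ns and ambiguity codes as missing, drops columns whose missing fraction
exceeds 0.5 (configurable) and breaks exact frequency ties
alphabetically.  The maf filter is inclusive (≥ 0.05) so that sites
observed at exactly the threshold frequency survive; common-bean
sequencing controls (taxon `control`) are excluded from frequency
computations by default.

π uses pairwise deletion with a per-pair effective length (a
complete-deletion mode is available by flag); θ_W = S/(a₁L); Tajima's D
uses the 1989 constants and is reported as missing (NaN), never 0, when
S = 0 or n < 4.  Per-taxon summaries recount segregating sites within
the taxon without a frequency filter, while the pooled "All" row applies
the maf ≥ 0.05 filter so that its S matches the reported SNP panel;
taxa with fewer than 4 sequences are skipped as unreliable.

## Structure

Per-SNP differentiation uses Hudson's estimator
`Fst = 1 − H_w/H_b`, with the within-taxon heterozygosity corrected by
n/(n−1) and `H_b = p₁(1−p₂) + p₂(1−p₁)`.  The sample-size correction
makes the raw estimate slightly negative when the two sample
frequencies coincide; reports floor at 0 and keep the raw value.  The
estimator is isolated in one function so Weir–Cockerham could be
swapped in.

PCA mean-centers the genotype matrix (missing imputed to the column
mean) and takes the SVD.  IBS kinship is the fraction of co-called SNPs
with identical alleles; a pair sharing no called SNP is an error rather
than a silent missing entry.  Neighbor joining (scikit-bio) runs on
p-distances with pairwise deletion (Jukes–Cantor by flag); negative
branch lengths are floored at 0, and bootstrap support resamples
alignment columns with replacement, scoring each internal bipartition
of the point-estimate tree.

The median-joining network is implemented here because no installed
package provides it.  Haplotypes are collapsed over the columns with no
missing calls; the network starts from the minimum-spanning network
(tolerance ε, default 0) and repeatedly adds the quasi-median
(per-site majority consensus, branching when all three states differ)
of a connected triplet whenever that strictly reduces the total
spanning length, then prunes inferred nodes whose removal costs
nothing.  Note that adding a median can legitimately *replace*
observed-to-observed MSN edges by shorter paths through the median (the
three-haplotype star is the minimal example), so the final network is
the MSN over observed-plus-inferred nodes, not a supergraph of the
observed-only MSN.

## Association scans

The environmental index is the response and the SNP a predictor, the
convention of loading the index as the phenotype in standard GWAS
tools.  GLM is OLS of the index on the marker plus the first k = 2
principal components, with per-SNP removal of missing individuals.

MLM is the single-random-effect model
`y = gβ + PCγ + u + e, u ~ N(0, σ_g²K)`, fitted EMMA-style: one
spectral decomposition of K per scan, REML maximization of the variance
ratio δ = σ_e²/σ_g² on a log-grid with bounded refinement, and the
fitted δ from the *null* (no-marker) model reused for every marker
(P3D), with Wald t-tests on n − p degrees of freedom.  Non-PSD kinship
(IBS similarity matrices routinely have small negative eigenvalues) is
bent by flooring eigenvalues at 1e−6 with a warning.  Missing genotypes
are imputed to the column mean here (unlike GLM) so the single
decomposition remains valid for all markers.  At K = I the scan
collapses exactly onto GLM.

CMLM clusters individuals by average linkage on 1 − K, sweeps group
counts {1, ⌈n/8⌉, ⌈n/4⌉, ⌈n/2⌉, n} (configurable), sets the group
kinship to the mean pairwise K between groups, picks the count with the
best null REML likelihood, and runs the marker tests on the compressed
covariance.  Group count n reproduces MLM exactly.

The haplotype-level scan enters the haplotype class as a multi-level
fixed factor (classes with fewer than 2 carriers pooled into "other")
and reports the GLS omnibus F-test; with exactly two classes it reduces
to the marker MLM.  Significance is flagged at p < 0.05 and p ≤ 0.01;
the stricter inclusive cutoff stands in for FDR control in a small
a-priori candidate panel, rather than a Benjamini–Hochberg step.

## Synthetic data

The generator emulates the study panel: 52 haplotypes in four taxa
(23 wild + 6 cultivated *P. acutifolius*, 4 var. *tenuifolius*, 19
*P. parvifolius*), amplicon lengths of a few hundred bp, and θ = 5 per
locus by default.  Neutral alignments come from a standard n-coalescent
(exponential waiting times, uniform pair merges) with infinite-sites
mutation at rate θ/2 per lineage; `E[S] = θ·a₁` is the analytic check.
Structured mode converts each variant site, with probability
`divergence`, into a fixed difference between one random taxon and the
rest — a deliberately crude but verifiable way to reach any F_ST level
including 1.  Climate series use a cosine seasonal temperature cycle
(24 ± 8 °C peaking in July), gamma monthly precipitation with an arid
scale (~20 mm/month, wetter summers) and latitudes in 22–32° N — values
chosen once to represent Sonoran collection sites.  Coupled datasets
add `β·genotype + taxon effect + noise` to form the index and store the
truth for recovery tests.

The frequency-exact fixtures rebuild each published gene panel at
n = 100, where two-decimal frequencies are integral counts; the minor
allele goes to ⌈freq·n⌉ sequences drawn independently per site, because
haplotype phase is not recoverable from a frequency table.  Two
consequences: linkage between fixture sites is random (so
haplotype-level tests use the coalescent generator instead), and in the
few rows where the published major and minor frequencies sum to 1.01
(printed rounding) the minor frequency is reproduced exactly and the
major is its complement.  Passing fixture tests therefore demonstrates
frequency bookkeeping, not haplotype structure, and the synthetic
climates demonstrate the index pipeline, not WorldClim extraction
(rasters are out of scope; input is a generic CSV).

## Problem sizes and numerical choices

Calibration suites run at sizes chosen to give tight Monte-Carlo error
while staying desk-scale: 500 coalescent replicates (n = 20, θ = 5) for
the Tajima's D and θ-estimator checks (mean D within ±0.3; both
estimators within 15% relative bias), 1000 replicates for GLM and MLM
type-I error (band: two binomial standard errors around α = 0.05), 200
replicates for MLM power (> 80% at p ≤ 0.01 for a marker explaining 30%
of variance at n = 50).  δ is searched on log δ ∈ [−10, 10] with 41
grid points before bounded refinement; eigenvalue floor 1e−6; all
generators are pure functions of their seed.

## Known limitations

* The coalescent generator has no recombination, selection or
  demography; calibration under it shows estimator correctness, not
  robustness to real demographic history.
* Wald/P3D p-values are approximate in small samples; exact per-marker
  REML is deliberately not re-estimated (it is the standard trade-off).
* Fst is per-SNP Hudson only; multi-locus or Weir–Cockerham summaries
  would need the one isolated function replaced.
* Quasi-median enumeration is exponential in the number of three-state
  sites of a triplet; fine for amplicon panels, not for genome-scale
  haplotype sets.
* Coding/non-synonymous annotations are user-supplied; no ORF
  inference is attempted.
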