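# Methods

This note documents the models and estimators implemented in
`holoselect`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical choices a
maintainer would want to know.

## Genotype-likelihood machinery (`genolik`)

All low-coverage analyses work directly on per-site likelihood triplets
over the diploid genotypes {homRef, het, homAlt} of a biallelic site,
max-rescaled so each informative triplet has maximum 1; a flat triplet
encodes missing data and is inert in every likelihood sum.

**Allele frequency.** The alt-allele frequency p̂ maximizes
Σ_samples log Σ_g GL(g)·HWE(g|p) by EM (expected dosage under the
posterior, averaged over samples), iterated to |Δp| < 1e-8 or 100 sweeps.
The EM is vectorized over arbitrary leading axes, which is what makes the
permutation machinery below affordable. A grid-search oracle over 10,001
points is used in the test suite to confirm convergence to the global
maximizer.

**Dosages.** Posterior mean alt-allele count
E[g | GL, p̂] = Σ g·GL(g)HWE(g|p̂) / Σ GL(g)HWE(g|p̂). Missing triplets
collapse to the prior mean 2p̂, so the dosage matrix needs no separate
imputation step before PCA.

**IBS.** Distances use per-sample maximum-likelihood genotype calls
(ties broken to het) and d(i,j) = mean |g_i − g_j|/2 over co-called
sites, then average-linkage clustering. Single-read-sampling IBS (as
implemented in low-coverage toolkits) is approximated by these hard
calls — a documented divergence; the distance still satisfies
identity-of-clones (0) and the triangle inequality, which is what the
clonality/species check uses.

**PCA.** Samples × loci dosages are column-centered (optionally scaled
by √(p̂(1−p̂)); unscaled is the default since there is no principled
reason to prefer either for these data) and decomposed by SVD. PC1 sign
is fixed so its loading sum is ≥ 0. Per-ontology PC1 summaries reuse the
same routine on a locus subset; a zero-variance subset is an error that
names the subset.

## Association scans (`assoc`)

**Binary.** Per locus, LRT = 2[ℓ(p̂_case) + ℓ(p̂_ctrl) − ℓ(p̂_pooled)]
on the GL-marginal likelihood under HWE, 1 df, clamped at 0; invariant
under swapping the two labels. Filters: a polymorphism LRT
(free p̂ vs the better of p = 0 and p = 1) must reach p < 2e-6, and both
groups need ≥ 5 informative (non-missing) samples. Since genotype
likelihoods carry no read depths, the minimum-depth idea is interpreted
as minimum informative samples — a documented divergence.

**Continuous.** The symbiont proportion is clamped to
[1e-3, 1 − 1e-3], logit-transformed and regressed on dosage;
LRT = n·log(RSS₀/RSS₁), beta = slope. This is a deliberate, simpler
stand-in for the latent-genotype score test of low-coverage association
tools: identical null behavior (χ²₁, verified by QQ calibration in the
tests), transparent effect sizes. Filters mirror the score-test ones:
≥ 3 samples with dosage ≥ 0.9 ("confidently non-reference") and ≥ 3
minor-allele carriers (dosage past 0.5 on the minor side).

**Max-statistic permutation threshold.** Trait labels are permuted
n_perm times (default 10,000); the full per-locus scan is recomputed per
permutation and its maximum statistic kept; the genome-wide cutoff is
the nearest-rank empirical quantile — order statistic ⌈level·n_perm⌉ —
of the maxima (level 0.9999 by default, i.e. the largest maximum at
10,000 permutations). Nearest-rank was chosen because it is
distribution-free and well defined at extreme levels. If n_perm exceeds
the number of distinct binary label assignments C(n, k), all assignments
are enumerated instead (warning emitted). Permutations are sampled
without a uniqueness constraint: at the default design (11 vs 11,
C(22,11) ≈ 7e5) collisions are negligible. The pooled-likelihood term is
label-invariant and computed once; group EMs run batched across
permutations.

The family-wise error of this construction is calibrated by simulation
in the acceptance suite: on null datasets the threshold at level 0.95
with 200 permutations is exceeded by the observed scan in ~5% of
datasets (the observed maximum is exchangeable with the permutation
maxima, so the exact expectation is 11/201 ≈ 0.055; genotype-data ties
push it slightly down).

**Single-locus power ceiling.** With m unlinked equal-effect causal
loci, locus j can explain at most V_j/ΣV of the trait's genetic
variance, and Σ_j R²_j ≤ 1. At 22 colonies this caps the single-locus
LRT near −n·log(1 − 1/m); for m = 5 that is ≈ 5, well below the top-1%
rank threshold of a 2,000-locus scan (~7+). Consequently, ranking 3 of 5
planted loci in the top 1% is not achievable in most seeds at this
sample size under any noise level — the acceptance suite measures and
reports this operating characteristic honestly rather than tuning the
generator around it.

## Pool-seq FST and PBS (`poolsel`)

**Estimator.** Per-site Hudson-type FST with a double sampling
correction:

    h_i = [d_i/(d_i−1)]·[n_i/(n_i−1)]·2p̂_i(1−p̂_i)     (within pool i)
    h_b = p̂_a(1−p̂_b) + p̂_b(1−p̂_a)                     (between)
    FST = (h_b − (h_a + h_b_within)/2) / h_b

with read depth d and haploid pool size n. This is simpler than the full
ANOVA pool-seq estimator but shares its key property: unbiasedness at
zero differentiation (|mean| < 0.01 at depth ≥ 20 over 10,000 loci in
the tests); estimates may be negative and are clamped to [−1, 1]. Sites
with depth < 2 in either pool are missing.

**PBS.** Branch lengths T = −log(1 − FST) with negative FST floored at 0
inside the transform only (raw FST is reported unfloored) and FST capped
at 1 − 1e-6 to keep fixed differences finite;
PBS_A = (T_AB + T_AC − T_BC)/2, symmetric in the outgroups.

**Scan filters.** Retained loci need depth ≥ 10 in all four pools
(parental, initial, final ambient, final heat), both alleles observed
(≥ 1 read each; no count threshold is claimed anywhere, so 1 is the
least-assuming choice) in parental and initial pools, and
FST(initial, parental) < 0.05 — together these rule out heterozygosity
artifacts of the library. The focal branch is the final heat pool; the
initial pool and the final ambient pool are the outgroups, so drift and
batch effects shared by the arms cancel and only heat-specific change
inflates PBS.

## Rank enrichment (`enrich`)

Variants map to every gene whose interval ± 2,500 bp contains them;
per-gene heat defaults to the max over assigned variants (conservative
for "is any variant near this gene hot"; mean is available). Categories
are tested by two-tailed Mann-Whitney U of member vs non-member heats:
exact enumeration when the category has ≤ 8 members and the pooled heats
are tie-free, otherwise the normal approximation with tie-corrected
variance and continuity correction. Delta-rank (mean member rank − mean
rest rank, midranks for ties) is the effect size; BH FDR across tested
categories. Categories below 15 members after intersection with the heat
set, equal to the whole gene set, or duplicating another category's
membership are dropped. Because only ranks enter, results are invariant
to strictly monotone transforms of the heats — so LRT, log-LRT or
percentile heats give identical enrichment. Ontology-graph propagation
(parent-term merging) is intentionally out of scope; a pre-expanded
gene→ancestor map can be supplied as the category input.

## qPCR symbiont proportions (`qpcr`)

Technical duplicates per (sample, assay) pass QC unless the CT standard
deviation exceeds 1 cycle (FAIL_SD) or only a single replicate amplified
(FAIL_SINGLE); zero amplified replicates is ABSENT — a legitimate
biological zero (heat-sensitive larvae typically carry no *Durusdinium*
at all), not a failure. Corrected copies are
eff^(−CT + f_X)/c_X with per-assay fluorescence offsets f and per-genus
actin copy numbers c (identity by default — the published correction
constants are configuration, not code) and amplification efficiency 2
(perfect doubling, configurable). Proportion = D/(C + D); only-D → 1,
only-C → 0, neither → missing. Colony means average PASS/ABSENT branch
replicates. The host assay is read and carried but does not enter the
proportion.

## Metabolite modules (`metabmod`)

Missing abundances are imputed with each feature's minimum observed
value, then log2 — the standard treatment when missingness is
left-censoring at the detection limit. Unsigned adjacency |cor|^β;
the soft threshold β is chosen as the smallest power whose
scale-free-topology fit reaches 0.8 *at mean connectivity ≥ 1*: the fit
is the signed R² of log10 density vs log10 mean connectivity over 10
equal-occupancy bins, and the connectivity floor matters because raising
pure noise to a high power yields a sparse heavy-tailed network that
looks deceptively scale-free. Topological overlap
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij) feeds
average-linkage clustering of 1 − TOM with a **static cut** (default
height 0.97) — a deliberate simplification of hybrid dynamic tree
cutting; heights in 0.95–0.98 recover planted modules robustly, while
cutting at 0.99 lets average-linkage chaining through noise features
occasionally fuse modules. Clusters below 25 features are unassigned;
eigen-features are the PC1 of standardized member abundances (oriented
to positive mean kME); features with kME < 0.8 are released and the size
floor re-applied; modules whose eigen-feature correlation dissimilarity
is below 0.15 merge iteratively until stable (idempotent by
construction). Module–trait association is Spearman correlation of
eigen-features against per-sample traits (e.g. per-ontology genotype
PC1) with BH FDR over the full matrix; class composition is tested per
(module, class) with a two-sided Fisher exact test (sample and
conditional-MLE odds ratios reported) and BH FDR.

## Heritability (`herit`)

Broad-sense H² = MS_between/(MS_between + MS_within) from a one-way
ANOVA of replicate survivorship with phenotype as the factor, computed
from replicates or reconstructed exactly from (mean, SE, n) group
summaries (SD = SE·√n; SS_within = Σ(n_g − 1)SD²_g). The mean-square
ratio — not the sum-of-squares ratio — is the definition consistent with
the published worked value this package reproduces (0.963 from
4.9 ± 2.0 vs 24.9 ± 3.4 percent at n = 15). A consequence worth knowing:
under the null of equal group means the MS ratio is F/(F + 1) with 1
numerator df, whose median is ≈ 0.32 and whose single-seed draws are
widely dispersed — "no heritability" manifests as a null-shaped
distribution over replications, not as a value pinned near zero. No
angular or logit transform is applied to the proportions (none is needed
to reproduce the worked value). H² is invariant to affine rescaling of
the response (percent vs proportion).

## Synthetic generator (`simulate`)

The generator emulates the statistical structure of the study design,
with one named RNG child stream per stage (sites, genotypes, symbionts,
liability, pools, qPCR, metabolites, survivorship) derived from a single
root seed — identical (config, seed) is byte-identical output and new
stages never perturb old streams.

* **Population**: 22 colonies, one admixture-free population; biallelic
  unlinked sites at uniform(0.1, 0.5) frequencies; genotypes are HWE
  draws.
* **Symbionts**: logit(proportion *Durusdinium*) = maternal component
  intercept (±1.0, two maternal lines) + 2.0 × centered alt-allele count
  over 5 symbiont-causal loci + N(0, 0.5). The component gap and noise
  place colonies in the C-dominated/D-dominated bimodal regime seen in
  this system while leaving genotype a strong determinant.
* **Phenotype**: liability = causal-genotype term + 2·(proportion − ½) +
  N(0,1), thresholded at the median → two balanced groups of 11
  ("bleached"/"nonbleached").
* **Reads**: adult depth ~ Poisson(30) per site/sample (typical RAD
  coverage), read-level error 1%, likelihood triplets from the binomial
  read model (the same model used for inference — the generator is
  well-specified by construction).
* **Larval pools**: parental frequency = mean of contributing colonies;
  gamete sampling (binomial, 5,000 gametes) into the initial pool; drift
  resampling into the ambient arm; one episode of genic viability
  selection p′ = p(1+s)/(1+sp), s = 0.5 at the phenotype-causal loci,
  before resampling into the heat arm; pool libraries at
  Poisson(600) depth. Pool sizes and depth reflect deep pooled
  resequencing of large larval cultures (thousands of larvae per
  conical; depth well below the pool's chromosome count, the regime
  pool-seq estimators assume). Bulk fertilization is modeled as a single
  gamete cloud — no individual crosses, no selfing exclusion.
* **Assays**: qPCR CT = 22 − log2(copies) + N(0, 0.15) per technical
  replicate, two replicates × three branches, branch-level logit jitter
  0.2; metabolites = 3 planted modules of 30 features (unit loading on a
  module factor, residual SD 0.1 on log2 scale) among 60 noise features,
  with class labels enriched 80% within modules and left-censored
  dropout below each feature's 5% intensity quantile; survivorship =
  Binomial(50, π) per replicate, 15 replicates per phenotype ×
  temperature, π = 0.05/0.25/0.33 (bleached/nonbleached/cross) at high
  temperature and 0.37/0.37/0.40 at ambient (equal pure-phenotype
  ambient survival: the ambient arm shows no phenotype effect).

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: linkage disequilibrium and haplotype
structure (sites are exchangeable), admixture or cryptic population
structure, reference/mapping bias and indel error, overdispersed
(beta-binomial) pool sequencing, symbiont shuffling over time,
batch/plate effects in qPCR and LC-MS, and correlated metabolite noise
beyond the planted factors. Recovery results calibrate the estimators
under their own assumptions; they are not field validation.

## Numerical conventions

EM tolerance 1e-8 (100 sweeps max); logit clamp 1e-3; FST cap 1 − 1e-6;
negative FST floored only inside the PBS log; IBS genotype ties → het;
PC1 loading-sum sign convention; nearest-rank quantiles for permutation
thresholds; midranks for tied heats; RSS floored at 1e-12·SYY in the
regression LRT to keep the perfect-fit limit finite; degenerate ANOVA
(zero between and within variance) yields NaN with a flag rather than an
arbitrary value.

## Problem sizes

The test and acceptance runs use study-scale or moderately reduced
sizes chosen to give stable Monte-Carlo estimates: 500 null datasets of
200 loci for the family-wise-error calibration, 50 seeds of 5,000 loci
for the selection-scan recovery, 50 seeds of 2,000 loci for association
power, 100 sites for the EM/grid agreement, and the full 150-feature
metabolite design.
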