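# Methods

This note documents the models, estimators, defaults and numerical choices
behind the pipeline, and what the synthetic cohort does and does not
emulate.

## Synthetic cohort generator

The generator reproduces the study design as its defaults: 69 mother–fetus
pairs — 35 in population 1 (16 male, 19 female newborns) and 34 in
population 2 (21, 13) — each contributing 7 placental-layer samples
(UC, AN, CN, CP, VF, VI, VM; 483 samples), a 17,284-gene expression
universe, 800 biallelic SNPs, and a 192-gene selection-nominated panel.

**Genotypes.** Alt-allele frequencies are Uniform(0.05, 0.95); mothers are
Hardy–Weinberg draws; each fetus receives one transmitted maternal allele
(fair coin at heterozygous sites) plus one paternal allele drawn from the
population frequency, so Mendelian consistency holds by construction and
informative SNPs (fetus-het/mother-hom and vice versa) arise at realistic
rates (~100 per class per pair at the defaults).

**Allele-specific reads.** Per variant, read depth is Poisson(30) (the
simplest defensible model; the data source does not specify one). Each read
comes from the fetal pool with probability equal to the layer's fetal
fraction f, carries the alt allele according to the originating genotype,
and is miscalled with probability 0.002. At a fetal-specific SNP the
alt-read rate is therefore f/2·(1−e) + (1−f/2)·e. Default layer fractions:
UC 1.0, VF 1.0, AN 0.97, CP 0.97, VI 0.97, VM 0.96, CN 0.30 — fully fetal
cord and fetal villus, maternal-dominant chorion.

**Expression counts.** Gene g, sample j: NB with mean
libsize_j · baseline_g · 2^(x_j β + covariates) and gene-wise dispersion
α_g ~ Gamma(2, 0.05) (mean 0.1, floored at 1e-4). Baselines are
2^N(5, 2); library sizes log-normal (σ = 0.3). The population effect β is
nonzero exactly for the planted effect genes of the sample's layer and
effect class: a "shared" class acting in both sexes concentrated in the
villus layers (VI 300, VF 170, others 8), a "male" class acting only in
male-newborn samples concentrated in UC/AN/VF (400/180/190, others 10),
and a "female" class at one tenth of the male counts (the
`male_bias_factor = 10` regime; both the male-biased and symmetric-null
regimes are generable). Effect sizes are ±|N(1.5, 0.5)| floored at 0.5 in
log2 units. Five per cent of genes carry small maternal-age coefficients
(N(0, 0.05) per age z-score) and five per cent carry fetal-sex effects
(N(0, 0.5)), so the DE covariates matter.

**Modules and traits.** Five planted modules (sizes 100/80/60/50/40) share
per-pair latent factors: member genes add loading·latent to their log2
mean (loadings Uniform(0.3, 0.8)), and the 11 newborn traits are linear in
the latents plus N(0, 0.5) noise on a standardized scale (physical units
are out of scope). Module 1 loads on birth weight (0.6) and placental
volume (0.4); the remaining modules load on amniotic-fluid and growth
traits. Module 1's latent is additionally shifted by +0.8 in population 1,
the generative analogue of a significantly differential module
(population- and trait-associated at once). Traits are correlated with one
another only through shared modules, so the effective number of
independent traits in synthetic cohorts is near the trait count (~10) —
unlike strongly collinear clinical traits, where the same estimator
collapses to small values.

All randomness flows from one seed through named CRC32-keyed substreams;
identical config + seed gives bit-identical cohorts.

## Origin deconvolution

Informative SNPs are classified exactly by the definition (fetal-specific:
fetus het, mother hom — either homozygote, with the specific allele being
whichever the mother lacks; maternal-specific mirrored). Per replicate, 5
covered SNPs (depth ≥ 10) are sampled without replacement from each class;
the allelic ratio pools reads, R = ΣB/(ΣA+ΣB), which is robust to uneven
depth and equals the mean of per-SNP ratios when depth is equal. R_f and
R_m are means of 5 replicates. The fraction conversion inverts the
expectation E[R_f] = f/2(1−2e) + e:  f̂ = clip(2(R_f − e)/(1 − 2e), 0, 1),
which at the default e = 0 is clip(2·R_f, 0, 1); the alternative
normalization R_f/(R_f + R_m) is available (`method="ratio"`). Samples with
fewer than 5 covered SNPs in either class are recorded and skipped. At 50
informative SNPs per class and depth 100 the mean absolute error over the
mixing grid {0, 0.25, 0.5, 0.75, 1} is ~0.015; the clip induces a small
inward bias at the boundaries (pure-fetal samples average ~0.985).

## Differential expression

Size factors are DESeq-style median-of-ratios against the geometric-mean
pseudo-reference, falling back to total-count scaling (warning) when no
gene is expressed in every sample. Genes with mean normalized count < 1
are excluded before testing (NA p, not counted in the BH correction;
threshold configurable). Maternal age is z-scored in the design for
numerical stability; the log2FC sign convention (positive = higher in
population 1) is written into every output header.

The NB GLM is fitted by iteratively reweighted least squares vectorized
across genes (batched p×p solves; ridge 1e-10 on the normal equations for
degenerate genes; linear predictor clipped to ±30). Dispersion is
estimated per gene, without sharing across genes, by **Pearson moment
matching**: solve Σ_j (y−μ)²/(μ + αμ²) = n − p by Newton iteration started
from the plain residual-moment estimate, floored at 1e-8. Weighting the
residuals by the NB variance rather than μ² alone makes the estimate much
less noisy for high-count genes. The population coefficient's Wald
statistic is referred to a **t distribution on n − p degrees of freedom**:
with a few dozen samples and moment-estimated dispersions the normal
reference is anticonservative exactly in the far tail that survives
multiple-testing correction. Measured on null simulations at the cohort's
male-stratum size (16 vs 21), the combination gives a nominal-level
rejection rate of 0.050 and a family-wise error rate of 0.03 at BH 0.05
over 400-gene replicates. No empirical-Bayes shrinkage is applied; this is
deliberately a transparent approximation whose guarantees are the measured
calibration properties, not identity with any published tool's output.

BH adjustment is the standard step-up with monotonicity enforcement,
capped at 1; NaNs pass through and do not count toward the number of
tests. BH is applied per layer × stratum, mirroring per-layer DEG calling.

DEG summaries report layer sharing (per-gene k-layer classes and layer
combinations) with percentages rounded half-up to two decimals — note that
published tallies mix two denominators (distinct genes vs per-layer
occurrences), so both totals are always reported. Direction discordance
counts, among male-stratum DEGs of a layer, the fraction whose
female-stratum log2FC has strictly opposite sign (zero counts as
concordant; genes missing from the female fit are excluded from the
denominator and tallied).

## Co-expression modules

Expression enters as log2(count/size factor + 1) — a variance-stabilizing
approximation chosen over the exact transform for transparency; on NB
simulations it flattens the mean–variance slope, which is the property the
network construction needs. Networks use unsigned adjacency |cor|^β
(signed networks are a config away but not the default, since the analysis
treats anticorrelated genes as connected).

**Soft power.** β is the smallest candidate (1..20) whose scale-free fit
R² ≥ 0.8, where the fit regresses log10 p(k) on log10 k over 10
equal-width degree bins with two guards: bins holding fewer than 5 genes
are dropped (singleton tail bins fake a power law for any right-skewed
degree distribution), and a power is only selectable while mean
connectivity ≥ 1 — raising any correlation matrix to a high enough power
disconnects the network, and past that point i.i.d. noise passes the R²
criterion spuriously at every sample size we tried. If no eligible power
reaches the target the best-fitting power is returned with a warning (the
regime for structureless data, where downstream everything lands in the
unassigned class anyway). The binned R² is a noisy statistic on small gene
sets; recovery benchmarks therefore score module detection at the
canonical unsigned power 6 rather than through the selector.

**Modules.** Topological overlap is the standard formula on the
zero-diagonal adjacency; 1−TOM feeds average-linkage clustering with a
**static absolute height cut at 0.99** (the field's static-cut convention).
A quantile-based cut was considered and rejected: it always keeps nearly
all merges, so noise genes could never end up unassigned. Clusters below
`min_size = 30` go to module 0 (unassigned); modules are renumbered by
size. Eigengenes are the first PC of the standardized member submatrix,
unit variance, oriented so the mean correlation with members is
nonnegative — note this orientation necessarily flips when every member is
negated; what is invariant is the relative orientation.

**Association and thresholds.** Module–trait and module–population
correlations are Pearson on pairwise-complete samples (minimum 4), with
p from t = r√((n−2)/(1−r²)); population is coded 0/1 (point-biserial).
The effective number of independent traits is the eigenvalue-based
estimator Meff = Σ I(λ ≥ 1) + (λ − ⌊λ⌋) on the trait correlation spectrum
(eigenvalues rounded to 10 decimals first — an eigenvalue of exactly k
computed as k−ε would otherwise inflate the sum by ~1), and the Bonferroni
trait threshold is 0.05/round(Meff). Both the nominal-0.05 and the
0.05/Meff SDM rules are computed and reported, with a config switch for
which drives `is_sdm`; module–DEG overlap is scored by the hypergeometric
upper tail (the natural test; none is prescribed), and the key module is
the SDM minimizing (trait p, overlap p) lexicographically. Hub genes
satisfy kME > 0.2, best |trait r| > 0.8, and intra-module TOM-degree rank
≤ 3, with ties at the cutoff all included and flagged.

## Panel enrichment

The permutation null draws panel-sized gene sets without replacement from
the expressed universe (the DE stage's tested-gene list by default,
overridable by file); the DEG set is the union of per-layer DEG genes for
the stratum. Empirical p = count/n_perm, reported as the upper bound
"< 1/n_perm" when the count is zero; the (count+1)/(n_perm+1) convention
is available behind a flag but is not the default, since the count/n_perm
convention is pinned by the reporting format. Because the null is exactly
hypergeometric sampling, the closed-form upper tail (scipy's survival
function) runs alongside every permutation result as an internal
consistency check; at 10,000 permutations the two agree within three
binomial standard errors across the tested grid.

## Problem sizes

The default generator is full study scale (483 samples × 17,284 genes) and
is what the acceptance script runs end-to-end, restricting network
construction to the 1,500 most variable genes per layer × stratum (TOM is
quadratic in genes; 1,500 preserves every planted module with margin). The
test suite uses down-scaled cohorts (≈1,000–2,000 genes, 40–300 SNPs, full
69-pair × 7-layer shape) chosen so each suite finishes in seconds while
keeping every estimator in its intended regime; calibration checks
(type-I error, FDP, recovery) were sized so their Monte Carlo error is
small against the asserted bands.

## Limitations

* The generator emulates design structure, not sequencing artifacts: no
  GC/length bias, batch effects, cell-composition variation, read-level
  errors beyond a flat miscall rate, or missing trait values. Passing
  recovery tests therefore demonstrates estimator correctness under the
  stated model, not robustness to real-data pathologies.
* The NB GLM is an unshrunken approximation; with very few samples per
  stratum its per-gene dispersions are noisy, and power (not calibration)
  suffers relative to shrinkage-based estimators.
* Module counts from the static height cut are not comparable to
  dynamic-tree-cut counts; analyses should treat module identities, not
  their number, as the meaningful output.
* Trait correlation structure in synthetic cohorts is sparse, so the
  0.05/Meff threshold is stricter there (Meff ≈ 10) than in clinical
  cohorts with collinear traits (where Meff can be ~4 for 12 traits,
  giving the 0.0125 threshold).
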