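# Methods

This note documents the models, parameter choices, numerical decisions
and known limitations of `nddprs`.  It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Study design being emulated

The pipeline mirrors a postmortem-brain study design: genome-wide
genotypes for 24 schizophrenia cases and 48 non-psychiatric controls;
antemortem clinical records (DIBS subscale timelines and daily
chlorpromazine-equivalent dose) for 19 of the cases; polygenic risk
scores for ADHD and ASD built from large external discovery GWAS;
correlation of those scores with symptom severity and with an
antipsychotic responsiveness score (ARS); a median split of the 19
patients on the ADHD score; and bulk prefrontal-cortex RNA-seq
differential expression between the resulting subgroups, followed by
gene-set over-representation.  Because such patient data are
access-restricted, the package pairs the analysis chain with a synthetic
cohort generator that reproduces the statistical structure each stage
assumes.

## Synthetic cohort generator

**Genotypes.**  Variants are laid out in `n_blocks` contiguous LD blocks
cycling over autosomes 1–22 (10 kb between variants, >1 Mb between
blocks).  Each haplotype copy of each sample is a latent Gaussian with
within-block correlation `within_block_r` (equicorrelated by default,
AR(1) optionally), thresholded at Φ⁻¹(MAF) with MAF ~ Uniform(`maf_range`).
Because the two copies are independent, genotypes are in Hardy–Weinberg
equilibrium marginally by construction; within-block dosage correlation
is controllable, which is what the clumping stage needs.  This is *not* a
human LD map: no recombination hotspots, no allele-frequency/LD coupling,
no imputation error model.  Missingness is concentrated: a
`low_callrate_frac` (default 2%) of variants carry 25% missing calls
(they should fall to the call-rate filter) over a 0.2% background; a
uniform ~1% rate would place every sample's genotyping rate on the 0.99
sample-exclusion boundary and randomly halve the cohort, which matches
neither real post-imputation data nor the study's near-zero sample
attrition.  An `ambiguous_frac` (2%) of variants receives A/T or C/G
alleles to exercise QC.  INFO scores are Beta(30, 2) (mass near 1).

**Discovery GWAS.**  `n_causal` variants (default 100) receive true
per-allele effects with total variance `heritability_liability`
(default 0.3); the observed effect adds noise with the standard error of
a `discovery_n`-sample (default 50,000) regression,
SE = (2p(1−p)·N)^(−1/2), and the p-value comes from the Wald statistic.
A fraction of records is emitted with swapped effect/other alleles (30%)
or on the opposite strand (20%) so the harmonization step is exercised
end to end.

**Diagnosis and clinical records.**  Liability is
√h²·z(score) + √(1−h²)·ε and the top `n_cases` samples by liability are
cases, tying case/control status to the true genetic score so threshold
selection has signal to find.  For `n_clinical` (19) cases, a latent
responsiveness variable is drawn from a Gaussian copula against the
normal scores of the true genetic score, with copula correlation
2·sin(π·ρ/6) so the *rank* correlation targets `prs_ars_rho`
(default −0.5, the regime of interest).  The positive-subscale DIBS
timeline is then back-solved: most-severe scores are 1 + Poisson(8)
integers, the improvement count is the latent rank quantile times the
most-severe score (rounded), and CP-eq (log-normal, median 450 mg/day,
σ_log 0.9) is nudged downward when quantization would create a tie — so
ARS-PS reproduces the latent ranks exactly.  A direct copula on ARS would
be ill-defined because ARS is a derived ratio of integers over a dose.
The negative and general-psychopathology subscales get independent
latents (their most-severe scores are 1 + Poisson(2.5) and
1 + Poisson(2.2)), reflecting the null behaviour expected of them.  The
quantization to integer DIBS scores slightly shrinks the recovered rank
correlation (ties at low improvement counts); the acceptance run
measures the realized value over 500 replicate cohorts.

**Counts.**  Gene-wise relative abundances are log-normal (σ = 1.5,
normalized), library sizes log-normal around 3×10⁶ (σ_log 0.2), and
dispersions follow a scaled inverse-χ²: φ_g = `dispersion_shape` ·
df / χ²_df with df = 20, i.e. φ concentrated near 0.1, typical of bulk
brain RNA-seq.  `n_de_genes` autosomal genes receive log2 fold changes
N(0, `lfc_sd`); when `lfc_min` is set the magnitude is floored at it,
preserving sign (used for the planted-effect calibration runs).  5% of
genes are placed on chrX/chrY to exercise the autosome filter.  Counts
are negative binomial; no batch structure, no gene–gene correlation, no
length/GC effects.

**Reproducibility.**  Every generator draws from
`default_rng([seed, stage_offset])` with fixed per-stage offsets, so each
stage is bit-reproducible in isolation and the whole cohort is a pure
function of the config.

## Genotype QC

Filters apply in a fixed, reported order: autosomal → call rate
(strict > 0.90) → duplicates (same chrom:pos and unordered allele set;
first kept) → strand-ambiguous → MAF (retain ≥ 0.01) → HWE (retain
exact p ≥ 10⁻⁵).  The HWE test conditions on allele counts and sums the
probabilities of heterozygote counts no more probable than the observed
one (relative tie tolerance 10⁻¹²), with the probabilities built by the
upward recurrence — exact for any n, no χ² approximation.  HWE uses
control samples when a diagnosis column identifies them (standard
practice; configurable to all samples).  Sample QC removes genotyping
rates strictly below 0.99, then iteratively breaks up pairs whose
MAF-standardized GRM entry exceeds 0.2, dropping the lower-call-rate
member (ties: the lexicographically larger id).  Missing dosages are
never imputed for QC statistics.

## Polygenic scores

Harmonization keeps records with INFO ≥ 0.8 and resolves allele
orientation: direct match keeps β, swapped alleles flip its sign,
opposite-strand spellings are complemented first (non-ambiguous pairs
only), anything else is dropped and counted.  Clumping is greedy on
ascending GWAS p (ties: chromosome, then position), removing variants
within 200 kb (center-to-center, boundary inclusive) whose squared
Pearson dosage correlation in the *target* sample exceeds 0.1 strictly;
no external LD reference is introduced.  Scores average β per allele:
Σβx/(2m_i) with missing dosages mean-imputed into the numerator and m_i
the sample's non-missing variant count; the raw sum is emitted too.
Flipping every target allele pair shifts all scores by the same constant
(β·x ↦ β·x − 2β), leaving every between-sample contrast unchanged.
Threshold selection fits diagnosis ~ score by maximum-likelihood
logistic regression (the score is z-standardized inside the fit, which
leaves the pseudo-R² unchanged and makes the diverging-coefficient
separation check scale-free) and picks the threshold maximizing
Nagelkerke's R² = [1 − (L₀/L₁)^{2/n}]/[1 − L₀^{2/n}]; non-converged or
separated fits are flagged and excluded, ties go to the smaller
threshold.

## ARS

change_rate = (S_max − S_pre)/S_max and ARS = change_rate/D, per
subscale.  S_max = 0 or D = 0 leaves the value undefined — flagged with
a reason and excluded from correlations, never imputed or clipped; a
negative change rate (worsening past the recorded maximum) is retained
and flagged.  The input's `dibs_*_max` columns may encode either
convention for "most severe" — the subscale value at the time of the
maximum *total* score, or each subscale's own maximum — and the
arithmetic is identical under both; the conventions differ only when
subscales peak at different times, the choice is genuinely open, and
which one a dataset uses should be recorded alongside it.  The
synthetic generator emits a single most-severe value per subscale, so
the two coincide there.

## Association statistics

Spearman uses average ranks; p is exact by full enumeration of the n!
pairings for 3 < n ≤ 10 (enumerated in 100k-permutation chunks) and the
t approximation t = ρ√((n−2)/(1−ρ²)) above.  BH adjustment is the
step-up q_(i) = min_{j≥i} p_(j)·m/j capped at 1.  The BH family defaults
to six tests per PRS (three severity + three ARS correlations),
matching a per-panel presentation; a single 12-test family is available
— the choice is ambiguous and both are shipped.  Welch's t operates on
summary statistics (so printed group means/SDs can be re-tested) or raw
vectors, with the Welch–Satterthwaite df.  The exact r×c test uses the
Freeman–Halton probability ordering — sum over all margin-fixed tables
with probability ≤ the observed (relative tolerance 10⁻¹²) — enumerated
recursively with a 10⁷-table cap and an optional Monte-Carlo mode; a
zero margin returns p = 1.  The median split labels scores strictly
above the median "high": with 19 distinct scores that reproduces a 9/10
split, and ties at the median fall to the low group.

## Differential expression

Counts for gene g are NB with mean μ = exp(Xβ_g + offset) and variance
μ + φ_g μ²; offsets are log effective library sizes (TMM factors times
library size).  TMM follows the standard recipe: reference sample by
75th-percentile proximity to the mean, 30%/5% trims on M/A ranks,
precision-weighted mean of surviving log-ratios, factors rescaled to
geometric mean 1.  The design holds intercept, sex, age-decade dummies
(unordered categories, first level reference, empty levels dropped,
collinear covariate columns dropped with a warning) and the group
indicator last (low group reference; positive coefficients mean higher
expression in the high-PRS group).  All genes share the design, so the
IRLS solver is vectorized across genes (batched normal equations,
working weight μ/(1+φμ), η clipped at ±30, ridge 10⁻¹⁰ on the normal
matrix, convergence max|Δβ| < 10⁻⁸ within 100 iterations; non-converged
genes are excluded with a reason).  Dispersions maximize the Cox–Reid
adjusted profile likelihood APL(φ) = ℓ(β̂(φ)) − ½ log det(XᵀWX) on a
31-point log grid over [10⁻⁴, 5] with parabolic refinement; gene-wise
values maximize APL_g + (d₀/df_resid)·mean-APL with prior df d₀ = 10,
shrinking noisy per-gene estimates toward the common value (a single
gene is fully shrunk).  This is a deliberate simplification of
empirical-Bayes count pipelines: no abundance-dispersion trend and no
quasi-likelihood F-test; the group test is a likelihood-ratio χ²₁
between the full and group-free fits (statistics within −10⁻⁸ of zero
clamped; worse-than-reduced full fits flagged and excluded).  Genes are
pre-filtered to autosomes with CPM ≥ 1 in at least min-group-size
samples — a necessary low-expression filter, configurable.  The
fixed-dispersion GLM, LRT and TMM factors are cross-checked against the
reference R implementation in the test suite; dispersion estimation and
shrinkage are validated by parameter recovery instead, since the
simplified prior is not meant to replicate any package's internals.

## Over-representation

Upper-tail hypergeometric p for the overlap between the nominal-p<0.05
DEG list and each GMT set, both intersected with the universe of
analyzed (autosomal, expressed) genes; BH across sets; ranking by
ascending p with ties broken by enrichment ratio (observed/expected
overlap).  The universe choice is documented rather than inherited from
any proprietary knowledge base, which this stage deliberately replaces
with a transparent test.

## Problem sizes and runtime

The default configuration — 6,000 variants in 300 blocks, 72 samples,
8,000 genes — was chosen so the full pipeline completes in seconds and
the whole validation suite in about a minute while keeping every
statistical regime of interest (LD for clumping, 19-patient clinical
statistics, overdispersed counts with 9 vs 10 groups).  Calibration
checks use 2,000-gene null panels and twenty 500-gene planted-effect
panels at the study's 9/10 split.

## Limitations

* The generator's LD, missingness and count models are structural
  stand-ins; passing tests demonstrate correctness of the *procedures*
  and calibration under the stated models, not performance on real
  genotype or expression data.
* Imputation, phasing, population-structure correction and
  cross-ancestry PRS transfer are out of scope; scores use target-sample
  LD only.
* The dispersion shrinkage is a documented simplification; FDR control
  is verified empirically at the shipped sample sizes, not guaranteed
  theoretically.
* CP-eq aggregation across drugs, DIBS item-level scoring and diagnosis
  instruments are assumed upstream of the package's inputs.
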