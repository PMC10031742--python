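# Methods

This note documents the models, numerical choices and limitations behind
`mitoarray`, in the order the pipeline runs.

## Log R ratio

`compute_lrr` defines the expected intensity of a marker as its **median
across samples**: `LRR_ij = log2(R_ij / median_i R_ij)`. The median is
robust to copy-number outliers and makes the median sample's LRR exactly
zero. Zero or missing intensities become missing LRRs; an all-zero marker
yields an all-missing column and is flagged. A consequence worth knowing:
any cohort-level constant (e.g. the average batch shift) is absorbed into
the per-marker median, so LRRs measure *relative* signal within a cohort,
never absolute DNA quantity.

## GC-wave correction

Long-range "genomic waves" in array LRRs track regional GC content. We
model them per sample as a quadratic: OLS of autosomal LRR on
`(gc, gc²)`, the model family popularised by array CNV callers. Design
columns are centered on the autosomal markers used in the fit, so the
subtraction is exactly mean-preserving per sample; the intercept (the
sample's overall intensity level, which carries the copy-number and batch
information) is never removed. Mitochondrial and sex-chromosome markers
are corrected with the autosomal-fit coefficients because the
mitochondrial GC range (~0.40–0.48) is too narrow to support its own fit.
Samples with fewer than 10 usable autosomal LRRs are left uncorrected and
flagged rather than fitted on noise.

## High-quality marker selection

Autosomal markers must not be off-target (secondary alignment identity
> 80%, consumed as a manifest flag), must have call rate > 0.95 and exact
HWE P > 1e-6, and are then LD-pruned (sliding window of 50 markers, step
5, drop the later-position marker of any pair with r² ≥ 0.3; undefined r²
counts as no LD) and optionally thinned to a target count by maximum
spacing. Mitochondrial markers face only the off-target and call-rate
filters — HWE and LD are diploid, recombining-genome concepts.

The HWE test is the exact conditional test on heterozygote counts given
allele counts, two-sided by probability mass, computed with the
numerically stable mode-outward recurrence; a chi-square variant exists
for comparison. The exact test is preferred because marker QC operates in
the extreme tail (P ~ 1e-6) where the asymptotic test is unreliable for
low-MAF markers. X-chromosome HWE is computed on females only; Y/MT are
exempt.

**Maximum spacing.** The budget is split across chromosomes proportionally
to spanned length (largest-remainder rounding); within a chromosome we
solve the maximin-gap subset problem *exactly* by binary search on the gap
with a greedy left-to-right feasibility sweep (the classic linear
arrangement argument makes the greedy check exact). This is O(n log range)
and deterministic. We chose the exact solver over heuristic quantile
binning because binning demonstrably misses the optimum even on 10 equally
spaced markers.

## Confounder adjustment and extraction

PCA (full SVD, deterministic sign: largest-|loading| entry positive) of
the HQ autosomal LRRs yields per-sample scores for up to **80 PCs**
(capped at `n_samples − 1`, with a warning — production cohorts never hit
the cap, small test fixtures do). Missing LRRs are mean-imputed per marker
beforehand, flagged when a marker exceeds 20% missingness. Each
mitochondrial marker's LRR is then residualised on the PCs by OLS *with
intercept* (intercept included so residuals are centered per marker).

The raw MCN score is the first PC of the adjusted mitochondrial LRR
matrix. PC sign is indeterminate, so it is aligned to correlate
nonnegatively with the per-sample mean adjusted mitochondrial LRR: more
signal means more copies. Standardization uses the Blom rank-based
inverse-normal transform `Φ⁻¹((r − 3/8)/(n + 1/4))` with average ranks for
ties (a fully tied vector maps to exactly zero). The transform is
monotone, so raw and standardized scores are rank-identical by
construction. A first PC explaining < 5% of variance is returned but
flagged low-signal.

A bias worth stating plainly: regressing on k PCs removes a k-dimensional
subspace from the mitochondrial signal. With k = 80 and n = 500 samples,
roughly k/(n−1) ≈ 16% of any sample-level signal variance is removed along
with the confounders, bounding attainable recovery at Pearson
√(1 − 80/499) ≈ 0.92 even in the no-noise limit. Large cohorts
(n ≫ 80·10) make this negligible; small ones should reduce `n_pcs`.

## Sample QC and association

Samples fail for exactly four reasons: call rate < 0.95; autosomal LRR SD
> 0.35 (computed on the GC-corrected HQ autosomal LRRs — post-correction
chosen for stability); inferred-vs-reported sex mismatch where both are
known (X-inbreeding F > 0.8 plus Y call rate ≥ 0.5 → male, F < 0.2 →
female, else unknown — the thresholds are conventions, the signals are
standard); and, in association mode only, absence of any phenotype data.
Estimation runs on all samples; the flags gate downstream association.

`associate` uses Spearman rank correlation with a Fisher-z 95% CI
(variance 1.06/(n−3), clamped to [−1, 1]) and the t-approximation P-value.
Sex is encoded female = 0, male = 1.

The WGS estimator is `2 · mean mito depth / mean autosomal depth` — an
autosomal locus is present twice per cell, so the factor 2 puts the ratio
on a copies-per-cell scale.

## Array design and imputation scoring

Greedy tagging: anchors are credited first, then each round selects the
candidate covering the most still-uncovered targets at genotype r² ≥ 0.8
within ±1 Mb (both config-exposed; the defaults follow field convention).
Ties break by higher MAF, then smaller position, then lexicographic id —
determinism matters more than which of several equivalent tags wins. r² is
computed from diploid genotype dosages for consistency with the QC
module's LD definition.

Direct coverage matches on (chromosome, position) and allele-set equality
allowing ref/alt swap but **no strand flip** (same-strand manifests
assumed); strand reconciliation including flips lives in the harmonizer,
which tries identity → swap → flip → swap+flip and drops A/T and C/G
(strand-ambiguous) sites where flip and swap are indistinguishable.
Imputation metrics follow the usual definitions: dosage r² per marker
(pairwise-complete Pearson²), best-guess discordance, and coverage as the
fraction of markers with r² **strictly** greater than 0.8, stratified into
common (MAF ≥ 0.05) and low-frequency (0.01 ≤ MAF < 0.05) strata, with a
profile over bin edges {0.01, 0.02, 0.05, 0.1, 0.2, 0.5}. Aggregate r² and
discordance are unweighted means across markers. Concordance excludes
test-missing entries from numerator and denominator and reports the
test-missing fraction separately — missingness is already captured by call
rate, and folding it into concordance would conflate two failure modes.

## Synthetic data

The generator exists to make every stage testable with known truth, not to
be a realistic population-genetic simulator.

* **LD** comes from a two-founder copying process: complementary founders,
  per-marker state redraw with probability `ld_decay` (default 0.1 —
  adjacent-marker genotype r² ≈ 0.81, decaying geometrically). This is the
  minimal machinery that gives tunable pairwise r² for tagging and pruning
  tests; it produces allele frequencies concentrated near 0.5, no realistic
  frequency spectrum, a single ancestry, and no mutation/error model.
  A `maf_floor` (default 0.05) is enforced by planting minor alleles.
* **Intensity model**: autosomal LRR = batch shift + GC wave + noise;
  mitochondrial LRR = `slope · log2(mcn/2)` + batch shift + noise;
  `R = R_base · 2^LRR`. Defaults are the package's reference conditions:
  500 samples, 2000 autosomal + 200 mitochondrial markers, 4 batches,
  batch SD 0.2, noise SD 0.1. The batch shift loads identically on
  autosomal and mitochondrial probes (that is what makes the PC adjustment
  identifiable and testable); `mcn_log_sd = 0.25` gives ±20–40% copy-number
  variation, in the range reported for blood-derived DNA, and
  `mito_signal_slope = 1.0` encodes intensity proportional to
  mitochondrial DNA quantity. GC waves hit autosomal markers only by
  default so the correction stage has an isolated signal to remove.
* **Depths**: autosomal ~ Normal(30, 3) truncated positive; mitochondrial
  = autosomal × (mcn/2) × lognormal(0, 0.05) — multiplicative noise keeps
  depths positive.
* **Phenotypes** are linear in standardized true log-MCN (effects
  age −0.3, WBC +0.3, HEMO +0.2, PLT +0.3 — signs per the epidemiology:
  MCN falls with age and tracks blood cell counts) plus unit noise, then
  affinely mapped to clinical units, which leaves rank statistics
  untouched.
* Marker GC fractions are abstract per-marker annotations drawn
  Uniform(0.30, 0.70) autosomal / Uniform(0.40, 0.48) mitochondrial; no
  flanking-window size is modelled.
* All randomness flows through one `numpy.random.default_rng` (PCG64)
  generator; identical config + seed is bit-identical across platforms.

Passing tests on this generator demonstrate that the pipeline removes the
confounding it models (shared additive batch shifts, quadratic GC waves)
and recovers a monotone copy-number signal. They do not demonstrate
robustness to probe-specific binding chemistry, genotype-calling error,
plate-position effects, population structure, or heteroplasmy — none of
which the generator emulates.

## Problem sizes and numerical conventions

The shipped test suite and acceptance script run the reference
configuration (n = 500, 2000 + 200 markers) over 10 seeds for recovery
statistics, a 3-point probe-noise grid (SD 0.4, 0.2, 0.05) for the
estimator-agreement check, and the exhaustive exact-HWE grid over all
genotype triples with total ≤ 100 — sizes chosen so the whole suite
completes in a few minutes on one core while keeping Monte-Carlo error
well inside the asserted tolerances. The pipeline itself contains no
randomness: given identical inputs it is deterministic to the last bit,
with PCA signs fixed by the largest-loading convention and all OLS via
`numpy.linalg.lstsq`.

Known limitations: biallelic SNPs only (multi-allelic records are rejected
at parse time); no BAF/heteroplasmy modelling; no CNV calling; LD pruning
is order-dependent (keep-first) as in standard tooling, not globally
optimal; the greedy tagger recomputes r² lazily and is meant for panels of
thousands, not millions, of markers.
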