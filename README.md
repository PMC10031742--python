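# mitoarray

A Python toolkit for SNP genotyping arrays in population cohorts, built
around estimating **mitochondrial DNA copy number (MCN)** from raw array
intensity data. MCN — the relative abundance of mitochondrial genomes per
cell — is an emerging biomarker of aging-related disease, and because
mitochondrial probes on a genotyping array fluoresce in proportion to the
amount of mitochondrial DNA in the assay, a biobank that genotypes its
cohort gets MCN almost for free. The toolkit also covers the surrounding
array workflow: marker/sample quality control, greedy tag-SNP selection
for array design, and scoring of genotyping/imputation accuracy.

Intended users: statistical geneticists and bioinformaticians working with
array intensity data (log R ratios), reference haplotype panels, and
imputation output.

## The estimation model

Let `R_ij` be the total probe intensity of sample *i* at marker *j*. The
log R ratio is

```
LRR_ij = log2( R_ij / median_i R_ij )
```

a per-marker-normalised measure of DNA quantity. The pipeline removes the
two dominant artifacts and extracts the mitochondrial dose signal:

1. **GC waves** — per sample, OLS of autosomal LRR on `(gc_j, gc_j²)`
   (flanking GC fraction); the centered fitted effect is subtracted from
   all markers, so the correction is mean-preserving per sample.
2. **High-quality markers** — drop off-target probes (secondary alignment
   identity > 80%), call rate ≤ 0.95, exact Hardy–Weinberg P ≤ 1e-6; then
   LD pruning (r² < 0.3) and maximum spacing.
3. **Latent confounders** — PCA of the HQ autosomal LRRs yields 80 PCs per
   sample capturing batch effects and DNA-concentration variation; each
   mitochondrial marker's LRR is replaced by its residual after regressing
   on those PCs.
4. **Extraction** — the first principal component of the adjusted
   mitochondrial LRRs is the raw MCN score, sign-aligned with the mean
   mitochondrial LRR and mapped to a standard normal scale by the Blom
   rank-based inverse-normal transform `Φ⁻¹((r − 3/8)/(n + 1/4))`.

An independent estimator from whole-genome sequencing,
`MCN_wgs = 2 · depth_mito / depth_autosomal`, serves as a cross-check, and
`associate` reports Spearman rank correlations (Fisher-z 95% CIs,
variance 1.06/(n−3)) of MCN with phenotypes such as age and blood counts.

Everything ships with a synthetic-data generator (`simulate_dataset`) that
emulates LD-structured genotypes, intensities with known true MCN, batch
shifts, GC waves, WGS depth pairs and phenotypes, so the full pipeline is
testable at desk scale.

## Worked example

```python
import mitoarray as ma
from scipy.stats import spearmanr

cfg = ma.SimulationConfig(seed=1)          # 500 samples, 2000 autosomal
ds = ma.simulate_dataset(cfg)              # + 200 mito markers, 4 batches
res = ma.run_mcn_pipeline(ds.genotypes, ds.intensity,
                          samples=ds.samples, depths=ds.depths, n_pcs=80)
print(res.stage_report[["stage", "n_markers", "note"]].to_string(index=False))
rho = spearmanr(res.table["mcn"], ds.truth.true_mcn).statistic
print(f"recovery rho = {rho:.3f}")
```

prints

```
            stage  n_markers              note
            input       2200
      compute_lrr       2200
       gc_correct       2200         skipped=0
select_hq_markers        524 auto=324 mito=200
  adjust_mito_lrr        200          n_pcs=80
      extract_mcn        200         evr=0.864
    mcn_sample_qc        200          failed=0
recovery rho = 0.929
```

Reading this: of 2000 autosomal markers, 324 survive QC + LD pruning and
feed the 80-PC confounder model; all 200 mitochondrial markers are high
quality; the first PC of their adjusted LRRs explains 86.4% of variance;
and the standardized estimate ranks the cohort's true copy numbers with
Spearman ρ = 0.93. The same estimator class is available in sklearn style:
`ma.MCNEstimator(n_pcs=80).fit(ds.intensity, genotypes=ds.genotypes).mcn_`.

A command-line interface mirrors the library:

```bash
mitoarray --out-dir sim simulate
mitoarray --out-dir out mcn-estimate --genotypes sim/genotypes.vcf \
    --intensity sim/intensity.tsv --markers sim/markers.tsv \
    --samples sim/samples.tsv --wgs-depths sim/depths.tsv
```

Other subcommands: `design-tags`, `qc`, `impute-eval`, `coverage`.

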