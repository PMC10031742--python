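"""Mitochondrial copy number (MCN) estimation from SNP-array intensities.

The mitochondrial genome is present in many copies per cell, so the total
fluorescent signal of mitochondrial probes scales with the amount of
mitochondrial DNA in the assay. The estimation pipeline turns that signal
into a per-sample relative copy-number score:

1. ``compute_lrr``       -- log R ratio: log2 of each probe's intensity over
                            its per-marker median across samples.
2. ``gc_correct``        -- per-sample quadratic regression of autosomal LRR
                            on flanking GC content removes "genomic waves".
3. ``select_hq_markers`` -- high-quality marker selection: drop off-target
                            probes, call rate <= 0.95, HWE P <= 1e-6, then
                            LD pruning (r2 < 0.3) and maximum spacing.
4. ``autosomal_pcs``     -- PCA of the autosomal LRRs (80 PCs by default)
                            captures latent confounding shared with the
                            mitochondrial probes: batch effects, DNA
                            concentration, residual waves.
5. ``adjust_mito_lrr``   -- each mitochondrial probe's LRR is replaced by
                            its residual after regressing on the PCs.
6. ``extract_mcn``       -- the first principal component of the adjusted
                            mitochondrial LRRs is the raw MCN score; it is
                            mapped to a standard normal scale by a Blom
                            rank-based inverse-normal transform.

A WGS-based estimator (``wgs_mcn`` = 2 x mito/autosomal mean depth) and a
Spearman association against phenotypes complete the module. The pipeline
is fully deterministic: no randomness enters estimation.

Stages 2, 4+5 and the whole pipeline are also exposed as sklearn-style
estimators (:class:`GCWaveCorrector`, :class:`PCConfounderAdjuster`,
:class:`MCNEstimator`) so they compose with sklearn tooling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .datatypes import (
    AUTOSOMES,
    GenotypeMatrix,
    IntensityMatrix,
    LRRMatrix,
)
from . import qc as _qc


class PipelineError(RuntimeError):
    """A pipeline stage could not proceed; the message names the stage."""


# ---------------------------------------------------------------------------
# Stage 1: log R ratio


def compute_lrr(intensity: IntensityMatrix) -> LRRMatrix:
    """LRR[i,j] = log2(R[i,j] / median_i R[.,j]).

    The per-marker median across samples is the expected intensity; the
    median sample of each marker therefore gets LRR exactly 0. Zero or
    missing intensities give missing LRRs; an all-zero/all-missing marker
    yields an all-missing column.
    """
    if intensity.n_samples < 2:
        raise ValueError("compute_lrr requires at least two samples")
    r = intensity.signal.copy()
    r[r == 0] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(r, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        lrr = np.log2(r / med)
    lrr[~np.isfinite(lrr)] = np.nan
    return LRRMatrix(intensity.sample_ids, intensity.markers, lrr)


# ---------------------------------------------------------------------------
# Stage 2: GC-wave correction


@dataclass
class GCModel:
    """Per-sample coefficients of the quadratic LRR-on-GC regression."""

    coefficients: pd.DataFrame = field(repr=False)  # sample x (gc, gc2, ...)
    gc_means: np.ndarray = field(repr=False)  # centering means of the design
    skipped: list[str] = field(default_factory=list)


def _gc_design(gc: np.ndarray, degree: int) -> np.ndarray:
    return np.column_stack([gc**d for d in range(1, degree + 1)])


def gc_correct(
    lrr: LRRMatrix,
    markers: pd.DataFrame | None = None,
    degree: int = 2,
    min_markers: int = 10,
) -> tuple[LRRMatrix, GCModel]:
    """Remove the genomic-wave component of LRR by per-sample regression.

    For each sample, autosomal LRR is regressed by OLS on mean-centered
    (gc, gc^2); the fitted effect is subtracted from every marker of that
    sample, mitochondrial (and sex-chromosome) markers included, using the
    autosomal-fit coefficients. Because the design is centered on the
    autosomal markers used in the fit, the correction is mean-preserving
    per sample. Samples with fewer than ``min_markers`` usable autosomal
    markers are left uncorrected and flagged.
    """
    m = markers if markers is not None else lrr.markers
    if list(m["marker_id"]) != lrr.marker_ids:
        raise ValueError("marker manifest does not match LRR columns")
    gc = m["gc_fraction"].to_numpy(float)
    auto = np.isin(m["chromosome"].to_numpy(), AUTOSOMES)
    if np.isnan(gc[auto]).any():
        raise ValueError("gc_fraction must be available for all autosomal markers")
    design_all = _gc_design(np.nan_to_num(gc), degree)
    out = lrr.lrr.copy()
    coefs = np.full((lrr.n_samples, degree), np.nan)
    gc_means = np.nanmean(design_all[auto], axis=0)
    skipped: list[str] = []
    for i, sid in enumerate(lrr.sample_ids):
        y = lrr.lrr[i]
        ok = auto & np.isfinite(y)
        if ok.sum() < min_markers:
            skipped.append(sid)
            continue
        x_mean = design_all[ok].mean(axis=0)
        xc = design_all[ok] - x_mean
        beta, *_ = np.linalg.lstsq(xc, y[ok] - y[ok].mean(), rcond=None)
        coefs[i] = beta
        effect = (design_all - x_mean) @ beta
        out[i] = y - effect
        out[i, ~np.isfinite(y)] = np.nan
    model = GCModel(
        coefficients=pd.DataFrame(
            coefs, index=lrr.sample_ids, columns=[f"gc^{d}" for d in range(1, degree + 1)]
        ),
        gc_means=gc_means,
        skipped=skipped,
    )
    return LRRMatrix(lrr.sample_ids, lrr.markers, out), model


# ---------------------------------------------------------------------------
# Stage 3: high-quality marker selection


def select_hq_markers(
    g: GenotypeMatrix,
    markers: pd.DataFrame | None = None,
    target_auto_count: int | None = None,
    min_call_rate: float = 0.95,
    min_hwe_p: float = 1e-6,
    r2_max: float = 0.3,
    female_mask: np.ndarray | None = None,
) -> dict[str, list[str]]:
    """Select the autosomal and mitochondrial markers used for estimation.

    Autosomal: drop off-target probes, call rate <= ``min_call_rate`` and
    HWE P <= ``min_hwe_p``; LD-prune the survivors at r2 < ``r2_max``; thin
    to ``target_auto_count`` by maximum spacing when a cap is set.
    Mitochondrial: drop off-target and low call rate only.
    """
    m = markers if markers is not None else g.markers
    if list(m["marker_id"]) != g.marker_ids:
        raise ValueError("marker manifest does not match genotype columns")
    stats_df = _qc.marker_stats(
        g, min_call_rate=min_call_rate, min_hwe_p=min_hwe_p, min_mac=0,
        female_mask=female_mask,
    )
    chrom = m["chromosome"].to_numpy()
    off = m["off_target"].to_numpy(bool)
    auto = np.isin(chrom, AUTOSOMES)
    mito = chrom == "MT"
    cr = stats_df["call_rate"].to_numpy()
    hwe = stats_df["hwe_p"].to_numpy()

    auto_ok = auto & ~off & (cr > min_call_rate) & ~(np.nan_to_num(hwe, nan=1.0) <= min_hwe_p)
    mito_ok = mito & ~off & (cr > min_call_rate)

    auto_ids = [mid for mid, k in zip(g.marker_ids, auto_ok) if k]
    if auto_ids:
        pruned = _qc.ld_prune(g.subset_markers(auto_ids), r2_max=r2_max)
    else:
        pruned = []
    if target_auto_count is not None and len(pruned) > target_auto_count:
        sub = m.set_index("marker_id").loc[pruned].reset_index()
        pruned = _qc.max_spacing_select(sub, target_auto_count)
    mito_ids = [mid for mid, k in zip(g.marker_ids, mito_ok) if k]
    if not mito_ids:
        raise PipelineError("select_hq_markers: no mitochondrial markers survive QC")
    return {"autosomal": pruned, "mitochondrial": mito_ids}


# ---------------------------------------------------------------------------
# Stages 4-5: PC extraction and confounder adjustment


def _mean_impute(x: np.ndarray, max_missing_warn: float = 0.2) -> np.ndarray:
    out = x.copy()
    miss = ~np.isfinite(out)
    if miss.any():
        frac = miss.mean(axis=0)
        if (frac > max_missing_warn).any():
            warnings.warn(
                f"{int((frac > max_missing_warn).sum())} markers exceed "
                f"{max_missing_warn:.0%} missing LRR before PCA", stacklevel=3
            )
        col_mean = np.where(miss.all(axis=0), 0.0, np.nanmean(np.where(miss, np.nan, out), axis=0))
        out[miss] = np.broadcast_to(col_mean, out.shape)[miss]
    return out


def _signed_pca(x: np.ndarray, n_components: int) -> tuple[np.ndarray, PCA]:
    """Full-SVD PCA with a deterministic sign: the largest-|loading| entry
    of each component is made positive."""
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    for k in range(pca.components_.shape[0]):
        j = int(np.argmax(np.abs(pca.components_[k])))
        if pca.components_[k, j] < 0:
            pca.components_[k] *= -1
            scores[:, k] *= -1
    return scores, pca


def autosomal_pcs(lrr_auto_hq: LRRMatrix, n_pcs: int = 80) -> tuple[np.ndarray, PCA]:
    """Sample scores of the top PCs of the high-quality autosomal LRRs.

    Missing LRRs are mean-imputed per marker; markers are centered by the
    PCA itself. The component count is capped at min(n_pcs, n_samples - 1,
    n_markers); components are variance-ordered with a deterministic sign.
    """
    n, p = lrr_auto_hq.n_samples, lrr_auto_hq.n_markers
    if n < 2:
        raise ValueError("autosomal_pcs requires at least two samples")
    k = min(n_pcs, n - 1, p)
    if k < n_pcs:
        warnings.warn(f"n_pcs reduced from {n_pcs} to {k} (rank bound)", stacklevel=2)
    x = _mean_impute(lrr_auto_hq.lrr)
    return _signed_pca(x, k)


def adjust_mito_lrr(lrr_mito_hq: LRRMatrix, pcs: np.ndarray) -> LRRMatrix:
    """Residualize each mitochondrial marker's LRR on the autosomal PCs.

    Ordinary least squares with intercept; with n_samples <= n_pcs + 1 the
    PC count is reduced (leading components kept) with a warning so the
    regression keeps at least one residual degree of freedom.
    """
    pcs = np.asarray(pcs, float)
    n = lrr_mito_hq.n_samples
    if pcs.ndim == 1:
        pcs = pcs[:, None]
    if pcs.shape[0] != n:
        raise ValueError("PC scores do not match sample count")
    max_pcs = max(n - 2, 0)
    if pcs.shape[1] > max_pcs:
        warnings.warn(
            f"reducing adjustment PCs from {pcs.shape[1]} to {max_pcs} "
            "(too few samples)", stacklevel=2
        )
        pcs = pcs[:, :max_pcs]
    y = _mean_impute(lrr_mito_hq.lrr)
    x = np.column_stack([np.ones(n), pcs])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return LRRMatrix(lrr_mito_hq.sample_ids, lrr_mito_hq.markers, resid)


# ---------------------------------------------------------------------------
# Stage 6: extraction and standardization


def inverse_normal_transform(x: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Blom rank-based inverse-normal transform.

    z_i = Phi^{-1}((r_i - 3/8) / (n + 1/4)) with average ranks for ties;
    a totally tied vector maps to all zeros.
    """
    x = np.asarray(x, float)
    r = stats.rankdata(x, method="average")
    return stats.norm.ppf((r - offset) / (len(x) + 1 - 2 * offset))


@dataclass
class MCNResult:
    """Per-sample MCN estimate with QC flags and stage metadata."""

    table: pd.DataFrame = field(repr=False)  # sample_id, raw_score, mcn
    explained_variance_ratio: float = np.nan
    low_signal: bool = False
    flags: pd.DataFrame | None = field(default=None, repr=False)
    stage_report: pd.DataFrame | None = field(default=None, repr=False)


def extract_mcn(adjusted_mito: LRRMatrix) -> MCNResult:
    """First PC of the adjusted mitochondrial LRRs, standardized.

    The PC sign is aligned so the score correlates nonnegatively with the
    per-sample mean adjusted mitochondrial LRR (more signal = more copies).
    Standardization is the Blom inverse-normal transform, which preserves
    rank order exactly. A first PC explaining < 5% of variance is returned
    but flagged low-signal.
    """
    n, p = adjusted_mito.n_samples, adjusted_mito.n_markers
    if p < 2 or n < 3:
        raise ValueError("extract_mcn requires >=2 mitochondrial markers and >=3 samples")
    x = _mean_impute(adjusted_mito.lrr)
    if np.allclose(x.var(axis=0).sum(), 0.0):
        raw = np.zeros(n)
        evr = np.nan
    else:
        scores, pca = _signed_pca(x, 1)
        raw = scores[:, 0]
        evr = float(pca.explained_variance_ratio_[0])
        row_mean = x.mean(axis=1)
        if np.std(raw) > 0 and np.std(row_mean) > 0:
            if np.corrcoef(raw, row_mean)[0, 1] < 0:
                raw = -raw
    std = inverse_normal_transform(raw)
    table = pd.DataFrame(
        dict(sample_id=adjusted_mito.sample_ids, raw_score=raw, mcn=std)
    )
    return MCNResult(
        table=table,
        explained_variance_ratio=evr,
        low_signal=not np.isfinite(evr) or evr < 0.05,
    )


# ---------------------------------------------------------------------------
# WGS estimator, sample QC, association


def wgs_mcn(autosomal_depth, mito_depth) -> np.ndarray | float:
    """MCN from sequencing depth: 2 x mitochondrial / autosomal mean depth.

    The factor 2 puts the estimate on a per-diploid-genome copy scale
    (an autosomal locus is present twice per cell).
    """
    a = np.asarray(autosomal_depth, float)
    m = np.asarray(mito_depth, float)
    if (a <= 0).any() or (m <= 0).any():
        raise ValueError("depths must be positive")
    out = 2.0 * m / a
    return float(out) if out.ndim == 0 else out


def mcn_sample_qc(
    g: GenotypeMatrix,
    lrr: LRRMatrix | None,
    samples: pd.DataFrame | None = None,
    require_phenotypes: bool = False,
    phenotype_columns: tuple[str, ...] = ("age", "WBC", "HEMO", "PLT"),
    thresholds: _qc.SampleQCThresholds | None = None,
) -> pd.DataFrame:
    """Per-sample pass/fail for MCN analysis.

    Fails exactly four conditions: call rate < 0.95 (reason ``call_rate``),
    autosomal LRR SD > 0.35 (``lrr_sd``), inferred-vs-reported sex mismatch
    where both are known (``sex``), and — in association mode only — no
    available phenotype data (``phenotype``).
    """
    th = thresholds or _qc.SampleQCThresholds()
    base = _qc.sample_stats(g, lrr=lrr, thresholds=th)
    rows = []
    reported = None
    if samples is not None:
        reported = samples.set_index("sample_id")["reported_sex"]
    for sid, row in base.iterrows():
        reasons = []
        if row["call_rate"] < th.min_call_rate:
            reasons.append("call_rate")
        if np.isfinite(row["lrr_sd"]) and row["lrr_sd"] > th.max_lrr_sd:
            reasons.append("lrr_sd")
        if reported is not None and sid in reported.index:
            rep = reported.loc[sid]
            if rep != "unknown" and row["inferred_sex"] != "unknown" and rep != row["inferred_sex"]:
                reasons.append("sex")
        if require_phenotypes and samples is not None and sid in samples["sample_id"].values:
            srow = samples.set_index("sample_id").loc[sid]
            have = [c for c in phenotype_columns if c in srow.index and np.isfinite(float(srow[c]))]
            if not have:
                reasons.append("phenotype")
        rows.append(dict(sample_id=sid, passed=not reasons, reasons=",".join(reasons)))
    return pd.DataFrame(rows).set_index("sample_id")


def associate(
    mcn: MCNResult | pd.DataFrame,
    samples: pd.DataFrame,
    phenotypes: tuple[str, ...] | None = None,
    min_n: int = 10,
) -> pd.DataFrame:
    """Spearman rank correlation of the MCN estimate with each phenotype.

    95% CI from the Fisher z transform with variance 1.06/(n-3) (clamped
    to [-1, 1]); P from the t approximation. ``reported_sex`` is encoded
    female=0, male=1 when requested as a phenotype named ``sex``.
    """
    table = mcn.table if isinstance(mcn, MCNResult) else mcn
    merged = table.merge(samples, on="sample_id", how="inner")
    if phenotypes is None:
        phenotypes = tuple(
            c for c in ("age", "sex", "WBC", "HEMO", "PLT") if c in merged.columns or c == "sex"
        )
    rows = []
    for pheno in phenotypes:
        if pheno == "sex" and "reported_sex" in merged.columns:
            vals = merged["reported_sex"].map({"female": 0.0, "male": 1.0})
        elif pheno in merged.columns:
            vals = pd.to_numeric(merged[pheno], errors="coerce")
        else:
            continue
        ok = vals.notna() & merged["mcn"].notna()
        n = int(ok.sum())
        if n < min_n:
            raise ValueError(f"phenotype {pheno!r}: only {n} complete samples (need >= {min_n})")
        x = merged.loc[ok, "mcn"].to_numpy(float)
        y = vals[ok].to_numpy(float)
        if np.ptp(y) == 0:
            rows.append(dict(phenotype=pheno, rho=np.nan, ci_low=np.nan, ci_high=np.nan,
                             p=np.nan, n=n, flag="constant"))
            continue
        rho, p = stats.spearmanr(x, y)
        z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
        se = np.sqrt(1.06 / (n - 3))
        lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
        rows.append(dict(phenotype=pheno, rho=float(rho),
                         ci_low=float(max(-1.0, lo)), ci_high=float(min(1.0, hi)),
                         p=float(p), n=n, flag=""))
    return pd.DataFrame(rows).set_index("phenotype")


# ---------------------------------------------------------------------------
# Orchestration


def run_mcn_pipeline(
    genotypes: GenotypeMatrix,
    intensity: IntensityMatrix,
    markers: pd.DataFrame | None = None,
    samples: pd.DataFrame | None = None,
    depths: pd.DataFrame | None = None,
    n_pcs: int = 80,
    gc_degree: int = 2,
    target_auto_count: int | None = None,
    r2_max: float = 0.3,
    min_call_rate: float = 0.95,
    min_hwe_p: float = 1e-6,
    require_phenotypes: bool = False,
    gc_correction: bool = True,
) -> MCNResult:
    """Run the full array-intensity MCN pipeline and return the estimates.

    Composes LRR computation, GC correction, HQ marker selection, autosomal
    PCA, mitochondrial adjustment, extraction/standardization and sample
    QC; per-stage marker/sample counts are collected in
    ``result.stage_report``. Estimation itself uses all samples; QC flags
    mark which estimates should enter downstream association analyses.
    Passing ``depths`` adds a ``wgs_mcn`` column to the result table.
    """
    markers = markers if markers is not None else intensity.markers
    if genotypes.sample_ids != intensity.sample_ids:
        raise PipelineError("inputs: genotype and intensity sample ids differ")
    report: list[dict] = []

    def stage(name: str, n_markers: int, n_samples: int, note: str = "") -> None:
        report.append(dict(stage=name, n_markers=n_markers, n_samples=n_samples, note=note))

    stage("input", intensity.n_markers, intensity.n_samples)
    lrr = compute_lrr(intensity)
    stage("compute_lrr", lrr.n_markers, lrr.n_samples)
    if gc_correction:
        lrr, gc_model = gc_correct(lrr, markers=markers, degree=gc_degree)
        stage("gc_correct", lrr.n_markers, lrr.n_samples,
              f"skipped={len(gc_model.skipped)}")
    else:
        gc_model = None
    hq = select_hq_markers(
        genotypes, markers=genotypes.markers, target_auto_count=target_auto_count,
        min_call_rate=min_call_rate, min_hwe_p=min_hwe_p, r2_max=r2_max,
    )
    stage("select_hq_markers", len(hq["autosomal"]) + len(hq["mitochondrial"]),
          lrr.n_samples, f"auto={len(hq['autosomal'])} mito={len(hq['mitochondrial'])}")
    lrr_auto = lrr.subset_markers([m for m in hq["autosomal"] if m in lrr.marker_ids])
    lrr_mito = lrr.subset_markers([m for m in hq["mitochondrial"] if m in lrr.marker_ids])
    if lrr_mito.n_markers < 2:
        raise PipelineError("adjust_mito_lrr: fewer than 2 mitochondrial HQ markers with intensity")
    if n_pcs > 0:
        pcs, _pca = autosomal_pcs(lrr_auto, n_pcs=n_pcs)
        adjusted = adjust_mito_lrr(lrr_mito, pcs)
        stage("adjust_mito_lrr", adjusted.n_markers, adjusted.n_samples,
              f"n_pcs={pcs.shape[1]}")
    else:
        center = lrr_mito.lrr - np.nanmean(lrr_mito.lrr, axis=0)
        adjusted = LRRMatrix(lrr_mito.sample_ids, lrr_mito.markers, center)
        stage("adjust_mito_lrr", adjusted.n_markers, adjusted.n_samples, "n_pcs=0")
    result = extract_mcn(adjusted)
    stage("extract_mcn", adjusted.n_markers, adjusted.n_samples,
          f"evr={result.explained_variance_ratio:.3f}" if np.isfinite(result.explained_variance_ratio) else "evr=nan")
    flags = mcn_sample_qc(
        genotypes, lrr_auto, samples=samples, require_phenotypes=require_phenotypes,
    )
    stage("mcn_sample_qc", adjusted.n_markers, int(flags["passed"].sum()),
          f"failed={int((~flags['passed']).sum())}")
    result.flags = flags
    result.table = result.table.merge(
        flags.reset_index()[["sample_id", "passed", "reasons"]], on="sample_id"
    )
    if depths is not None:
        d = depths.set_index("sample_id").loc[result.table["sample_id"]]
        result.table["wgs_mcn"] = wgs_mcn(
            d["autosomal_depth"].to_numpy(), d["mito_depth"].to_numpy()
        )
    result.stage_report = pd.DataFrame(report)
    return result


# ---------------------------------------------------------------------------
# sklearn-style estimators


class GCWaveCorrector(TransformerMixin, BaseEstimator):
    """Per-sample quadratic GC-wave correction as a transformer.

    fit(X, gc=..., autosomal=...) learns per-row regression coefficients of
    X (samples x markers) on the centered GC design over the autosomal
    columns; transform subtracts the fitted effect. Because the fit is
    per-sample, transform applies to the same rows that were fitted.
    """

    def __init__(self, degree: int = 2, min_markers: int = 10):
        self.degree = degree
        self.min_markers = min_markers

    def fit(self, X, y=None, *, gc, autosomal=None):
        X = np.asarray(X, float)
        gc = np.asarray(gc, float)
        autosomal = np.ones(X.shape[1], bool) if autosomal is None else np.asarray(autosomal, bool)
        lrr = LRRMatrix(
            [f"s{i}" for i in range(X.shape[0])],
            _minimal_manifest(X.shape[1], gc, autosomal),
            X,
        )
        corrected, model = gc_correct(lrr, degree=self.degree, min_markers=self.min_markers)
        self.coef_ = model.coefficients.to_numpy()
        self.gc_means_ = model.gc_means
        self.skipped_ = model.skipped
        self._corrected = corrected.lrr
        return self

    def transform(self, X):
        if not hasattr(self, "coef_"):
            raise RuntimeError("GCWaveCorrector is not fitted")
        return self._corrected

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, **fit_params).transform(X)


class PCConfounderAdjuster(TransformerMixin, BaseEstimator):
    """Residualize target columns on the top PCs of a reference matrix.

    fit(X) runs PCA on the reference (autosomal LRR) matrix and stores the
    per-sample scores; transform(Y) returns the residuals of each column
    of Y (mitochondrial LRR, same rows) regressed on those scores plus an
    intercept.
    """

    def __init__(self, n_pcs: int = 80):
        self.n_pcs = n_pcs

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        lrr = LRRMatrix(
            [f"s{i}" for i in range(X.shape[0])],
            _minimal_manifest(X.shape[1]),
            X,
        )
        self.scores_, pca = autosomal_pcs(lrr, n_pcs=self.n_pcs)
        self.components_ = pca.components_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        return self

    def transform(self, Y):
        if not hasattr(self, "scores_"):
            raise RuntimeError("PCConfounderAdjuster is not fitted")
        Y = np.asarray(Y, float)
        lrr = LRRMatrix(
            [f"s{i}" for i in range(Y.shape[0])],
            _minimal_manifest(Y.shape[1], chromosome="MT", position0=1),
            Y,
        )
        return adjust_mito_lrr(lrr, self.scores_).lrr


class MCNEstimator(BaseEstimator):
    """Full MCN pipeline with an sklearn-style interface.

    Parameters mirror :func:`run_mcn_pipeline`. After ``fit(intensity,
    genotypes=...)`` the estimates live in ``mcn_`` (standard-normal
    scale), ``raw_score_``, ``flags_`` and ``stage_report_``.
    """

    def __init__(
        self,
        n_pcs: int = 80,
        gc_degree: int = 2,
        target_auto_count: int | None = None,
        r2_max: float = 0.3,
        min_call_rate: float = 0.95,
        min_hwe_p: float = 1e-6,
        gc_correction: bool = True,
    ):
        self.n_pcs = n_pcs
        self.gc_degree = gc_degree
        self.target_auto_count = target_auto_count
        self.r2_max = r2_max
        self.min_call_rate = min_call_rate
        self.min_hwe_p = min_hwe_p
        self.gc_correction = gc_correction

    def fit(
        self,
        intensity: IntensityMatrix,
        y=None,
        *,
        genotypes: GenotypeMatrix,
        markers: pd.DataFrame | None = None,
        samples: pd.DataFrame | None = None,
        depths: pd.DataFrame | None = None,
    ):
        result = run_mcn_pipeline(
            genotypes, intensity, markers=markers, samples=samples, depths=depths,
            n_pcs=self.n_pcs, gc_degree=self.gc_degree,
            target_auto_count=self.target_auto_count, r2_max=self.r2_max,
            min_call_rate=self.min_call_rate, min_hwe_p=self.min_hwe_p,
            gc_correction=self.gc_correction,
        )
        self.result_ = result
        self.mcn_ = result.table["mcn"].to_numpy()
        self.raw_score_ = result.table["raw_score"].to_numpy()
        self.sample_ids_ = result.table["sample_id"].tolist()
        self.flags_ = result.flags
        self.stage_report_ = result.stage_report
        self.explained_variance_ratio_ = result.explained_variance_ratio
        return self

    def fit_predict(self, intensity, y=None, **kwargs):
        return self.fit(intensity, **kwargs).mcn_


def _minimal_manifest(
    n: int, gc: np.ndarray | None = None, autosomal: np.ndarray | None = None,
    chromosome: str = "1", position0: int = 1,
) -> pd.DataFrame:
    chrom = np.full(n, chromosome, dtype=object)
    if autosomal is not None:
        chrom = np.where(np.asarray(autosomal, bool), "1", "MT")
    return pd.DataFrame(
        dict(
            marker_id=[f"m{j}" for j in range(n)],
            chromosome=chrom,
            position=np.arange(position0, position0 + n),
            ref_allele="A",
            alt_allele="G",
            gc_fraction=gc if gc is not None else np.nan,
        )
    )
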