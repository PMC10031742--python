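"""Synthetic genotyping datasets with known ground-truth copy number.

Every pipeline stage in this package can be exercised without any external
download: the generator emits an LD-structured haplotype panel, diploid
genotypes, a probe-intensity matrix whose mitochondrial signal encodes a
known true mitochondrial copy number (MCN), shared batch effects and GC
waves, WGS depth pairs, and phenotypes linearly coupled to the true MCN.

Generative model
----------------
* Haplotypes: a two-founder copying process. The two founders are
  complementary at every marker; each haplotype copies one founder and,
  independently at each marker with probability ``ld_decay``, redraws which
  founder it copies. ``ld_decay = 0`` reproduces the founders exactly
  (complete LD); ``ld_decay = 1`` gives independent markers.
* True MCN: ``2 * 2**Normal(0, mcn_log_sd)`` (2 = reference diploid-scale
  copy number).
* Latent LRR (before intensities):
  autosomal   ``batch_shift + gc_wave_amp * (gc - mean gc) + N(0, noise_sd)``
  mitochondrial ``mito_signal_slope * log2(mcn/2) + batch_shift + N(0, noise_sd)``
  Intensity is ``R_base * 2**lrr`` with a per-marker baseline ``R_base``.
* WGS depths: autosomal ``Normal(30, 3)`` truncated positive; mitochondrial
  ``auto_depth * (mcn/2) * exp(Normal(0, depth_noise))``.
* Phenotypes: ``effect * z(true MCN) + Normal(0, 1)``, shifted/scaled to
  realistic clinical units (affine, so rank statistics are unchanged).

All randomness flows through one ``numpy.random.default_rng`` (PCG64)
instance seeded from ``cfg.seed``: identical config + seed gives
bit-identical output on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import (
    GenotypeMatrix,
    HaplotypePanel,
    IntensityMatrix,
    validate_samples,
)

#: realistic offsets/scales used to place phenotypes on clinical units
_PHENO_UNITS = {
    "age": (70.0, 6.0),     # years
    "WBC": (6.0, 1.5),      # 10^9 / L
    "HEMO": (135.0, 12.0),  # g / L
    "PLT": (220.0, 50.0),   # 10^9 / L
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults are the package's reference conditions: 500 samples, 2000
    autosomal markers over 4 chromosomes plus 200 mitochondrial markers,
    4 batches with LRR shifts of SD 0.2, residual probe noise SD 0.1,
    true copy number varying with log2-SD 0.25 and unit signal slope.
    """

    n_samples: int = 500
    n_auto_markers: int = 2000
    n_mito_markers: int = 200
    n_chromosomes: int = 4
    ld_decay: float = 0.1
    maf_floor: float = 0.05
    n_batches: int = 4
    batch_sd: float = 0.2
    gc_wave_amp: float = 0.2
    gc_wave_on_mito: bool = False
    mcn_log_sd: float = 0.25
    mito_signal_slope: float = 1.0
    noise_sd: float = 0.1
    depth_noise: float = 0.05
    pheno_effects: dict = field(
        default_factory=lambda: {"age": -0.3, "WBC": 0.3, "HEMO": 0.2, "PLT": 0.3}
    )
    n_x_markers: int = 0
    n_y_markers: int = 0
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_auto_markers", "n_mito_markers", "n_chromosomes", "n_batches"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.ld_decay <= 1:
            raise ValueError("ld_decay must be a probability")
        if not 0 <= self.maf_floor < 0.5:
            raise ValueError("maf_floor must be in [0, 0.5)")
        for name in ("batch_sd", "gc_wave_amp", "mcn_log_sd", "mito_signal_slope",
                     "noise_sd", "depth_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class SimulationTruth:
    """Ground truth hidden from the pipeline."""

    true_mcn: np.ndarray
    batch_label: np.ndarray
    true_sex: np.ndarray

    def to_frame(self, sample_ids: list[str]) -> pd.DataFrame:
        return pd.DataFrame(
            dict(sample_id=sample_ids, true_mcn=self.true_mcn,
                 batch_label=self.batch_label, true_sex=self.true_sex)
        )


@dataclass
class SimulatedDataset:
    panel: HaplotypePanel
    genotypes: GenotypeMatrix
    intensity: IntensityMatrix
    markers: pd.DataFrame
    samples: pd.DataFrame
    depths: pd.DataFrame
    truth: SimulationTruth


_NUCS = np.array(list("ACGT"))


def _auto_marker_manifest(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    per = np.full(cfg.n_chromosomes, cfg.n_auto_markers // cfg.n_chromosomes)
    per[: cfg.n_auto_markers % cfg.n_chromosomes] += 1
    rows = []
    k = 0
    for c in range(cfg.n_chromosomes):
        gaps = rng.integers(1_000, 10_001, size=per[c])
        pos = np.cumsum(gaps)
        for p in pos:
            ref, alt = rng.choice(4, size=2, replace=False)
            rows.append(
                dict(marker_id=f"A{k:06d}", chromosome=str(c + 1), position=int(p),
                     ref_allele=_NUCS[ref], alt_allele=_NUCS[alt],
                     gc_fraction=float(rng.uniform(0.30, 0.70)))
            )
            k += 1
    return pd.DataFrame(rows)


def simulate_panel(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    markers: pd.DataFrame | None = None,
) -> HaplotypePanel:
    """Phased haplotypes for ``2 * n_samples`` chromosomes under the
    two-founder copying process (see module docstring).

    Within each chromosome the copy state is redrawn with probability
    ``ld_decay`` per marker, giving adjacent-marker correlation
    (1 - ld_decay) per step. Markers whose empirical frequency falls below
    ``maf_floor`` get minor alleles planted by flipping random haplotypes.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    markers = markers if markers is not None else _auto_marker_manifest(cfg, rng)
    n_hap = 2 * cfg.n_samples
    n_markers = len(markers)
    founder_a = rng.integers(0, 2, size=n_markers, dtype=np.int8)
    chrom = markers["chromosome"].to_numpy()
    new_chrom = np.r_[True, chrom[1:] != chrom[:-1]]
    redraw = rng.random((n_hap, n_markers)) < cfg.ld_decay
    redraw[:, new_chrom] = True
    draws = rng.integers(0, 2, size=(n_hap, n_markers), dtype=np.int8)
    state = np.empty((n_hap, n_markers), dtype=np.int8)
    prev = draws[:, 0]
    for j in range(n_markers):
        prev = np.where(redraw[:, j], draws[:, j], prev)
        state[:, j] = prev
    haps = np.where(state == 1, founder_a, 1 - founder_a).astype(np.int8)
    # enforce the MAF floor by planting minor alleles where needed
    if cfg.maf_floor > 0:
        need = int(np.ceil(cfg.maf_floor * n_hap))
        freq = haps.sum(axis=0)
        for j in np.flatnonzero((freq < need) | (n_hap - freq < need)):
            minor = 1 if freq[j] < need else 0
            carriers = np.flatnonzero(haps[:, j] != minor)
            flip = rng.choice(carriers, size=need - (n_hap - len(carriers)), replace=False)
            haps[flip, j] = minor
    return HaplotypePanel(markers.reset_index(drop=True), haps)


def _mito_manifest(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    pos = np.sort(rng.choice(np.arange(1, 16570), size=cfg.n_mito_markers, replace=False))
    rows = []
    for k, p in enumerate(pos):
        ref, alt = rng.choice(4, size=2, replace=False)
        rows.append(
            dict(marker_id=f"M{k:04d}", chromosome="MT", position=int(p),
                 ref_allele=_NUCS[ref], alt_allele=_NUCS[alt],
                 gc_fraction=float(rng.uniform(0.40, 0.48)))
        )
    return pd.DataFrame(rows)


def _sex_manifest(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for k in range(cfg.n_x_markers):
        ref, alt = rng.choice(4, size=2, replace=False)
        rows.append(
            dict(marker_id=f"X{k:04d}", chromosome="X",
                 position=int(rng.integers(1, 155_000_000)),
                 ref_allele=_NUCS[ref], alt_allele=_NUCS[alt],
                 gc_fraction=float(rng.uniform(0.30, 0.70)))
        )
    for k in range(cfg.n_y_markers):
        ref, alt = rng.choice(4, size=2, replace=False)
        rows.append(
            dict(marker_id=f"Y{k:04d}", chromosome="Y",
                 position=int(rng.integers(1, 57_000_000)),
                 ref_allele=_NUCS[ref], alt_allele=_NUCS[alt],
                 gc_fraction=float(rng.uniform(0.30, 0.70)))
        )
    df = pd.DataFrame(rows, columns=["marker_id", "chromosome", "position",
                                     "ref_allele", "alt_allele", "gc_fraction"])
    return df.sort_values(["chromosome", "position"]).reset_index(drop=True)


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate a complete synthetic cohort (see module docstring).

    Returns panel, genotypes (autosomal + mitochondrial + optional X/Y),
    intensity matrix, marker manifest, sample table with phenotypes, WGS
    depth pairs and the hidden :class:`SimulationTruth`.
    """
    rng = np.random.default_rng(cfg.seed)
    sample_ids = [f"S{i:04d}" for i in range(cfg.n_samples)]
    panel = simulate_panel(cfg, rng=rng)
    auto_markers = panel.markers
    mito_markers = _mito_manifest(cfg, rng)
    sex_markers = _sex_manifest(cfg, rng)

    true_sex = np.where(rng.random(cfg.n_samples) < 0.5, "female", "male")
    batch_label = np.repeat(np.arange(cfg.n_batches), -(-cfg.n_samples // cfg.n_batches))[: cfg.n_samples]
    batch_shift_values = rng.normal(0.0, cfg.batch_sd, size=cfg.n_batches)
    batch_shift = batch_shift_values[batch_label]
    true_mcn = 2.0 * 2.0 ** rng.normal(0.0, cfg.mcn_log_sd, size=cfg.n_samples)

    # genotypes: autosomal from haplotype pairs; mitochondrial homoplasmic;
    # X haploid in males (coded 0/2), Y present in males only
    auto_calls = (panel.haplotypes[0::2] + panel.haplotypes[1::2]).astype(float)
    mito_freq = rng.uniform(0.1, 0.9, size=cfg.n_mito_markers)
    mito_calls = 2.0 * (rng.random((cfg.n_samples, cfg.n_mito_markers)) < mito_freq)
    sex_calls = np.empty((cfg.n_samples, len(sex_markers)))
    if len(sex_markers):
        is_x = (sex_markers["chromosome"] == "X").to_numpy()
        freq = rng.uniform(0.2, 0.8, size=len(sex_markers))
        male = true_sex == "male"
        for j in range(len(sex_markers)):
            if is_x[j]:
                a1 = rng.random(cfg.n_samples) < freq[j]
                a2 = rng.random(cfg.n_samples) < freq[j]
                col = np.where(male, 2.0 * a1, (a1 + a2).astype(float))
            else:
                col = np.where(male, 2.0 * (rng.random(cfg.n_samples) < freq[j]), np.nan)
            sex_calls[:, j] = col

    frames = [f for f in (auto_markers, sex_markers, mito_markers) if len(f)]
    markers = pd.concat(frames, ignore_index=True)
    markers["is_mitochondrial"] = markers["chromosome"] == "MT"
    markers["off_target"] = False
    calls = np.hstack([auto_calls, sex_calls, mito_calls])
    genotypes = GenotypeMatrix(sample_ids, markers, calls)

    # latent LRR -> intensity
    gc_auto = auto_markers["gc_fraction"].to_numpy()
    gc_mito = mito_markers["gc_fraction"].to_numpy()
    lrr_auto = (
        batch_shift[:, None]
        + cfg.gc_wave_amp * (gc_auto - gc_auto.mean())[None, :]
        + rng.normal(0.0, cfg.noise_sd, size=auto_calls.shape)
    )
    lrr_mito = (
        cfg.mito_signal_slope * np.log2(true_mcn / 2.0)[:, None]
        + batch_shift[:, None]
        + rng.normal(0.0, cfg.noise_sd, size=mito_calls.shape)
    )
    if cfg.gc_wave_on_mito:
        lrr_mito = lrr_mito + cfg.gc_wave_amp * (gc_mito - gc_auto.mean())[None, :]
    lrr_sexchr = rng.normal(0.0, cfg.noise_sd, size=sex_calls.shape) + batch_shift[:, None]
    r_base = rng.uniform(80.0, 120.0, size=len(markers))
    lrr_all = np.hstack([lrr_auto, lrr_sexchr, lrr_mito])
    intensity = IntensityMatrix(sample_ids, markers, r_base[None, :] * 2.0**lrr_all)

    # WGS depth pairs
    auto_depth = np.clip(rng.normal(30.0, 3.0, size=cfg.n_samples), 1e-3, None)
    mito_depth = auto_depth * (true_mcn / 2.0) * np.exp(rng.normal(0.0, cfg.depth_noise, cfg.n_samples))
    depths = pd.DataFrame(
        dict(sample_id=sample_ids, autosomal_depth=auto_depth, mito_depth=mito_depth)
    )

    # phenotypes linear in standardized true MCN
    log_mcn = np.log2(true_mcn)
    z = (log_mcn - log_mcn.mean()) / log_mcn.std()
    pheno = {"sample_id": sample_ids, "reported_sex": true_sex}
    for name, effect in cfg.pheno_effects.items():
        raw = effect * z + rng.normal(0.0, 1.0, size=cfg.n_samples)
        loc, scale = _PHENO_UNITS.get(name, (0.0, 1.0))
        pheno[name] = loc + scale * raw
    samples = validate_samples(pd.DataFrame(pheno))

    return SimulatedDataset(
        panel=panel,
        genotypes=genotypes,
        intensity=intensity,
        markers=genotypes.markers,
        samples=samples,
        depths=depths,
        truth=SimulationTruth(true_mcn=true_mcn, batch_label=batch_label, true_sex=true_sex),
    )


def write_dataset(ds: SimulatedDataset, out_dir) -> None:
    """Emit the file bundle used by the command-line interface."""
    from pathlib import Path

    from . import io as _io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _io.write_haplotypes_vcf(ds.panel, out / "panel.vcf")
    _io.write_genotypes_vcf(ds.genotypes, out / "genotypes.vcf")
    _io.write_table(ds.intensity, out / "intensity.tsv", "intensity")
    _io.write_table(ds.markers, out / "markers.tsv", "markers")
    _io.write_table(ds.samples, out / "samples.tsv", "samples")
    _io.write_table(ds.depths, out / "depths.tsv", "depths")
    ds.truth.to_frame(ds.genotypes.sample_ids).to_csv(out / "truth.tsv", sep="\t", index=False)
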