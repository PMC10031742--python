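"""Core in-memory containers for array genotyping data.

All containers use 1-based inclusive genomic coordinates (VCF convention).
Genotypes are alt-allele counts in {0, 1, 2}; dosages are expected
alt-allele counts in [0, 2]. Missing is a first-class value everywhere and
is represented as NaN in float matrices; every downstream statistic defines
its denominator over non-missing entries.

A marker manifest ("MarkerSet") is a :class:`pandas.DataFrame` with the
columns listed in :data:`MARKER_COLUMNS`, validated by
:func:`validate_markers`. Using a plain DataFrame keeps the manifest open
to extra annotation columns, which are carried through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

AUTOSOMES = tuple(str(c) for c in range(1, 23))
VALID_CHROMOSOMES = AUTOSOMES + ("X", "Y", "MT")

MARKER_COLUMNS = (
    "marker_id",
    "chromosome",
    "position",
    "ref_allele",
    "alt_allele",
    "gc_fraction",
    "is_mitochondrial",
    "off_target",
)


class SchemaError(ValueError):
    """An input table or matrix violates its documented schema."""


def validate_markers(markers: pd.DataFrame) -> pd.DataFrame:
    """Validate a marker manifest and return it with normalised dtypes.

    Required columns: marker_id, chromosome, position, ref_allele,
    alt_allele. Optional columns gc_fraction (NaN allowed),
    is_mitochondrial and off_target are filled with defaults when absent
    (is_mitochondrial derived from chromosome == "MT").
    """
    df = markers.copy()
    for col in ("marker_id", "chromosome", "position", "ref_allele", "alt_allele"):
        if col not in df.columns:
            raise SchemaError(f"marker table is missing mandatory column {col!r}")
    df["marker_id"] = df["marker_id"].astype(str)
    df["chromosome"] = df["chromosome"].astype(str)
    if df["marker_id"].duplicated().any():
        dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
        raise SchemaError(f"duplicated marker_id {dup!r}")
    bad_chrom = ~df["chromosome"].isin(VALID_CHROMOSOMES)
    if bad_chrom.any():
        raise SchemaError(
            f"invalid chromosome {df.loc[bad_chrom, 'chromosome'].iloc[0]!r}; "
            f"expected one of 1..22, X, Y, MT"
        )
    df["position"] = _numeric(df["position"], "position").astype(np.int64)
    if (df["position"] < 1).any():
        raise SchemaError("position must be >= 1 (coordinates are 1-based)")
    if (df["ref_allele"].astype(str) == df["alt_allele"].astype(str)).any():
        raise SchemaError("ref_allele must differ from alt_allele")
    if "gc_fraction" in df.columns:
        gc = _numeric(df["gc_fraction"], "gc_fraction").astype(float)
        finite = gc.dropna()
        if ((finite < 0) | (finite > 1)).any():
            raise SchemaError("gc_fraction must lie in [0, 1]")
        df["gc_fraction"] = gc
    else:
        df["gc_fraction"] = np.nan
    if "is_mitochondrial" in df.columns:
        df["is_mitochondrial"] = _boolify(df["is_mitochondrial"])
        if (df["is_mitochondrial"] != (df["chromosome"] == "MT")).any():
            raise SchemaError("is_mitochondrial must be equivalent to chromosome == 'MT'")
    else:
        df["is_mitochondrial"] = df["chromosome"] == "MT"
    if "off_target" in df.columns:
        df["off_target"] = _boolify(df["off_target"])
    else:
        df["off_target"] = False
    return df.reset_index(drop=True)


def _numeric(series: pd.Series, name: str) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna()
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(f"non-numeric value {series.iloc[idx]!r} in column {name!r} at row {idx}")
    return out


def _boolify(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "t": True, "f": False, "yes": True, "no": False,
    }
    out = series.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        idx = int(np.flatnonzero(out.isna().to_numpy())[0])
        raise SchemaError(f"cannot interpret {series.iloc[idx]!r} as a boolean at row {idx}")
    return out.astype(bool)


@dataclass
class _SampleByMarker:
    """Common validation for sample x marker matrices."""

    sample_ids: list[str]
    markers: pd.DataFrame
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SchemaError("duplicate sample ids")
        self.markers = validate_markers(self.markers)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.markers)):
            raise SchemaError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.markers)} markers"
            )

    @property
    def marker_ids(self) -> list[str]:
        return self.markers["marker_id"].tolist()

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.marker_ids)

    def subset_markers(self, marker_ids: Sequence[str]):
        wanted = list(marker_ids)
        pos = {m: i for i, m in enumerate(self.marker_ids)}
        missing = [m for m in wanted if m not in pos]
        if missing:
            raise KeyError(f"unknown marker ids: {missing[:5]}")
        idx = [pos[m] for m in wanted]
        return type(self)(
            self.sample_ids,
            self.markers.iloc[idx].reset_index(drop=True),
            self.values[:, idx],
        )


@dataclass
class GenotypeMatrix(_SampleByMarker):
    """Hard genotype calls: alt-allele counts {0,1,2}, NaN = missing."""

    def __post_init__(self) -> None:
        super().__post_init__()
        finite = self.values[np.isfinite(self.values)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise SchemaError("genotype calls must be in {0, 1, 2} or missing")

    @property
    def calls(self) -> np.ndarray:
        return self.values


@dataclass
class DosageMatrix(_SampleByMarker):
    """Continuous expected alt-allele dosages in [0, 2], NaN = missing."""

    def __post_init__(self) -> None:
        super().__post_init__()
        finite = self.values[np.isfinite(self.values)]
        if finite.size and ((finite < 0) | (finite > 2)).any():
            raise SchemaError("dosages must lie in [0, 2] or be missing")

    @property
    def dosages(self) -> np.ndarray:
        return self.values


@dataclass
class IntensityMatrix(_SampleByMarker):
    """Total probe intensity R per sample and marker (nonnegative)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite < 0).any():
            raise SchemaError("intensities must be nonnegative")

    @property
    def signal(self) -> np.ndarray:
        return self.values


@dataclass
class LRRMatrix(_SampleByMarker):
    """Log R ratios (log2 observed/expected intensity), NaN = missing."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.isinf(self.values).any():
            raise SchemaError("LRR values must be finite where not missing")

    @property
    def lrr(self) -> np.ndarray:
        return self.values


@dataclass
class HaplotypePanel:
    """Phased reference haplotypes: 2n rows of {0,1} alleles.

    Row 2i and 2i+1 are the two haplotypes of sample i.
    """

    markers: pd.DataFrame
    haplotypes: np.ndarray = field(repr=False)
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.markers = validate_markers(self.markers)
        self.haplotypes = np.asarray(self.haplotypes)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] % 2:
            raise SchemaError("haplotypes must be a 2D array with an even number of rows")
        if self.haplotypes.shape[1] != len(self.markers):
            raise SchemaError("haplotype columns do not match marker count")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise SchemaError("haplotype alleles must be 0 or 1")
        if self.sample_ids is None:
            self.sample_ids = [f"S{i:04d}" for i in range(self.haplotypes.shape[0] // 2)]
        if 2 * len(self.sample_ids) != self.haplotypes.shape[0]:
            raise SchemaError("sample_ids must number half the haplotype rows")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    def to_genotypes(self) -> GenotypeMatrix:
        """Collapse phased haplotype pairs to diploid alt-allele counts."""
        calls = self.haplotypes[0::2] + self.haplotypes[1::2]
        return GenotypeMatrix(list(self.sample_ids), self.markers, calls.astype(float))

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


PHENOTYPE_COLUMNS = ("age", "WBC", "HEMO", "PLT")


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample table: sample_id, reported_sex, phenotype columns.

    reported_sex is normalised to {"male", "female", "unknown"}; phenotype
    columns are coerced to float with NaN for missing.
    """
    df = samples.copy()
    if "sample_id" not in df.columns:
        raise SchemaError("sample table is missing mandatory column 'sample_id'")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        raise SchemaError("duplicate sample_id in sample table")
    if "reported_sex" in df.columns:
        sex = df["reported_sex"].astype(str).str.strip().str.lower()
        valid = {"male", "female", "unknown", "nan", ""}
        bad = ~sex.isin(valid)
        if bad.any():
            raise SchemaError(f"invalid reported_sex {df.loc[bad, 'reported_sex'].iloc[0]!r}")
        df["reported_sex"] = sex.replace({"nan": "unknown", "": "unknown"})
    else:
        df["reported_sex"] = "unknown"
    for col in df.columns:
        if col in ("sample_id", "reported_sex"):
            continue
        if col in PHENOTYPE_COLUMNS:
            df[col] = _numeric(df[col], col).astype(float)
    return df.reset_index(drop=True)
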