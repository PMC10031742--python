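"""Readers and writers for VCF genotype/dosage files and TSV tables.

VCF handling is biallelic-SNP only: multi-allelic records are rejected
rather than split, because every downstream statistic (MAF, HWE, LD,
dosage r2) is defined on a single alternate allele. Reading goes through
cyvcf2; writing emits plain VCF 4.2 text.

Tab-separated tables use a documented header per ``kind``:

* ``markers``:   marker_id chromosome position ref_allele alt_allele
                 [gc_fraction is_mitochondrial off_target ...]
* ``samples``:   sample_id [reported_sex age WBC HEMO PLT ...]
* ``intensity``/``lrr``: sample_id followed by one column per marker
* ``depths``:    sample_id autosomal_depth mito_depth
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import (
    DosageMatrix,
    GenotypeMatrix,
    HaplotypePanel,
    IntensityMatrix,
    LRRMatrix,
    SchemaError,
    validate_markers,
    validate_samples,
)

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)
_DS_HEADER = '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">\n'


def _marker_frame(records: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame.from_records(
        records,
        columns=["marker_id", "chromosome", "position", "ref_allele", "alt_allele"],
    )
    return validate_markers(df)


def read_genotypes_vcf(
    path: str | Path, dosage_field: str | None = None
) -> GenotypeMatrix | tuple[GenotypeMatrix, DosageMatrix]:
    """Read a biallelic VCF into a :class:`GenotypeMatrix`.

    GT is mapped to alt-allele counts {0,1,2}; any missing allele gives a
    missing call. With ``dosage_field`` (a per-genotype FORMAT key such as
    "DS") a :class:`DosageMatrix` is returned as well.
    """
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare Exceptions on bad files
        raise SchemaError(f"cannot open VCF {path!r}: {exc}") from exc
    sample_ids = list(vcf.samples)
    records, call_rows, dose_rows = [], [], []
    seen: set[str] = set()
    for lineno, var in enumerate(vcf, start=1):
        if len(var.ALT) != 1:
            raise SchemaError(
                f"{path}: record {lineno} ({var.CHROM}:{var.POS}) is not biallelic; "
                "multi-allelic records are rejected, not split"
            )
        mid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}:{var.REF}:{var.ALT[0]}"
        if mid in seen:
            raise SchemaError(f"{path}: duplicated marker_id {mid!r} at record {lineno}")
        seen.add(mid)
        records.append(
            dict(
                marker_id=mid,
                chromosome=var.CHROM.removeprefix("chr"),
                position=var.POS,
                ref_allele=var.REF,
                alt_allele=var.ALT[0],
            )
        )
        row = np.full(len(sample_ids), np.nan)
        for i, g in enumerate(var.genotypes):
            alleles = g[:-1]
            if any(a < 0 for a in alleles):
                continue
            row[i] = float(sum(alleles))
        call_rows.append(row)
        if dosage_field is not None:
            fmt = var.format(dosage_field)
            if fmt is None:
                dose_rows.append(np.full(len(sample_ids), np.nan))
            else:
                d = np.asarray(fmt, dtype=float).reshape(len(sample_ids), -1)[:, 0]
                d = np.where(np.isfinite(d) & (d >= -1e9), d, np.nan)
                dose_rows.append(d)
    markers = _marker_frame(records)
    calls = (
        np.asarray(call_rows).T if call_rows else np.empty((len(sample_ids), 0))
    )
    geno = GenotypeMatrix(sample_ids, markers, calls)
    if dosage_field is None:
        return geno
    doses = np.asarray(dose_rows).T if dose_rows else np.empty((len(sample_ids), 0))
    return geno, DosageMatrix(sample_ids, markers, doses)


def _gt_string(call: float) -> str:
    if not math.isfinite(call):
        return "./."
    return {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}[call]


def write_genotypes_vcf(
    g: GenotypeMatrix,
    path: str | Path,
    dosages: DosageMatrix | None = None,
) -> None:
    """Write a :class:`GenotypeMatrix` as an unphased diploid VCF 4.2 file."""
    fmt = "GT" if dosages is None else "GT:DS"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_VCF_HEADER)
        if dosages is not None:
            fh.write(_DS_HEADER)
        cols = "\t".join(["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"] + g.sample_ids)
        fh.write(cols + "\n")
        m = g.markers
        for j in range(g.n_markers):
            fields = [
                m.at[j, "chromosome"],
                str(int(m.at[j, "position"])),
                m.at[j, "marker_id"],
                m.at[j, "ref_allele"],
                m.at[j, "alt_allele"],
                ".",
                "PASS",
                ".",
                fmt,
            ]
            for i in range(g.n_samples):
                gt = _gt_string(g.calls[i, j])
                if dosages is not None:
                    d = dosages.dosages[i, j]
                    gt += ":" + (f"{d:.6g}" if math.isfinite(d) else ".")
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")


def write_haplotypes_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a phased haplotype panel as a VCF with phased GT (0|1)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_VCF_HEADER)
        cols = "\t".join(
            ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
            + list(panel.sample_ids)
        )
        fh.write(cols + "\n")
        m = panel.markers
        h = panel.haplotypes
        for j in range(len(m)):
            fields = [
                m.at[j, "chromosome"],
                str(int(m.at[j, "position"])),
                m.at[j, "marker_id"],
                m.at[j, "ref_allele"],
                m.at[j, "alt_allele"],
                ".",
                "PASS",
                ".",
                "GT",
            ]
            fields += [f"{h[2 * i, j]}|{h[2 * i + 1, j]}" for i in range(len(panel.sample_ids))]
            fh.write("\t".join(fields) + "\n")


def read_haplotypes_vcf(path: str | Path) -> HaplotypePanel:
    """Read a phased VCF into a :class:`HaplotypePanel` (2n x markers)."""
    path = str(path)
    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    records, hap_cols = [], []
    for lineno, var in enumerate(vcf, start=1):
        if len(var.ALT) != 1:
            raise SchemaError(f"{path}: record {lineno} is not biallelic")
        records.append(
            dict(
                marker_id=var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}",
                chromosome=var.CHROM.removeprefix("chr"),
                position=var.POS,
                ref_allele=var.REF,
                alt_allele=var.ALT[0],
            )
        )
        col = np.empty(2 * len(sample_ids), dtype=np.int8)
        for i, g in enumerate(var.genotypes):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                raise SchemaError(f"{path}: missing allele in phased panel at record {lineno}")
            col[2 * i], col[2 * i + 1] = a, b
        hap_cols.append(col)
    markers = _marker_frame(records)
    haps = np.asarray(hap_cols).T if hap_cols else np.empty((2 * len(sample_ids), 0), dtype=np.int8)
    return HaplotypePanel(markers, haps, sample_ids=sample_ids)


# ---------------------------------------------------------------------------
# TSV tables

TABLE_KINDS = ("markers", "samples", "intensity", "lrr", "depths")


def read_table(path: str | Path, kind: str):
    """Read a TSV of the given ``kind`` into its typed container.

    Unknown columns in marker/sample tables are preserved as opaque
    metadata. Any schema violation raises :class:`SchemaError`.
    """
    if kind not in TABLE_KINDS:
        raise ValueError(f"unknown table kind {kind!r}; expected one of {TABLE_KINDS}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if kind == "markers":
        return validate_markers(df)
    if kind == "samples":
        out = df.copy()
        for col in out.columns:
            if col not in ("sample_id", "reported_sex"):
                out[col] = _try_float(out[col], col)
        return validate_samples(out)
    if kind == "depths":
        for col in ("sample_id", "autosomal_depth", "mito_depth"):
            if col not in df.columns:
                raise SchemaError(f"depths table is missing mandatory column {col!r}")
        out = df[["sample_id", "autosomal_depth", "mito_depth"]].copy()
        out["autosomal_depth"] = _try_float(out["autosomal_depth"], "autosomal_depth")
        out["mito_depth"] = _try_float(out["mito_depth"], "mito_depth")
        return out
    # wide sample x marker matrices
    if df.columns[0] != "sample_id":
        raise SchemaError(f"{kind} table must start with a 'sample_id' column")
    sample_ids = df["sample_id"].astype(str).tolist()
    marker_ids = list(df.columns[1:])
    values = np.empty((len(sample_ids), len(marker_ids)))
    for j, col in enumerate(marker_ids):
        values[:, j] = _try_float(df[col], col)
    markers = _placeholder_markers(marker_ids)
    cls = IntensityMatrix if kind == "intensity" else LRRMatrix
    return cls(sample_ids, markers, values)


def _try_float(series: pd.Series, name: str) -> np.ndarray:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna() & (series.astype(str).str.strip() != "")
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(f"non-numeric value {series.iloc[idx]!r} in column {name!r} at row {idx}")
    return out.to_numpy(dtype=float)


def _placeholder_markers(marker_ids: list[str]) -> pd.DataFrame:
    """Minimal manifest when a wide matrix TSV carries only marker ids.

    Coordinates are unknown; callers attach a real manifest via
    :func:`attach_markers` before any position-aware step.
    """
    return pd.DataFrame(
        dict(
            marker_id=marker_ids,
            chromosome="1",
            position=np.arange(1, len(marker_ids) + 1),
            ref_allele="A",
            alt_allele="G",
        )
    )


def attach_markers(matrix, markers: pd.DataFrame):
    """Replace a matrix's placeholder manifest with a full one (id-matched)."""
    markers = validate_markers(markers)
    order = markers.set_index("marker_id")
    missing = [m for m in matrix.marker_ids if m not in order.index]
    if missing:
        raise SchemaError(f"manifest lacks markers: {missing[:5]}")
    new = order.loc[matrix.marker_ids].reset_index()
    return type(matrix)(matrix.sample_ids, new, matrix.values)


def write_table(obj, path: str | Path, kind: str) -> None:
    """Write the typed object back to TSV (inverse of :func:`read_table`)."""
    if kind in ("markers", "samples", "depths"):
        obj.to_csv(path, sep="\t", index=False)
        return
    if kind in ("intensity", "lrr"):
        df = obj.to_frame()
        df.insert(0, "sample_id", df.index)
        df.to_csv(path, sep="\t", index=False)
        return
    raise ValueError(f"unknown table kind {kind!r}")
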