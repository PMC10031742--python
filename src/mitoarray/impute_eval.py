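"""Genotyping / imputation accuracy metrics.

Harmonizes two marker sets (allele swap / strand flip reconciliation) and
scores an externally produced call set or dosage set against a truth set:
call rate, genotype concordance, per-marker dosage r2, best-guess
discordance, and imputation-based genomic coverage stratified by minor
allele frequency (common: MAF >= 0.05; low-frequency: 0.01 <= MAF < 0.05).

Coverage deliberately uses the strict inequality r2 > threshold, so a
marker sitting exactly at the threshold does not count as covered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
MAF_BIN_EDGES = (0.01, 0.02, 0.05, 0.1, 0.2, 0.5)


def _flip(allele: str) -> str | None:
    if len(allele) == 1:
        return _COMPLEMENT.get(allele.upper())
    comp = [_COMPLEMENT.get(b.upper()) for b in reversed(allele)]
    return None if None in comp else "".join(comp)


def _is_ambiguous(ref: str, alt: str) -> bool:
    return {ref.upper(), alt.upper()} in ({"A", "T"}, {"C", "G"})


@dataclass
class HarmonizedPair:
    """Per-marker harmonization actions between two marker sets.

    ``table`` has columns marker_id_a, marker_id_b, action with action in
    {exact, swapped, flipped, swapped+flipped, dropped_ambiguous,
    dropped_mismatch}. ``matched`` lists the (id_a, id_b) pairs kept.
    """

    table: pd.DataFrame = field(repr=False)

    @property
    def matched(self) -> pd.DataFrame:
        return self.table[~self.table["action"].str.startswith("dropped")]


def harmonize(
    a: pd.DataFrame, b: pd.DataFrame, drop_ambiguous: bool = True
) -> HarmonizedPair:
    """Match markers of manifest ``b`` to manifest ``a`` on (chromosome,
    position) and reconcile alleles.

    Reconciliation tries, in order: identity, ref/alt swap, strand flip,
    swap+flip. Strand-ambiguous (A/T, C/G) sites are dropped when
    ``drop_ambiguous`` because flip and swap are indistinguishable there.
    Swapped markers need their dosages re-expressed as 2 - d (see
    :func:`apply_action`).
    """
    a_by_locus: dict[tuple[str, int], tuple[str, str, str]] = {}
    for mid, c, p, r, alt in zip(
        a["marker_id"], a["chromosome"], a["position"], a["ref_allele"], a["alt_allele"]
    ):
        a_by_locus[(str(c), int(p))] = (mid, r.upper(), alt.upper())
    rows = []
    for mid, c, p, r, alt in zip(
        b["marker_id"], b["chromosome"], b["position"], b["ref_allele"], b["alt_allele"]
    ):
        hit = a_by_locus.get((str(c), int(p)))
        if hit is None:
            continue
        aid, ar, aa = hit
        r, alt = r.upper(), alt.upper()
        if drop_ambiguous and (_is_ambiguous(r, alt) or _is_ambiguous(ar, aa)):
            action = "dropped_ambiguous"
        elif (r, alt) == (ar, aa):
            action = "exact"
        elif (alt, r) == (ar, aa):
            action = "swapped"
        else:
            fr, fa = _flip(r), _flip(alt)
            if (fr, fa) == (ar, aa):
                action = "flipped"
            elif (fa, fr) == (ar, aa):
                action = "swapped+flipped"
            else:
                action = "dropped_mismatch"
        rows.append(dict(marker_id_a=aid, marker_id_b=mid, action=action))
    return HarmonizedPair(pd.DataFrame(rows, columns=["marker_id_a", "marker_id_b", "action"]))


def apply_action(values: np.ndarray, action: str) -> np.ndarray:
    """Re-express alt-allele counts/dosages of marker b on marker a's alleles."""
    if action in ("exact", "flipped"):
        return values
    if action in ("swapped", "swapped+flipped"):
        return 2.0 - values
    raise ValueError(f"cannot apply dropped action {action!r}")


# ---------------------------------------------------------------------------
# Accuracy statistics


def call_rate(designed: int, recommended: int) -> float:
    """Array call rate: recommended (passing) markers / designed markers."""
    if designed <= 0:
        raise ValueError("designed marker count must be positive")
    if not 0 <= recommended <= designed:
        raise ValueError("recommended must lie in [0, designed]")
    return recommended / designed


def concordance_rate(
    truth: GenotypeMatrix, test: GenotypeMatrix
) -> dict[str, object]:
    """Genotype concordance of ``test`` against ``truth``.

    Numerator: entries where both are non-missing and equal. Denominator:
    entries where both are non-missing (test-missing entries are excluded
    from both and reported separately as ``test_missing_fraction`` of the
    truth-non-missing entries). Returns the overall rate, per-sample rates
    and their mean.
    """
    if truth.sample_ids != test.sample_ids or truth.marker_ids != test.marker_ids:
        raise ValueError("matrices must be harmonized to identical samples and markers")
    t, x = truth.calls, test.calls
    t_ok = np.isfinite(t)
    both = t_ok & np.isfinite(x)
    agree = both & (t == x)
    denom = both.sum()
    per_sample_denom = both.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_sample = np.where(per_sample_denom > 0, agree.sum(axis=1) / per_sample_denom, np.nan)
    overall = agree.sum() / denom if denom else np.nan
    return {
        "concordance": float(overall) if denom else np.nan,
        "per_sample": pd.Series(per_sample, index=truth.sample_ids),
        "mean_per_sample": float(np.nanmean(per_sample)) if np.isfinite(per_sample).any() else np.nan,
        "test_missing_fraction": float((t_ok & ~np.isfinite(x)).sum() / t_ok.sum()) if t_ok.sum() else np.nan,
        "n_compared": int(denom),
    }


def imputation_r2(truth_dosage: np.ndarray, imputed_dosage: np.ndarray) -> float:
    """Squared Pearson correlation between truth and imputed allele dosages.

    Pairwise-complete; NaN when fewer than two complete pairs remain or
    either vector is constant on them.
    """
    t = np.asarray(truth_dosage, float)
    d = np.asarray(imputed_dosage, float)
    ok = np.isfinite(t) & np.isfinite(d)
    if ok.sum() < 2:
        return np.nan
    ts, ds = t[ok], d[ok]
    if np.ptp(ts) == 0 or np.ptp(ds) == 0:
        return np.nan
    r = np.corrcoef(ts, ds)[0, 1]
    return float(r * r)


def discordance_rate(truth: GenotypeMatrix, best_guess: GenotypeMatrix) -> float:
    """Fraction of best-guess genotypes disagreeing with truth.

    Denominator: entries non-missing in both. Best-guess calls come from
    genotype-probability argmax upstream, or rounded dosages
    (:func:`best_guess_from_dosage`).
    """
    if truth.sample_ids != best_guess.sample_ids or truth.marker_ids != best_guess.marker_ids:
        raise ValueError("matrices must be harmonized to identical samples and markers")
    t, x = truth.calls, best_guess.calls
    both = np.isfinite(t) & np.isfinite(x)
    if not both.any():
        return np.nan
    return float((both & (t != x)).sum() / both.sum())


def best_guess_from_dosage(dosages: np.ndarray) -> np.ndarray:
    """Round dosages in [0,2] to the nearest hard call (half rounds up)."""
    out = np.floor(np.asarray(dosages, float) + 0.5)
    return np.clip(out, 0, 2)


def coverage(
    per_marker: pd.DataFrame, r2_threshold: float = 0.8
) -> dict[str, object]:
    """Imputation-based genomic coverage from per-marker r2 and truth MAF.

    ``per_marker`` needs columns ``maf`` and ``r2``. A marker is covered
    when r2 > threshold (strict). Denominators are the evaluable (finite
    r2) markers of each stratum: common MAF >= 0.05, low-frequency
    0.01 <= MAF < 0.05. Also returns the per-bin profile over edges
    (0.01, 0.02, 0.05, 0.1, 0.2, 0.5).
    """
    if per_marker["maf"].isna().any():
        raise ValueError("every marker needs a truth MAF")
    maf = per_marker["maf"].to_numpy(float)
    r2 = per_marker["r2"].to_numpy(float)
    evaluable = np.isfinite(r2)
    hit = evaluable & (r2 > r2_threshold)

    def stratum(mask: np.ndarray) -> float:
        n = (mask & evaluable).sum()
        return float((mask & hit).sum() / n) if n else np.nan

    common = maf >= 0.05
    lowfreq = (maf >= 0.01) & (maf < 0.05)
    edges = MAF_BIN_EDGES
    bins = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (maf >= lo) & ((maf < hi) if hi != edges[-1] else (maf <= hi))
        bins.append(
            dict(maf_lo=lo, maf_hi=hi, n=int((mask & evaluable).sum()), coverage=stratum(mask))
        )
    return {
        "coverage_common": stratum(common),
        "coverage_lowfreq": stratum(lowfreq),
        "bins": pd.DataFrame(bins),
        "n_common": int((common & evaluable).sum()),
        "n_lowfreq": int((lowfreq & evaluable).sum()),
    }


def evaluate_imputation(
    truth_dosage: pd.DataFrame | np.ndarray,
    imputed_dosage: pd.DataFrame | np.ndarray,
    truth_maf: np.ndarray,
    marker_ids: list[str] | None = None,
    r2_threshold: float = 0.8,
) -> dict[str, object]:
    """Full per-marker + aggregate evaluation report.

    Inputs are sample x marker dosage arrays on harmonized markers.
    Aggregate r2 and discordance are unweighted means across markers.
    """
    t = np.asarray(truth_dosage, float)
    d = np.asarray(imputed_dosage, float)
    if t.shape != d.shape:
        raise ValueError("truth and imputed dosage shapes differ")
    n_markers = t.shape[1]
    marker_ids = marker_ids or [f"m{j}" for j in range(n_markers)]
    r2 = np.array([imputation_r2(t[:, j], d[:, j]) for j in range(n_markers)])
    tg = best_guess_from_dosage(t)
    dg = best_guess_from_dosage(d)
    both = np.isfinite(t) & np.isfinite(d)
    disc = np.array(
        [
            (both[:, j] & (tg[:, j] != dg[:, j])).sum() / both[:, j].sum()
            if both[:, j].any()
            else np.nan
            for j in range(n_markers)
        ]
    )
    per_marker = pd.DataFrame(
        dict(marker_id=marker_ids, maf=np.asarray(truth_maf, float), r2=r2, discordance=disc)
    )
    cov = coverage(per_marker, r2_threshold=r2_threshold)
    return {
        "per_marker": per_marker,
        "mean_r2": float(np.nanmean(r2)) if np.isfinite(r2).any() else np.nan,
        "mean_discordance": float(np.nanmean(disc)) if np.isfinite(disc).any() else np.nan,
        **cov,
    }
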