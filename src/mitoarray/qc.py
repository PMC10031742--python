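"""Marker- and sample-level quality control.

Implements the standard threshold rules used when building a genotyping
reference panel: per-marker call rate, minor allele count/frequency, the
exact conditional Hardy-Weinberg test, sliding-window LD pruning, maximum
spacing thinning, and per-sample heterozygosity / sex-inference / LRR-noise
checks.

Default thresholds: marker call rate > 0.95 (missing rate < 0.05), minor
allele count >= 3, HWE exact P > 1e-6; sample call rate >= 0.95,
heterozygosity within +-3 SD of the cohort mean, autosomal LRR SD <= 0.35.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AUTOSOMES, GenotypeMatrix, LRRMatrix


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def _hwe_het_probabilities(n: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of heterozygote counts given n genotypes and n_a copies
    of the minor allele, under Hardy-Weinberg equilibrium.

    Returns (het_counts, probabilities). Uses the numerically stable
    mode-outward recurrence on the exact conditional distribution.
    """
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return np.array([0]), np.array([1.0])
    hets = np.arange(rare % 2, rare + 1, 2)
    # start at (an even/odd value near) the distribution mode
    mid = int(round(rare * (2 * n - rare) / (2.0 * n)))
    if mid % 2 != rare % 2:
        mid += 1
    mid = min(max(mid, rare % 2), rare)
    probs = {mid: 1.0}
    # going down: P(h-2)/P(h) = h(h-1) / (4 * n_homr(h)+1)(n_homc(h)+1)
    h = mid
    while h >= rare % 2 + 2:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
    # going up: P(h+2)/P(h) = 4 n_homr n_homc / (h+2)(h+1)
    h = mid
    while h <= rare - 2:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        h += 2
    p = np.array([probs[int(h)] for h in hets])
    return hets, p / p.sum()


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count whose probability does not exceed that of the
    observed one. Monomorphic data give P = 1.
    """
    counts = (int(n_aa), int(n_ab), int(n_bb))
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be nonnegative")
    n = sum(counts)
    if n == 0:
        raise ValueError("at least one observed genotype is required")
    n_a = 2 * counts[0] + counts[1]
    hets, probs = _hwe_het_probabilities(n, n_a)
    obs = counts[1]
    p_obs = probs[np.searchsorted(hets, obs)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_chi2_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """One-df chi-square Hardy-Weinberg test (asymptotic alternative)."""
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("at least one observed genotype is required")
    p = (2 * n_aa + n_ab) / (2.0 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = ((obs - exp) ** 2 / exp).sum()
    return float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Marker statistics


def marker_stats(
    g: GenotypeMatrix,
    min_call_rate: float = 0.95,
    min_mac: int = 3,
    min_hwe_p: float = 1e-6,
    female_mask: np.ndarray | None = None,
    hwe_method: str = "exact",
) -> pd.DataFrame:
    """Per-marker call rate, MAF, minor allele count and HWE P-value.

    HWE is computed on autosomes for all samples and on the X chromosome
    for females only (requires ``female_mask``); Y and MT markers are
    exempt from the HWE and MAC filters. Returns a DataFrame indexed by
    marker_id with a boolean ``passed`` column and comma-joined ``reasons``.
    """
    if g.n_samples < 1:
        raise ValueError("marker_stats requires at least one sample")
    hwe_fn = hwe_exact_test if hwe_method == "exact" else hwe_chi2_test
    calls = g.calls
    n = g.n_samples
    nonmiss = np.isfinite(calls)
    n_called = nonmiss.sum(axis=0)
    call_rate = n_called / float(n)
    with np.errstate(invalid="ignore"):
        alt_count = np.nansum(calls, axis=0)
    total_alleles = 2.0 * n_called
    chrom = g.markers["chromosome"].to_numpy()
    rows = []
    for j, mid in enumerate(g.marker_ids):
        reasons: list[str] = []
        if n_called[j] == 0:
            rows.append(
                dict(marker_id=mid, call_rate=0.0, maf=np.nan, mac=0, hwe_p=np.nan,
                     passed=False, reasons="no_calls")
            )
            continue
        p_alt = alt_count[j] / total_alleles[j]
        maf = min(p_alt, 1.0 - p_alt)
        mac = int(round(min(alt_count[j], total_alleles[j] - alt_count[j])))
        col = calls[:, j]
        if chrom[j] in AUTOSOMES:
            sub = col[np.isfinite(col)]
        elif chrom[j] == "X" and female_mask is not None:
            sub = col[np.asarray(female_mask, bool) & np.isfinite(col)]
        else:
            sub = None  # Y/MT (or X without sex info): HWE not applicable
        if sub is not None and sub.size:
            hwe_p = hwe_fn(int((sub == 0).sum()), int((sub == 1).sum()), int((sub == 2).sum()))
        else:
            hwe_p = np.nan
        if call_rate[j] <= min_call_rate:
            reasons.append("call_rate")
        exempt = chrom[j] in ("Y", "MT")
        if not exempt and mac < min_mac:
            reasons.append("mac")
        if np.isfinite(hwe_p) and hwe_p <= min_hwe_p:
            reasons.append("hwe")
        rows.append(
            dict(marker_id=mid, call_rate=call_rate[j], maf=maf, mac=mac,
                 hwe_p=hwe_p, passed=not reasons, reasons=",".join(reasons))
        )
    return pd.DataFrame(rows).set_index("marker_id")


# ---------------------------------------------------------------------------
# Linkage disequilibrium


def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two genotype/dosage vectors.

    Computed over pairwise-complete samples; NaN when fewer than two
    complete pairs remain or either marker is monomorphic on that subset
    (callers treat NaN as "not in LD").
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2:
        return np.nan
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return np.nan
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def _window_r2(calls: np.ndarray) -> np.ndarray:
    """Pairwise r2 matrix for a block of genotype columns (NaN-aware)."""
    k = calls.shape[1]
    out = np.full((k, k), np.nan)
    finite = np.isfinite(calls)
    if finite.all():
        sd = calls.std(axis=0)
        poly = sd > 0
        if poly.any():
            c = np.corrcoef(calls[:, poly], rowvar=False)
            c = np.atleast_2d(c)
            idx = np.flatnonzero(poly)
            out[np.ix_(idx, idx)] = c * c
        return out
    for a in range(k):
        for b in range(a + 1, k):
            out[a, b] = out[b, a] = ld_r2(calls[:, a], calls[:, b])
    return out


def ld_prune(
    g: GenotypeMatrix,
    r2_max: float = 0.3,
    window: int = 50,
    step: int = 5,
) -> list[str]:
    """Sliding-window LD pruning: greedily drop markers so that no retained
    in-window pair has r2 >= ``r2_max``.

    Windows are ``window`` markers wide and advance by ``step`` within each
    chromosome (markers ordered by position). On a conflicting pair the
    earlier-position marker is kept; an undefined r2 (monomorphic or too
    few complete pairs) counts as no LD. Idempotent.
    """
    markers = g.markers
    keep = np.ones(g.n_markers, dtype=bool)
    order = np.lexsort((markers["position"].to_numpy(), markers["chromosome"].to_numpy()))
    for chrom in pd.unique(markers["chromosome"].to_numpy()[order]):
        idx = order[markers["chromosome"].to_numpy()[order] == chrom]
        start = 0
        while start < len(idx):
            win = idx[start : start + window]
            r2 = _window_r2(g.calls[:, win])
            for a in range(len(win)):
                if not keep[win[a]]:
                    continue
                for b in range(a + 1, len(win)):
                    if not keep[win[b]]:
                        continue
                    if np.isfinite(r2[a, b]) and r2[a, b] >= r2_max:
                        keep[win[b]] = False
            if start + window >= len(idx):
                break
            start += step
    return [m for m, k in zip(g.marker_ids, keep) if k]


# ---------------------------------------------------------------------------
# Maximum spacing selection


def _maximin_select(positions: np.ndarray, k: int) -> np.ndarray:
    """Indices (into sorted positions) of k markers maximising the minimum
    inter-marker gap, by binary search on the gap with a greedy left-to-right
    feasibility sweep."""
    n = len(positions)
    if k >= n:
        return np.arange(n)
    if k == 1:
        return np.array([0])

    def picked(gap: float) -> list[int]:
        chosen = [0]
        last = positions[0]
        for i in range(1, n):
            if positions[i] - last >= gap:
                chosen.append(i)
                last = positions[i]
        return chosen

    lo, hi = 0.0, float(positions[-1] - positions[0])
    for _ in range(64):
        mid = (lo + hi) / 2.0
        if len(picked(mid)) >= k:
            lo = mid
        else:
            hi = mid
    return np.array(picked(lo)[:k])


def max_spacing_select(markers: pd.DataFrame, k: int) -> list[str]:
    """Thin a marker manifest to ``k`` markers with maximal minimum spacing.

    The budget is split across chromosomes proportionally to their spanned
    length (largest-remainder rounding, at least one marker per chromosome
    when the budget allows); within a chromosome the exact maximin subset is
    found by binary search on the gap. Deterministic.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    total = len(markers)
    if k >= total:
        return markers["marker_id"].tolist()
    groups = []
    for chrom, grp in markers.groupby("chromosome", sort=True):
        grp = grp.sort_values(["position", "marker_id"])
        span = float(grp["position"].iloc[-1] - grp["position"].iloc[0])
        groups.append((chrom, grp, span))
    span_total = sum(s for _, _, s in groups) or 1.0
    # proportional allocation with largest remainder, floor 1, cap at size
    raw = [k * s / span_total for _, _, s in groups]
    alloc = [min(int(np.floor(r)), len(grp)) for r, (_, grp, _) in zip(raw, groups)]
    alloc = [max(a, 1) if k >= len(groups) else a for a in alloc]
    alloc = [min(a, len(grp)) for a, (_, grp, _) in zip(alloc, groups)]
    rema = sorted(
        range(len(groups)),
        key=lambda i: (raw[i] - np.floor(raw[i]), -groups[i][2]),
        reverse=True,
    )
    deficit = k - sum(alloc)
    ptr = 0
    while deficit > 0:
        i = rema[ptr % len(rema)]
        if alloc[i] < len(groups[i][1]):
            alloc[i] += 1
            deficit -= 1
        ptr += 1
    while deficit < 0:
        i = max(range(len(groups)), key=lambda i: alloc[i])
        alloc[i] -= 1
        deficit += 1
    out: list[str] = []
    for a, (_, grp, _) in zip(alloc, groups):
        if a <= 0:
            continue
        pos = grp["position"].to_numpy(float)
        sel = _maximin_select(pos, a)
        out.extend(grp["marker_id"].to_numpy()[sel])
    return out


# ---------------------------------------------------------------------------
# Sample statistics


@dataclass
class SampleQCThresholds:
    min_call_rate: float = 0.95
    max_het_z: float = 3.0
    max_lrr_sd: float = 0.35
    male_f: float = 0.8
    female_f: float = 0.2
    min_y_call_rate: float = 0.5


def sample_stats(
    g: GenotypeMatrix,
    lrr: LRRMatrix | None = None,
    thresholds: SampleQCThresholds | None = None,
) -> pd.DataFrame:
    """Per-sample call rate, autosomal heterozygosity (with cohort z-score),
    X-inbreeding F, Y call rate, inferred sex and optional autosomal LRR SD.

    Sex inference: F > ``male_f`` and (when Y markers exist) Y call rate >=
    ``min_y_call_rate`` -> male; F < ``female_f`` -> female; otherwise (or
    with no X markers) unknown. ``lrr`` should be the GC-corrected LRR
    matrix restricted to high-quality autosomal markers.
    """
    if g.n_samples < 2:
        raise ValueError("sample_stats requires at least two samples for cohort z-scores")
    th = thresholds or SampleQCThresholds()
    chrom = g.markers["chromosome"].to_numpy()
    auto = np.isin(chrom, AUTOSOMES)
    x_mask = chrom == "X"
    y_mask = chrom == "Y"
    calls = g.calls
    nonmiss = np.isfinite(calls)

    call_rate = nonmiss.mean(axis=1) if g.n_markers else np.ones(g.n_samples)
    auto_calls = calls[:, auto]
    auto_ok = np.isfinite(auto_calls)
    denom = auto_ok.sum(axis=1).astype(float)
    het = np.where(denom > 0, (auto_calls == 1).sum(axis=1) / np.maximum(denom, 1), np.nan)
    mu, sd = np.nanmean(het), np.nanstd(het, ddof=1)
    het_z = (het - mu) / sd if sd > 0 else np.zeros_like(het)

    # X inbreeding coefficient: excess observed homozygosity over HWE expectation
    f_x = np.full(g.n_samples, np.nan)
    if x_mask.any():
        xc = calls[:, x_mask]
        ok = np.isfinite(xc)
        with np.errstate(invalid="ignore"):
            p = np.nansum(xc, axis=0) / (2.0 * np.maximum(ok.sum(axis=0), 1))
        exp_het = 2.0 * p * (1.0 - p)
        obs_hom = ((xc != 1) & ok).sum(axis=1)
        n_obs = ok.sum(axis=1).astype(float)
        exp_hom = ((1.0 - exp_het)[None, :] * ok).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_x = (obs_hom - exp_hom) / (n_obs - exp_hom)

    y_rate = np.full(g.n_samples, np.nan)
    if y_mask.any():
        y_rate = np.isfinite(calls[:, y_mask]).mean(axis=1)

    sex = np.full(g.n_samples, "unknown", dtype=object)
    if x_mask.any():
        male = f_x > th.male_f
        if y_mask.any():
            male &= y_rate >= th.min_y_call_rate
        sex[male] = "male"
        sex[(f_x < th.female_f)] = "female"

    lrr_sd = np.full(g.n_samples, np.nan)
    if lrr is not None:
        la = np.isin(lrr.markers["chromosome"].to_numpy(), AUTOSOMES)
        vals = lrr.lrr[:, la]
        with np.errstate(invalid="ignore"):
            lrr_sd = np.array([np.nanstd(row[np.isfinite(row)], ddof=1) if np.isfinite(row).sum() > 1 else np.nan for row in vals])

    rows = []
    for i, sid in enumerate(g.sample_ids):
        reasons = []
        if call_rate[i] < th.min_call_rate:
            reasons.append("call_rate")
        if np.isfinite(het_z[i]) and abs(het_z[i]) > th.max_het_z:
            reasons.append("heterozygosity")
        if np.isfinite(lrr_sd[i]) and lrr_sd[i] > th.max_lrr_sd:
            reasons.append("lrr_sd")
        rows.append(
            dict(sample_id=sid, call_rate=call_rate[i], heterozygosity_rate=het[i],
                 het_z=het_z[i], x_inbreeding_F=f_x[i], y_call_rate=y_rate[i],
                 inferred_sex=sex[i], lrr_sd=lrr_sd[i],
                 passed=not reasons, reasons=",".join(reasons))
        )
    return pd.DataFrame(rows).set_index("sample_id")
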