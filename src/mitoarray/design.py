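"""Array content design: greedy tag-SNP selection and coverage accounting.

Tag selection works against a phased reference panel (or its diploid
collapse): a fixed anchor set is credited first, then markers are added
greedily, each round picking the candidate that covers the most
still-uncovered common targets at pairwise genotype r2 >= ``r2_min``
within a physical window. Ties break deterministically: higher MAF, then
smaller position, then lexicographically smaller marker id.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, HaplotypePanel
from .qc import ld_r2


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (display convention for printed percentages)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass
class TagSelection:
    """Result of greedy tag selection."""

    anchors: list[str]
    selected: list[str]
    coverage_map: dict[str, tuple[str, float]]  # target -> (tag, r2)
    uncovered: list[str]
    budget: int | None

    @property
    def n_tags(self) -> int:
        return len(self.anchors) + len(self.selected)


def _as_genotypes(panel: HaplotypePanel | GenotypeMatrix) -> GenotypeMatrix:
    return panel.to_genotypes() if isinstance(panel, HaplotypePanel) else panel


def greedy_tag_select(
    panel: HaplotypePanel | GenotypeMatrix,
    targets: list[str],
    anchors: list[str] | None = None,
    r2_min: float = 0.8,
    window_bp: int = 1_000_000,
    budget: int | None = None,
) -> TagSelection:
    """Select tag markers so every target is proxied at r2 >= ``r2_min``.

    ``targets`` are the marker ids that must be covered (typically the
    common, MAF > 0.05, panel SNPs); candidates are all panel markers.
    Anchors are credited before any greedy round. The budget counts anchors
    plus selections; greedy rounds stop when targets are exhausted, no
    candidate adds coverage, or the budget is reached.
    """
    anchors = list(anchors or [])
    if not 0 < r2_min <= 1:
        raise ValueError("r2_min must be in (0, 1]")
    g = _as_genotypes(panel)
    ids = g.marker_ids
    pos_of = {m: i for i, m in enumerate(ids)}
    unknown = [t for t in targets if t not in pos_of]
    if unknown:
        raise KeyError(f"targets absent from panel: {unknown[:5]}")
    if budget is not None and budget < len(anchors):
        raise ValueError("budget smaller than the anchor set")

    chrom = g.markers["chromosome"].to_numpy()
    pos = g.markers["position"].to_numpy()
    calls = g.calls
    with np.errstate(invalid="ignore"):
        p_alt = np.nanmean(calls, axis=0) / 2.0
    maf = np.minimum(p_alt, 1 - p_alt)

    t_idx = np.array([pos_of[t] for t in targets], dtype=int)
    # cover[c][k] True when candidate c tags target k
    n_t = len(t_idx)
    cover_sets: dict[int, np.ndarray] = {}
    r2_cache: dict[tuple[int, int], float] = {}

    def r2_pair(a: int, b: int) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in r2_cache:
            r2_cache[key] = ld_r2(calls[:, key[0]], calls[:, key[1]])
        return r2_cache[key]

    for c in range(len(ids)):
        in_win = (chrom[t_idx] == chrom[c]) & (np.abs(pos[t_idx] - pos[c]) <= window_bp)
        mask = np.zeros(n_t, dtype=bool)
        for k in np.flatnonzero(in_win):
            r2 = r2_pair(c, t_idx[k])
            mask[k] = np.isfinite(r2) and r2 >= r2_min
        cover_sets[c] = mask

    covered = np.zeros(n_t, dtype=bool)
    coverage_map: dict[str, tuple[str, float]] = {}

    def credit(tag_idx: int) -> None:
        for k in np.flatnonzero(cover_sets[tag_idx] & ~covered):
            coverage_map[targets[k]] = (ids[tag_idx], float(r2_pair(tag_idx, t_idx[k])))
            covered[k] = True

    for a in anchors:
        if a in pos_of:
            credit(pos_of[a])

    selected: list[str] = []
    anchor_set = set(anchors)
    candidates = [c for c in range(len(ids)) if ids[c] not in anchor_set]
    while not covered.all():
        if budget is not None and len(anchors) + len(selected) >= budget:
            break
        best, best_key = None, None
        for c in candidates:
            gain = int((cover_sets[c] & ~covered).sum())
            if gain == 0:
                continue
            key = (gain, maf[c], -pos[c], _neg_lex(ids[c]))
            if best_key is None or key > best_key:
                best, best_key = c, key
        if best is None:
            break
        credit(best)
        selected.append(ids[best])
        candidates.remove(best)

    uncovered = [targets[k] for k in np.flatnonzero(~covered)]
    return TagSelection(anchors, selected, coverage_map, uncovered, budget)


class _neg_lex(str):
    """Inverts lexicographic comparison so max() prefers the smaller id."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


# ---------------------------------------------------------------------------
# Coverage accounting


def direct_coverage(
    array_markers: pd.DataFrame, reference_markers: pd.DataFrame
) -> dict[str, float]:
    """Fraction of reference variants directly present on the array.

    A reference variant is matched when some array marker has the same
    (chromosome, position) and the same allele set, allowing ref/alt swap
    but no strand flipping (both manifests are assumed on the same strand).
    """
    if len(array_markers) == 0 or len(reference_markers) == 0:
        raise ValueError("both marker sets must be non-empty")
    array_keys = {
        (c, int(p), frozenset((r, a)))
        for c, p, r, a in zip(
            array_markers["chromosome"], array_markers["position"],
            array_markers["ref_allele"], array_markers["alt_allele"],
        )
    }
    matched = sum(
        (c, int(p), frozenset((r, a))) in array_keys
        for c, p, r, a in zip(
            reference_markers["chromosome"], reference_markers["position"],
            reference_markers["ref_allele"], reference_markers["alt_allele"],
        )
    )
    return {
        "matched": int(matched),
        "total": int(len(reference_markers)),
        "proportion": matched / len(reference_markers),
    }


@dataclass
class ContentSummary:
    """Marker counts and proportions per design category."""

    table: pd.DataFrame = field(repr=False)
    total: int = 0

    def display(self, ndigits: int = 2) -> pd.DataFrame:
        out = self.table.copy()
        out["percent"] = [round_half_up(100 * p, ndigits) for p in out["proportion"]]
        return out


def content_summary(categories: pd.Series | dict[str, str]) -> ContentSummary:
    """Tally markers per design category with raw and display proportions.

    ``categories`` maps marker_id -> category; every marker must be
    assigned exactly one category (missing assignments raise).
    """
    s = pd.Series(categories)
    if s.isna().any():
        bad = s.index[s.isna()][0]
        raise ValueError(f"marker {bad!r} has no category assignment")
    counts = s.value_counts()
    total = int(counts.sum())
    table = pd.DataFrame(
        {"category": counts.index, "count": counts.to_numpy(),
         "proportion": counts.to_numpy() / total}
    ).reset_index(drop=True)
    return ContentSummary(table=table, total=total)
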