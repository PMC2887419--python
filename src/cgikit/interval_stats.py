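"""Overlap statistics between island sets and genomic annotations.

Overlap everywhere means at least one shared base under half-open
arithmetic: intervals that merely touch (end == start) do not overlap.
Mean coverage is the mean over islands of (island bases covered by the
union of the elements) / (island length); the overlap fraction is the
fraction of islands sharing >= 1 bp with any element.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .errors import UndefinedStatisticError
from .genome_io import IntervalSet

__all__ = [
    "OverlapSummary",
    "TSSSpecificity",
    "overlap_summary",
    "nesting_counts",
    "tss_specificity",
    "extract_islets",
    "exclusive_islands",
]


@dataclass(frozen=True)
class OverlapSummary:
    mean_coverage: float
    overlap_fraction: float
    n_islands: int
    n_elements_touched: int


class TSSSpecificity(NamedTuple):
    n_overlapping_any: int
    n_unique: int
    n_multiple: int
    pct_unique: float
    pct_multiple: float


def _triples(objs: Iterable) -> list[tuple[str, int, int]]:
    """Normalize Islands / GenomicIntervals / an IntervalSet to (chrom, start, end)."""
    if isinstance(objs, IntervalSet):
        objs = objs.intervals
    return [(o.chrom, o.start, o.end) for o in objs]


def _merged_arrays(triples: Sequence[tuple[str, int, int]]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome disjoint sorted (starts, ends) arrays of the union."""
    per: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in triples:
        per.setdefault(chrom, []).append((s, e))
    out = {}
    for chrom, ivs in per.items():
        ivs.sort()
        m_starts, m_ends = [], []
        for s, e in ivs:
            if m_ends and s <= m_ends[-1]:
                m_ends[-1] = max(m_ends[-1], e)
            else:
                m_starts.append(s)
                m_ends.append(e)
        out[chrom] = (np.asarray(m_starts), np.asarray(m_ends))
    return out


def _covered_bp(a: int, b: int, merged: tuple[np.ndarray, np.ndarray]) -> int:
    starts, ends = merged
    lo = int(np.searchsorted(ends, a, side="right"))
    hi = int(np.searchsorted(starts, b, side="left"))
    if hi <= lo:
        return 0
    return int(np.sum(np.minimum(ends[lo:hi], b) - np.maximum(starts[lo:hi], a)))


def _overlaps_any(a: int, b: int, merged: tuple[np.ndarray, np.ndarray]) -> bool:
    starts, ends = merged
    j = int(np.searchsorted(starts, b, side="left"))
    return j > 0 and ends[j - 1] > a


def overlap_summary(islands: Iterable, elements: Iterable) -> OverlapSummary:
    """Coverage and overlap statistics of islands vs an annotation set.

    Raises UndefinedStatisticError for an empty island set. The statistics
    are invariant to element order and to splitting elements into adjacent
    pieces, because coverage is computed against the union of the elements.
    """
    isl = _triples(islands)
    elem = _triples(elements)
    if not isl:
        raise UndefinedStatisticError("overlap statistics undefined for an empty island set")
    merged_elem = _merged_arrays(elem)
    coverages = []
    n_overlapping = 0
    for chrom, a, b in isl:
        merged = merged_elem.get(chrom)
        cov = _covered_bp(a, b, merged) if merged is not None else 0
        coverages.append(cov / (b - a))
        n_overlapping += cov > 0
    merged_isl = _merged_arrays(isl)
    n_touched = sum(
        1
        for chrom, a, b in elem
        if chrom in merged_isl and _overlaps_any(a, b, merged_isl[chrom])
    )
    return OverlapSummary(
        mean_coverage=float(np.mean(coverages)),
        overlap_fraction=n_overlapping / len(isl),
        n_islands=len(isl),
        n_elements_touched=n_touched,
    )


def nesting_counts(
    outer_islands: Iterable, inner_islands: Iterable, containment: bool = False
) -> tuple[dict[int, int], float]:
    """Histogram of inner islands per outer island, and the fraction of outer
    islands hosting >= 2 inner islands.

    By default an inner island counts for every outer island it overlaps by
    >= 1 bp (an inner island straddling two outers counts once for each);
    with containment=True only inner islands fully inside the outer count.
    """
    outer = _triples(outer_islands)
    inner = _triples(inner_islands)
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {c for c, _, _ in inner}:
        ivs = [(s, e) for c, s, e in inner if c == chrom]
        starts = np.sort(np.array([s for s, _ in ivs]))
        ends = np.sort(np.array([e for _, e in ivs]))
        per_chrom[chrom] = (starts, ends)
    raw = {chrom: [(s, e) for c, s, e in inner if c == chrom] for chrom in per_chrom}

    hist: Counter[int] = Counter()
    for chrom, a, b in outer:
        if chrom not in per_chrom:
            hist[0] += 1
            continue
        if containment:
            count = sum(1 for s, e in raw[chrom] if s >= a and e <= b)
        else:
            starts, ends = per_chrom[chrom]
            # sorted-start/sorted-end trick: #(start < b) - #(end <= a)
            count = int(
                np.searchsorted(starts, b, side="left") - np.searchsorted(ends, a, side="right")
            )
        hist[count] += 1
    n_outer = len(outer)
    frac_ge2 = sum(v for k, v in hist.items() if k >= 2) / n_outer if n_outer else 0.0
    return dict(hist), frac_ge2


def tss_specificity(islands: Iterable, tss_points: Iterable) -> TSSSpecificity:
    """Classify islands by the number of transcription start sites they contain.

    TSSs must be 1-bp intervals. Islands containing exactly one TSS are
    "unique", those containing two or more are "multiple"; percentages are
    over the islands overlapping at least one TSS, to 2 decimals.
    """
    tss = _triples(tss_points)
    for chrom, s, e in tss:
        if e - s != 1:
            raise ValueError(f"TSS {chrom}:{s}-{e} is not a 1-bp interval")
    pos_by_chrom: dict[str, np.ndarray] = {}
    for chrom in {c for c, _, _ in tss}:
        pos_by_chrom[chrom] = np.sort(np.array([s for c, s, _ in tss if c == chrom]))
    n_any = n_unique = n_multiple = 0
    for chrom, a, b in _triples(islands):
        pos = pos_by_chrom.get(chrom)
        if pos is None:
            continue
        count = int(np.searchsorted(pos, b, side="left") - np.searchsorted(pos, a, side="left"))
        if count >= 1:
            n_any += 1
            if count == 1:
                n_unique += 1
            else:
                n_multiple += 1
    pct_unique = round(100.0 * n_unique / n_any, 2) if n_any else 0.0
    pct_multiple = round(100.0 * n_multiple / n_any, 2) if n_any else 0.0
    return TSSSpecificity(n_any, n_unique, n_multiple, pct_unique, pct_multiple)


def extract_islets(
    islands: Sequence, max_length: int = 200, pvalue_threshold: float = 1e-5
) -> list:
    """Islets: islands shorter than max_length bp with p-value <= threshold.

    Every island must carry a p-value (sliding-window islands do not and
    raise an error). The operation is idempotent.
    """
    for isl in islands:
        if isl.p_value is None:
            raise UndefinedStatisticError(
                f"island {isl.chrom}:{isl.start}-{isl.end} has no p-value; "
                "islets are defined only for cluster predictions"
            )
    return [
        isl
        for isl in islands
        if (isl.end - isl.start) < max_length and isl.p_value <= pvalue_threshold
    ]


def exclusive_islands(islands: Iterable, other_prediction_sets: Sequence[Iterable]) -> list:
    """Islands overlapping (>= 1 bp) no interval in any of the other sets."""
    others = [_merged_arrays(_triples(s)) for s in other_prediction_sets]
    kept = []
    for isl in islands if not isinstance(islands, IntervalSet) else islands.intervals:
        hit = any(
            isl.chrom in merged and _overlaps_any(isl.start, isl.end, merged[isl.chrom])
            for merged in others
        )
        if not hit:
            kept.append(isl)
    return kept
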