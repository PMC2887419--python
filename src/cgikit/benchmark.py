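"""Gold-standard evaluation: sensitivity, lower-bound PPV, promoter windows
and matched-set p-value calibration.

A predicted island is a true positive (TP) when it overlaps the gold
standard in at least 1 bp; a gold interval not touched by any prediction is
a false negative (FN). Sensitivity SN = TP / (TP + FN) therefore mixes
prediction-side TPs with gold-side FNs — the reading that reproduces the
published table cells. Because no complete gold standard exists, every
prediction without gold overlap is counted as a false positive, making
PPV = TP / n_predicted a lower bound: the method is at least this specific.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import UndefinedStatisticError
from .genome_io import GenomicInterval, IntervalSet
from .interval_stats import _merged_arrays, _overlaps_any, _triples

__all__ = [
    "BenchmarkResult",
    "CalibrationResult",
    "benchmark_vs_gold",
    "benchmark_from_counts",
    "promoters_from_tss",
    "calibrate_pvalue_threshold",
]


@dataclass(frozen=True)
class BenchmarkResult:
    n_predicted: int
    n_gold: int
    tp: int
    gold_touched: int
    fn: int
    sn: float
    ppv: float


def benchmark_from_counts(n_predicted: int, tp: int, gold_touched: int, n_gold: int) -> BenchmarkResult:
    """Assemble SN and lower-bound PPV from the four raw counts."""
    fn = n_gold - gold_touched
    return BenchmarkResult(
        n_predicted=n_predicted,
        n_gold=n_gold,
        tp=tp,
        gold_touched=gold_touched,
        fn=fn,
        sn=tp / (tp + fn),
        ppv=tp / n_predicted,
    )


def benchmark_vs_gold(islands: Iterable, gold: Iterable) -> BenchmarkResult:
    """Evaluate a prediction set against a gold-standard interval set."""
    pred = _triples(islands)
    gold_t = _triples(gold)
    if not pred or not gold_t:
        raise UndefinedStatisticError("benchmark needs non-empty prediction and gold sets")
    merged_gold = _merged_arrays(gold_t)
    tp = sum(
        1
        for chrom, a, b in pred
        if chrom in merged_gold and _overlaps_any(a, b, merged_gold[chrom])
    )
    merged_pred = _merged_arrays(pred)
    touched = sum(
        1
        for chrom, a, b in gold_t
        if chrom in merged_pred and _overlaps_any(a, b, merged_pred[chrom])
    )
    return benchmark_from_counts(len(pred), tp, touched, len(gold_t))


def promoters_from_tss(
    tss: IntervalSet,
    upstream: int = 1500,
    downstream: int = 500,
    chrom_sizes: dict[str, int] | None = None,
) -> IntervalSet:
    """Strand-aware promoter windows from 1-bp TSS intervals.

    + strand: [tss - upstream, tss + downstream); - strand mirrored.
    Windows are clipped at 0 and, when chrom_sizes is given, at the
    chromosome end. TSSs with unknown strand raise an error listing them.
    """
    unknown = [iv for iv in tss if iv.strand not in "+-"]
    if unknown:
        names = ", ".join(f"{iv.chrom}:{iv.start}({iv.label})" for iv in unknown[:10])
        raise ValueError(f"{len(unknown)} TSS record(s) with unknown strand: {names}")
    out = []
    for iv in tss:
        pos = iv.start
        if iv.strand == "+":
            start, end = pos - upstream, pos + downstream
        else:
            start, end = pos - downstream, pos + upstream
        start = max(start, 0)
        if chrom_sizes is not None and iv.chrom in chrom_sizes:
            end = min(end, chrom_sizes[iv.chrom])
        out.append(
            GenomicInterval(chrom=iv.chrom, start=start, end=end, strand=iv.strand, label=iv.label)
        )
    return IntervalSet(name=f"{tss.name}_promoters", intervals=out)


@dataclass(frozen=True)
class CalibrationResult:
    selected: tuple
    log10_threshold: float
    n_requested: int
    n_selected: int
    tied: bool


def calibrate_pvalue_threshold(islands: Sequence, target_count: int) -> CalibrationResult:
    """Pick the p-value cutoff that yields a prediction set of a given size.

    Islands are sorted by p-value ascending and the top target_count are
    selected; the threshold is -log10 of the target_count-th p-value. When
    several islands tie exactly at the cut, all tied islands are included
    (the selected set may exceed target_count, and the tie is reported).
    """
    if target_count <= 0:
        raise ValueError("target_count must be positive")
    if target_count > len(islands):
        raise ValueError(f"target_count {target_count} exceeds {len(islands)} islands")
    for isl in islands:
        if isl.p_value is None:
            raise UndefinedStatisticError("calibration requires p-values on every island")
    ordered = sorted(islands, key=lambda isl: isl.p_value)
    p_cut = ordered[target_count - 1].p_value
    selected = [isl for isl in ordered if isl.p_value <= p_cut]
    return CalibrationResult(
        selected=tuple(selected),
        log10_threshold=-math.log10(p_cut),
        n_requested=target_count,
        n_selected=len(selected),
        tied=len(selected) > target_count,
    )
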