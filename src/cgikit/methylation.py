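"""Methylation-state classification of CpGs and islands.

Amplicon-style data (clone counts per tissue) are filtered and labeled with
the 80/20 rules: a CpG's per-tissue mean is "methylated" at >= 80%,
"unmethylated" under 20%, "intermediate" in between. A CpG is usable in a
tissue only when supported by at least min_clones clones; CpGs seen in
fewer than min_tissues usable tissues stay unclassified. Across tissues a
CpG is methylated when methylated in more than half of the tissues and
never unmethylated (and mirrored for unmethylated); it is differentially
methylated when both extreme labels occur and intermediate labels are in
the minority. Island labels require data for more than half of the
island's CpGs and follow the same majority-with-veto logic over the
classified CpGs.

Read-style (whole-genome bisulfite) data use a per-cytosine read-depth
filter instead; array-style two-tissue data use the scaled 5mC log2-ratio
cutoff (< 0.3 means unmethylated).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError

__all__ = [
    "MethState",
    "MethylationThresholds",
    "load_methylation_table",
    "tissue_label",
    "classify_cpg",
    "classify_cpgs_table",
    "classify_island",
    "WeberResult",
    "extract_weber_regions",
    "island_mean_methylation",
    "HeterogeneityResult",
    "swa_heterogeneity",
    "PairTestResult",
    "compare_island_pair",
]


class MethState(str, Enum):
    METHYLATED = "methylated"
    UNMETHYLATED = "unmethylated"
    INTERMEDIATE = "intermediate"
    DIFFERENTIAL = "differential"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class MethylationThresholds:
    """Cutoffs for state assignment (percent scale unless noted).

    Boundary behaviour: a per-tissue mean of exactly 80 is methylated and
    exactly 20 is intermediate. The "never methylated/unmethylated" vetoes
    are absolute regardless of majorities. weber_unmeth_max is on the
    scaled 5mC log2-ratio scale; its complement (>= 0.3) is treated as the
    methylated side of a differential call.
    """

    methylated_min: float = 80.0
    unmethylated_max: float = 20.0
    min_clones: int = 2
    min_tissues: int = 6
    majority: float = 0.5
    island_cpg_coverage: float = 0.5
    weber_unmeth_max: float = 0.3
    lister_min_reads: int = 10
    pair_test_alpha: float = 0.05


_METH_COLUMNS = ["chrom", "cpg_position", "tissue", "mean_methylation", "n_support"]


def load_methylation_table(path) -> pd.DataFrame:
    """Read a tab-delimited methylation table with a header line.

    Expected columns: chrom, cpg_position, tissue, mean_methylation,
    n_support (clones or reads); extra columns are preserved.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _METH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing methylation columns {missing}")
    return df


def tissue_label(mean_methylation: float, thr: MethylationThresholds = MethylationThresholds()) -> MethState:
    """Per-tissue label of one CpG mean: >= 80 methylated, < 20 unmethylated."""
    if mean_methylation >= thr.methylated_min:
        return MethState.METHYLATED
    if mean_methylation < thr.unmethylated_max:
        return MethState.UNMETHYLATED
    return MethState.INTERMEDIATE


def _combine_tissue_labels(
    n_meth: int, n_unmeth: int, n_inter: int, thr: MethylationThresholds
) -> MethState:
    n_t = n_meth + n_unmeth + n_inter
    if n_t < thr.min_tissues:
        return MethState.UNCLASSIFIED
    if n_meth > thr.majority * n_t and n_unmeth == 0:
        return MethState.METHYLATED
    if n_unmeth > thr.majority * n_t and n_meth == 0:
        return MethState.UNMETHYLATED
    if n_meth > 0 and n_unmeth > 0 and n_inter < thr.majority * n_t:
        return MethState.DIFFERENTIAL
    return MethState.UNCLASSIFIED


def classify_cpg(
    records: "pd.DataFrame | Iterable[tuple]",
    thr: MethylationThresholds = MethylationThresholds(),
) -> MethState:
    """Cross-tissue state of one CpG.

    records: a DataFrame with columns tissue, mean_methylation, n_support,
    or an iterable of (tissue, mean_methylation, n_support) tuples. Records
    with fewer than min_clones supporting clones are dropped; multiple
    samples of the same tissue are averaged before labeling.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(
            list(records), columns=["tissue", "mean_methylation", "n_support"]
        )
    usable = records[records["n_support"] >= thr.min_clones]
    if usable.empty:
        return MethState.UNCLASSIFIED
    per_tissue = usable.groupby("tissue")["mean_methylation"].mean()
    labels = [tissue_label(v, thr) for v in per_tissue]
    return _combine_tissue_labels(
        labels.count(MethState.METHYLATED),
        labels.count(MethState.UNMETHYLATED),
        labels.count(MethState.INTERMEDIATE),
        thr,
    )


def classify_cpgs_table(
    table: pd.DataFrame, thr: MethylationThresholds = MethylationThresholds()
) -> dict[tuple[str, int], MethState]:
    """Vectorized classification of every CpG in a methylation table.

    Returns {(chrom, cpg_position): MethState}. Equivalent to calling
    classify_cpg per CpG, but grouped with pandas for whole-dataset runs.
    """
    usable = table[table["n_support"] >= thr.min_clones]
    if usable.empty:
        return {}
    per_tissue = (
        usable.groupby(["chrom", "cpg_position", "tissue"], sort=False)["mean_methylation"]
        .mean()
        .reset_index()
    )
    v = per_tissue["mean_methylation"]
    per_tissue["is_meth"] = v >= thr.methylated_min
    per_tissue["is_unmeth"] = v < thr.unmethylated_max
    agg = per_tissue.groupby(["chrom", "cpg_position"], sort=False).agg(
        n_t=("tissue", "size"), n_meth=("is_meth", "sum"), n_unmeth=("is_unmeth", "sum")
    )
    out = {}
    for (chrom, pos), row in agg.iterrows():
        n_inter = int(row.n_t - row.n_meth - row.n_unmeth)
        out[(chrom, int(pos))] = _combine_tissue_labels(
            int(row.n_meth), int(row.n_unmeth), n_inter, thr
        )
    return out


def classify_island(
    island_cpg_positions: Sequence[int],
    cpg_states: Mapping[int, MethState],
    thr: MethylationThresholds = MethylationThresholds(),
) -> MethState:
    """Island-level state from the states of its CpGs.

    Unclassified unless classified (non-unclassified) states exist for more
    than island_cpg_coverage of the island's CpGs; the majority fractions
    are then taken over the classified CpGs, with the absolute vetoes.
    """
    n_total = len(island_cpg_positions)
    if n_total == 0:
        return MethState.UNCLASSIFIED
    states = [
        cpg_states[p]
        for p in island_cpg_positions
        if cpg_states.get(p, MethState.UNCLASSIFIED) is not MethState.UNCLASSIFIED
    ]
    if len(states) <= thr.island_cpg_coverage * n_total:
        return MethState.UNCLASSIFIED
    n = len(states)
    n_meth = states.count(MethState.METHYLATED)
    n_unmeth = states.count(MethState.UNMETHYLATED)
    n_diff = states.count(MethState.DIFFERENTIAL)
    if n_meth > thr.majority * n and n_unmeth == 0:
        return MethState.METHYLATED
    if n_unmeth > thr.majority * n and n_meth == 0:
        return MethState.UNMETHYLATED
    if n_diff > thr.majority * n:
        return MethState.DIFFERENTIAL
    return MethState.UNCLASSIFIED


@dataclass(frozen=True)
class WeberResult:
    kept: tuple
    differential: tuple
    concordant_unmethylated: tuple


def extract_weber_regions(
    region_ratios: Mapping[str, Mapping[str, float]],
    thr: MethylationThresholds = MethylationThresholds(),
) -> WeberResult:
    """Two-tissue array-style region extraction by scaled 5mC log2 ratio.

    region_ratios: {region_id: {tissue: ratio}} with >= 2 tissues each.
    A tissue is unmethylated when ratio < weber_unmeth_max. Regions
    unmethylated in at least one tissue are kept; of those, regions
    unmethylated in some but not all tissues are differential, the rest
    concordant. kept == concordant + differential by construction.
    """
    kept, diff, conc = [], [], []
    for region, ratios in region_ratios.items():
        if len(ratios) < 2:
            raise ValueError(f"region {region!r} needs >= 2 tissues, got {len(ratios)}")
        unmeth = [r < thr.weber_unmeth_max for r in ratios.values()]
        if any(unmeth):
            kept.append(region)
            (diff if not all(unmeth) else conc).append(region)
    return WeberResult(tuple(kept), tuple(diff), tuple(conc))


def island_mean_methylation(
    island_cpg_positions: Sequence[int],
    reads_table: pd.DataFrame,
    thr: MethylationThresholds = MethylationThresholds(),
) -> float | None:
    """Mean methylation of an island from per-cytosine read data.

    reads_table columns: cpg_position, mean_methylation, n_support (reads);
    rows may appear once per strand per CpG and are averaged. Only
    cytosines with >= lister_min_reads reads count. Returns None unless
    more than half of the island's CpGs are covered, else the mean over
    covered CpGs.
    """
    n_total = len(island_cpg_positions)
    if n_total == 0:
        return None
    pos_set = set(int(p) for p in island_cpg_positions)
    usable = reads_table[
        (reads_table["n_support"] >= thr.lister_min_reads)
        & reads_table["cpg_position"].isin(pos_set)
    ]
    per_cpg = usable.groupby("cpg_position")["mean_methylation"].mean()
    if len(per_cpg) <= thr.island_cpg_coverage * n_total:
        return None
    return float(per_cpg.mean())


@dataclass(frozen=True)
class HeterogeneityResult:
    max_difference: dict
    fraction_above: float
    n_tested: int
    n_skipped: int
    per_tissue: dict = field(default_factory=dict, compare=False)


def swa_heterogeneity(
    outer_islands: Sequence,
    inner_islands: Sequence,
    methylation: pd.DataFrame,
    thr: MethylationThresholds = MethylationThresholds(),
    difference_cutoff: float = 30.0,
) -> HeterogeneityResult:
    """Within-outer-island methylation heterogeneity.

    For every outer (sliding-window) island hosting >= 2 inner (cluster)
    islands, the mean methylation of each inner island is computed per
    tissue (records with < min_clones support are ignored) and the maximum
    absolute difference between inner-island means — over all tissues and
    inner-island pairs — is reported, together with the fraction of tested
    outer islands whose maximum exceeds difference_cutoff (percent points).
    Outer islands with fewer than two measurable inner islands are skipped.
    """
    usable = methylation[methylation["n_support"] >= thr.min_clones]
    max_diff: dict[tuple[str, int, int], float] = {}
    per_tissue_detail: dict[tuple[str, int, int], dict[str, float]] = {}
    n_skipped = 0
    for outer in outer_islands:
        inners = [
            iv
            for iv in inner_islands
            if iv.chrom == outer.chrom and iv.start < outer.end and iv.end > outer.start
        ]
        if len(inners) < 2:
            n_skipped += 1
            continue
        chrom_meth = usable[usable["chrom"] == outer.chrom]
        # per (inner island, tissue) mean over its CpGs
        means: dict[int, dict[str, float]] = {}
        for idx, iv in enumerate(inners):
            sub = chrom_meth[
                (chrom_meth["cpg_position"] >= iv.start) & (chrom_meth["cpg_position"] < iv.end)
            ]
            if sub.empty:
                continue
            means[idx] = sub.groupby("tissue")["mean_methylation"].mean().to_dict()
        tissues = sorted({t for m in means.values() for t in m})
        best = None
        detail = {}
        for tissue in tissues:
            vals = [m[tissue] for m in means.values() if tissue in m]
            if len(vals) < 2:
                continue
            d = max(vals) - min(vals)
            detail[tissue] = d
            best = d if best is None else max(best, d)
        if best is None:
            n_skipped += 1
            continue
        key = (outer.chrom, outer.start, outer.end)
        max_diff[key] = best
        per_tissue_detail[key] = detail
    n_tested = len(max_diff)
    frac = (
        sum(1 for v in max_diff.values() if v > difference_cutoff) / n_tested if n_tested else 0.0
    )
    return HeterogeneityResult(max_diff, frac, n_tested, n_skipped, per_tissue_detail)


@dataclass(frozen=True)
class PairTestResult:
    u_statistic: float
    p_value: float
    significant: bool


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of sample a: #(a_i > b_j) + 0.5 #(a_i == b_j)."""
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def compare_island_pair(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alpha: float = 0.05,
    exact_max_n: int = 7,
) -> PairTestResult:
    """Two-sided Mann-Whitney rank-sum test on two islands' per-CpG values.

    Small samples (both sides <= exact_max_n) are tested by exhaustive
    enumeration of all assignments of the pooled values to the two sides,
    which is exact also under ties; the two-sided p-value is twice the
    smaller tail probability of the U distribution, capped at 1. Larger
    samples use scipy's tie-corrected normal approximation (with continuity
    correction). Significant iff p <= alpha.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both islands need >= 1 covered CpG for the pair test")
    u_obs = _u_statistic(a, b)
    if max(a.size, b.size) <= exact_max_n:
        pooled = np.concatenate([a, b])
        n = pooled.size
        idx = set(range(n))
        us = np.array(
            [
                _u_statistic(pooled[list(comb)], pooled[sorted(idx - set(comb))])
                for comb in itertools.combinations(range(n), a.size)
            ]
        )
        p = min(1.0, 2.0 * min(float(np.mean(us <= u_obs)), float(np.mean(us >= u_obs))))
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(min(res.pvalue, 1.0))
    return PairTestResult(u_obs, p, p <= alpha)
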