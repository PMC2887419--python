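"""Distance-based CpG clustering with negative-binomial significance.

The detector works in two steps. First, the distances between consecutive
CpG starts on a chromosome are computed and CpGs closer than a
distance threshold (a percentile of the intra-chromosome distance
distribution, the median by default) are clustered. Second, each cluster of
N CpGs spanning S = last_start - first_start bases is scored under a null
model in which inter-CpG distances are i.i.d. geometric on {1, 2, ...} with
success probability p_hat = n_cpgs / (chromosome_length - 1): the p-value is
P(sum of N-1 geometric distances <= S), the lower tail of a negative
binomial. Clusters at or below the p-value threshold are reported as
islands. Unlike sliding-window detectors there is no length, GC or O/E
criterion, so statistically significant clusters of any length — including
ones shorter than 200 bp ("islets") — are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError
from .genome_io import ChromSequence, scan_cpg_positions

__all__ = [
    "ClusterParams",
    "DistanceModel",
    "Island",
    "compute_distance_threshold",
    "cluster_cpgs",
    "fit_distance_model",
    "negbin_pvalue",
    "island_properties",
    "predict_islands",
]

RELAXED_PVALUE = 1e-5
STRICT_PVALUE = 1e-20


@dataclass(frozen=True)
class ClusterParams:
    """Parameters of the clustering detector.

    distance_percentile: percentile of the consecutive CpG-start distance
        distribution used as the clustering threshold (50 = median).
    pvalue_threshold: maximum p-value for reporting (1e-5 relaxed, 1e-20 strict).
    min_cpgs: minimum CpGs per cluster; a singleton has no distances and
        therefore no statistic, so the minimum is 2.
    strict_distance: if True, only distances strictly below the threshold
        cluster; by default distance == threshold clusters.
    """

    distance_percentile: float = 50.0
    pvalue_threshold: float = RELAXED_PVALUE
    min_cpgs: int = 2
    strict_distance: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.distance_percentile < 100:
            raise ValueError("distance_percentile must be in (0, 100)")
        if not 0 < self.pvalue_threshold <= 1:
            raise ValueError("pvalue_threshold must be in (0, 1]")
        if self.min_cpgs < 2:
            raise ValueError("min_cpgs must be >= 2")


@dataclass(frozen=True)
class DistanceModel:
    """Null model for one chromosome: geometric inter-CpG distances.

    p_hat is the per-position CpG start probability, estimated as
    n_cpgs / (chromosome_length - 1); threshold is the integer clustering
    distance in bp.
    """

    p_hat: float
    threshold: int

    def __post_init__(self) -> None:
        if not 0 < self.p_hat < 1:
            raise ValueError("p_hat must be in (0, 1)")
        if self.threshold < 2:
            raise ValueError("threshold must be >= 2")


@dataclass(frozen=True)
class Island:
    """A predicted CpG island.

    Coordinates are 0-based half-open; start is the first CpG start and end
    is the last CpG start + 2 so the closing G is included. p_value is None
    for islands that carry no cluster statistic (sliding-window or external
    predictions). source is one of {"cpgcluster", "tj", "external"}.
    """

    chrom: str
    start: int
    end: int
    n_cpg: int
    gc_percent: float
    oe_ratio: float
    cpg_density: float
    p_value: float | None = None
    source: str = "cpgcluster"

    @property
    def length(self) -> int:
        return self.end - self.start


def compute_distance_threshold(cpg_positions: np.ndarray, percentile: float = 50.0) -> int:
    """Percentile of consecutive CpG-start distances, as an integer >= 2.

    For the default median with an even number of distances, the floor of
    the midpoint average of the two central values is used.
    """
    pos = np.asarray(cpg_positions)
    if pos.size < 2:
        raise InsufficientDataError(
            f"need >= 2 CpG positions to compute a distance threshold, got {pos.size}"
        )
    dists = np.diff(pos)
    thr = math.floor(float(np.percentile(dists, percentile, method="midpoint")))
    return max(thr, 2)


def cluster_cpgs(
    cpg_positions: np.ndarray,
    threshold: int,
    min_cpgs: int = 2,
    strict: bool = False,
) -> list[np.ndarray]:
    """Group CpG starts into runs where consecutive distances are <= threshold
    (< threshold when strict). Runs with fewer than min_cpgs CpGs are dropped."""
    pos = np.asarray(cpg_positions)
    if pos.size == 0:
        return []
    dists = np.diff(pos)
    breaks = np.flatnonzero(dists >= threshold if strict else dists > threshold) + 1
    return [run for run in np.split(pos, breaks) if run.size >= min_cpgs]


def fit_distance_model(
    cpg_positions: np.ndarray, chrom_length: int, percentile: float = 50.0
) -> DistanceModel:
    """Estimate the per-chromosome null model and clustering threshold."""
    pos = np.asarray(cpg_positions)
    p_hat = pos.size / (chrom_length - 1)
    return DistanceModel(p_hat=p_hat, threshold=compute_distance_threshold(pos, percentile))


def negbin_pvalue(n_cpg: int, span: int, model: "DistanceModel | float") -> float:
    """Lower-tail cluster p-value P(S <= span).

    S is the sum of (n_cpg - 1) i.i.d. geometric distances on {1, 2, ...}
    with success probability p_hat, i.e. S - (n_cpg - 1) is negative binomial;
    the tail is evaluated through the regularized incomplete beta function
    (scipy's nbinom CDF), not by naive summation.
    """
    p_hat = model.p_hat if isinstance(model, DistanceModel) else float(model)
    if n_cpg < 2:
        raise InsufficientDataError("a cluster needs >= 2 CpGs to have a p-value")
    r = n_cpg - 1
    if span < r:
        raise ValueError(
            f"impossible geometry: span {span} < {r} minimal distances for {n_cpg} CpGs"
        )
    p = float(stats.nbinom.cdf(span - r, r, p_hat))
    # guard against underflow to exactly 0 for extremely dense clusters
    return max(p, float(np.finfo(float).tiny * np.finfo(float).tiny))


def island_properties(seq: "ChromSequence | str", start: int, end: int) -> tuple[float, float, float]:
    """(gc_percent, oe_ratio, cpg_density) of seq[start:end].

    gc_percent = 100 (nC + nG) / L; oe_ratio = nCpG * L / (nC * nG), reported
    as 0 when nC * nG == 0; cpg_density = nCpG / L.
    """
    s = seq.seq if isinstance(seq, ChromSequence) else seq
    if start < 0 or end > len(s) or start >= end:
        raise ValueError(f"island [{start}, {end}) out of sequence bounds (L={len(s)})")
    segment = s[start:end]
    n_c, n_g = segment.count("C"), segment.count("G")
    n_cpg = segment.count("CG")  # CG cannot overlap itself
    length = end - start
    gc = 100.0 * (n_c + n_g) / length
    oe = (n_cpg * length) / (n_c * n_g) if n_c * n_g > 0 else 0.0
    return gc, oe, n_cpg / length


def predict_islands(
    chrom: ChromSequence,
    params: ClusterParams = ClusterParams(),
    model: DistanceModel | None = None,
) -> list[Island]:
    """Run the full detector on one chromosome.

    Pipeline: scan CpGs -> distance threshold -> cluster -> negative-binomial
    p-value -> keep clusters with p <= pvalue_threshold. Chromosomes with
    fewer than 2 CpGs yield no islands. Each chromosome is processed
    independently: the null model is never pooled across records. A
    pre-fitted model can be supplied to reuse one across parameter sweeps.
    """
    positions = scan_cpg_positions(chrom)
    if positions.size < 2:
        return []
    if model is None:
        model = fit_distance_model(positions, chrom.length, params.distance_percentile)
    runs = cluster_cpgs(positions, model.threshold, params.min_cpgs, params.strict_distance)
    islands = []
    for run in runs:
        n = int(run.size)
        span = int(run[-1] - run[0])
        p = negbin_pvalue(n, span, model)
        if p <= params.pvalue_threshold:
            start, end = int(run[0]), int(run[-1]) + 2
            gc, oe, density = island_properties(chrom, start, end)
            islands.append(
                Island(
                    chrom=chrom.name, start=start, end=end, n_cpg=n,
                    gc_percent=gc, oe_ratio=oe, cpg_density=density,
                    p_value=p, source="cpgcluster",
                )
            )
    return islands
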