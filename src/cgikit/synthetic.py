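"""Synthetic genomes, methylation tracks and expression matrices with known
ground truth.

The background sequence model is i.i.d. base composition with CpG starts
injected by a Bernoulli process: spontaneous CG dimers arising from the
base composition are first destroyed, then CG dimers are planted at rate
cpg_prob_background (background) or cpg_prob_island (inside planted island
segments). This makes inter-CpG distances geometric to excellent
approximation — exactly the null the cluster p-value assumes — so analytic
checks remain possible. Planted islands are placed in evenly spaced slots
with jitter, guaranteeing wide separation. Methylation tracks plant
unmethylated, methylated and differentially methylated islands on top of a
methylated background; expression matrices plant coexpressed, divergent and
intermediate gene pairs built from housekeeping-like and tissue-specific
profiles. Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import ChromSequence, GenomicInterval, IntervalSet

__all__ = [
    "SimulationConfig",
    "simulate_genome",
    "simulate_methylation",
    "simulate_expression",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the simulator.

    Defaults: a 2 Mb chromosome with 100 planted islands of mean length
    500 bp (sd 100, floor 250), per-position CpG start probabilities 0.002
    (background) and 0.08 (islands), background GC 38% vs island GC 60%,
    a 12-tissue methylation panel with Gaussian noise (sd 3 percent points)
    and a 73-tissue expression panel.
    """

    seed: int = 0
    genome_length: int = 2_000_000
    n_islands: int = 100
    island_length_mean: float = 500.0
    island_length_sd: float = 100.0
    island_length_min: int = 250
    cpg_prob_background: float = 0.002
    cpg_prob_island: float = 0.08
    gc_background: float = 0.38
    gc_island: float = 0.60
    methylation_noise_sd: float = 3.0
    tissue_count: int = 12
    fraction_differential_islands: float = 0.2
    fraction_methylated_islands: float = 0.15
    fraction_low_support: float = 0.1
    expression_tissues: int = 73

    def __post_init__(self) -> None:
        if not 0 < self.cpg_prob_background < self.cpg_prob_island < 1:
            raise ValueError("need 0 < cpg_prob_background < cpg_prob_island < 1")
        if self.genome_length <= 0 or self.island_length_mean <= 0:
            raise ValueError("lengths must be positive")
        if not 0 <= self.gc_background <= 1 and 0 <= self.gc_island <= 1:
            raise ValueError("GC fractions must be in [0, 1]")


def _sample_bases(rng: np.random.Generator, gc: np.ndarray) -> np.ndarray:
    """Per-position base sampling given a per-position GC fraction."""
    u = rng.random(gc.size)
    # cumulative: A (1-gc)/2 | C gc/2 | G gc/2 | T (1-gc)/2
    at_half = (1.0 - gc) / 2.0
    gc_half = gc / 2.0
    out = np.empty(gc.size, dtype=np.uint8)
    out[:] = _BASES[0]
    out[u >= at_half] = _BASES[1]
    out[u >= at_half + gc_half] = _BASES[2]
    out[u >= at_half + 2 * gc_half] = _BASES[3]
    return out


def _place_islands(rng: np.random.Generator, config: SimulationConfig) -> list[tuple[int, int]]:
    if config.n_islands == 0:
        return []
    slot = config.genome_length // config.n_islands
    placements = []
    for i in range(config.n_islands):
        raw = rng.normal(config.island_length_mean, config.island_length_sd)
        length = int(max(config.island_length_min, round(raw)))
        margin = slot - length - 200  # keep >= 200 bp to the slot edges
        if margin <= 0:
            raise ValueError(
                f"islands of ~{length} bp do not fit {config.n_islands} slots of {slot} bp"
            )
        start = i * slot + 100 + int(rng.integers(0, margin))
        placements.append((start, start + length))
    return placements


def simulate_genome(config: SimulationConfig) -> tuple[ChromSequence, IntervalSet]:
    """Generate one chromosome plus the truth annotation of planted islands."""
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    placements = _place_islands(rng, config)

    gc = np.full(L, config.gc_background)
    cpg_p = np.full(L - 1, config.cpg_prob_background)
    for s, e in placements:
        gc[s:e] = config.gc_island
        cpg_p[s : e - 1] = config.cpg_prob_island

    arr = _sample_bases(rng, gc)
    # destroy spontaneous CG dimers so CpG density is controlled exactly
    spont = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
    arr[spont + 1] = np.where(rng.random(spont.size) < 0.5, ord("A"), ord("T")).astype(np.uint8)
    # inject CG dimers by a Bernoulli process, skipping overlaps
    candidates = np.flatnonzero(rng.random(L - 1) < cpg_p)
    last = -2
    for i in candidates:
        if i - last < 2:
            continue
        arr[i] = ord("C")
        arr[i + 1] = ord("G")
        last = i

    chrom = ChromSequence(name="chr1", seq=arr.tobytes().decode("ascii"))
    truth = IntervalSet(
        name="planted_islands",
        intervals=[
            GenomicInterval(chrom="chr1", start=s, end=e, label=f"island_{i + 1:04d}")
            for i, (s, e) in enumerate(placements)
        ],
    )
    return chrom, truth


def _island_states(rng: np.random.Generator, n: int, config: SimulationConfig) -> list[str]:
    states = []
    for _ in range(n):
        u = rng.random()
        if u < config.fraction_differential_islands:
            states.append("differential")
        elif u < config.fraction_differential_islands + config.fraction_methylated_islands:
            states.append("methylated")
        else:
            states.append("unmethylated")
    return states


def simulate_methylation(
    chrom: ChromSequence, truth: IntervalSet, config: SimulationConfig
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-CpG, per-tissue methylation values with planted island states.

    Background CpGs are methylated (85-95%); planted unmethylated islands
    sit near 5-15%; differential islands are unmethylated in the first half
    of the tissue panel and methylated in the second half. Gaussian noise
    (methylation_noise_sd) is added and values clipped to [0, 100]. A
    fraction_low_support of (CpG, tissue) records carries a single
    supporting clone to exercise the support filter. Returns the long-form
    table and {island label: planted state}.
    """
    from .genome_io import scan_cpg_positions

    rng = np.random.default_rng(config.seed + 1_000_003)
    positions = scan_cpg_positions(chrom)
    tissues = [f"tissue_{i + 1:02d}" for i in range(config.tissue_count)]
    half = config.tissue_count // 2

    states = _island_states(rng, len(truth), config)
    labels = {iv.label: st for iv, st in zip(truth, states)}

    starts = np.array([iv.start for iv in truth], dtype=np.int64)
    ends = np.array([iv.end for iv in truth], dtype=np.int64)
    idx = np.searchsorted(starts, positions, side="right") - 1
    in_island = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])

    rows = []
    for pos, inside, island_i in zip(positions, in_island, idx):
        state = states[island_i] if inside else "methylated"
        for t_i, tissue in enumerate(tissues):
            if state == "unmethylated":
                base = rng.uniform(5, 15)
            elif state == "methylated":
                base = rng.uniform(85, 95)
            else:  # differential: split by tissue-panel half
                base = rng.uniform(5, 15) if t_i < half else rng.uniform(85, 95)
            value = float(np.clip(base + rng.normal(0, config.methylation_noise_sd), 0, 100))
            low = rng.random() < config.fraction_low_support
            n_support = 1 if low else int(rng.integers(2, 12))
            rows.append((chrom.name, int(pos), tissue, value, n_support))
    df = pd.DataFrame(rows, columns=["chrom", "cpg_position", "tissue", "mean_methylation", "n_support"])
    return df, labels


def simulate_expression(
    n_pairs: int, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression matrix plus a gene-pair list with planted coexpression classes.

    Pairs cycle through coexpressed (identical on/off profile), divergent
    (housekeeping vs narrow tissue-specific profile, concordance <= 0.2) and
    intermediate. Off signals are uniform on (20, 150), on signals uniform
    on (300, 5000), so the expressed cutoff of 200 separates them cleanly.
    """
    rng = np.random.default_rng(config.seed + 2_000_003)
    T = config.expression_tissues
    tissues = [f"tissue_{i + 1:02d}" for i in range(T)]
    classes = ["coexpressed", "divergent", "intermediate"]

    def signals(on_mask: np.ndarray) -> np.ndarray:
        off = rng.uniform(20, 150, size=T)
        on = rng.uniform(300, 5000, size=T)
        return np.where(on_mask, on, off)

    expr_rows, pair_rows = [], []
    n_div = max(1, int(0.14 * T))  # concordance n_div/T stays <= 0.2
    for k in range(n_pairs):
        klass = classes[k % 3]
        g_a, g_b = f"gene_{2 * k + 1:04d}", f"gene_{2 * k + 2:04d}"
        if klass == "coexpressed":
            mask_a = rng.random(T) < 0.6
            mask_b = mask_a.copy()
        elif klass == "divergent":
            mask_a = np.ones(T, dtype=bool)  # housekeeping-like, breadth ~1
            mask_b = np.zeros(T, dtype=bool)  # tissue-specific, breadth ~0.15
            mask_b[rng.choice(T, size=n_div, replace=False)] = True
        else:
            mask_a = rng.random(T) < 0.6
            flip = rng.choice(T, size=max(2, T // 4), replace=False)
            mask_b = mask_a.copy()
            mask_b[flip] = ~mask_b[flip]
        for gene, mask in ((g_a, mask_a), (g_b, mask_b)):
            for tissue, sig in zip(tissues, signals(mask)):
                expr_rows.append((gene, tissue, float(sig)))
        pair_rows.append((g_a, g_b, klass))
    expr = pd.DataFrame(expr_rows, columns=["gene", "tissue", "signal"])
    pairs = pd.DataFrame(pair_rows, columns=["gene_a", "gene_b", "planted_class"])
    return expr, pairs
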