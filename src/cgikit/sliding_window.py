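"""Takai-Jones-style sliding-window CpG-island detection.

A window passes when GC content >= min_gc, observed/expected CpG ratio
>= min_oe and the CpG count is at least min_cpg_factor * L / 16 (the guard
against "mathematical" islands, evaluated on the segment's own length L).
The search slides a window 1 bp at a time until it qualifies, jumps by whole
windows while it keeps qualifying, rolls the last window back 1 bp at a time
to the last qualifying position, then trims the candidate segment 1 bp per
side until the whole segment passes all criteria with both ends on a CpG
(the C of the first, the G of the last). Nearby islands separated by at
most merge_gap bp are merged if the merged segment still passes everything;
islands shorter than min_length are discarded at the end. As a consequence,
every reported island satisfies all thresholds over its full extent, which
biases the distributions of island GC, O/E and length towards the
thresholds themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster import Island
from .genome_io import ChromSequence

__all__ = ["TJParams", "window_meets_criteria", "tj_predict"]


@dataclass(frozen=True)
class TJParams:
    """Sliding-window thresholds: length >= 500 bp, GC >= 55%, O/E >= 0.65,
    nCpG >= 0.6 * L / 16; scanning window defaults to min_length; islands
    separated by <= merge_gap bp (default 100) are candidates for merging."""

    min_length: int = 500
    min_gc: float = 55.0
    min_oe: float = 0.65
    min_cpg_factor: float = 0.6
    window: int | None = None
    merge_gap: int = 100

    def __post_init__(self) -> None:
        if self.window is not None and not 0 < self.window <= self.min_length:
            raise ValueError("need min_length >= window > 0")
        if not 0 <= self.min_gc <= 100:
            raise ValueError("min_gc must be in [0, 100]")
        if self.min_oe < 0:
            raise ValueError("min_oe must be >= 0")

    @property
    def effective_window(self) -> int:
        return self.window if self.window is not None else self.min_length


class _CompositionIndex:
    """Prefix-sum index over one sequence for O(1) segment composition."""

    def __init__(self, seq: str):
        a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        self.length = len(a)
        self.cum_c = np.concatenate(([0], np.cumsum(a == ord("C"), dtype=np.int64)))
        self.cum_g = np.concatenate(([0], np.cumsum(a == ord("G"), dtype=np.int64)))
        self.cum_n = np.concatenate(([0], np.cumsum(a == ord("N"), dtype=np.int64)))
        cpg = (a[:-1] == ord("C")) & (a[1:] == ord("G"))
        # cum_cpg[i] = number of CpG starts at positions < i
        self.cum_cpg = np.concatenate(([0], np.cumsum(cpg, dtype=np.int64)))
        self.cpg_starts = np.flatnonzero(cpg)

    def counts(self, a: int, b: int) -> tuple[int, int, int]:
        """(nC, nG, nCpG) over [a, b); only dimers fully inside are counted."""
        n_c = int(self.cum_c[b] - self.cum_c[a])
        n_g = int(self.cum_g[b] - self.cum_g[a])
        hi = max(b - 1, a)
        n_cpg = int(self.cum_cpg[hi] - self.cum_cpg[a])
        return n_c, n_g, n_cpg

    def n_count(self, a: int, b: int) -> int:
        return int(self.cum_n[b] - self.cum_n[a])

    def stats(self, a: int, b: int) -> dict[str, float]:
        n_c, n_g, n_cpg = self.counts(a, b)
        length = b - a
        gc = 100.0 * (n_c + n_g) / length
        oe = (n_cpg * length) / (n_c * n_g) if n_c * n_g > 0 else 0.0
        return {"gc_percent": gc, "oe_ratio": oe, "n_cpg": n_cpg, "length": length}

    def meets(self, a: int, b: int, params: TJParams) -> bool:
        n_c, n_g, n_cpg = self.counts(a, b)
        length = b - a
        if 100.0 * (n_c + n_g) < params.min_gc * length:
            return False
        if n_c * n_g == 0:
            return params.min_oe <= 0 and n_cpg >= params.min_cpg_factor * length / 16.0
        if n_cpg * length < params.min_oe * n_c * n_g:
            return False
        return n_cpg >= params.min_cpg_factor * length / 16.0

    def window_ok(self, w: int, params: TJParams) -> np.ndarray:
        """Boolean qualification of every window start 0 .. L-w."""
        n_c = self.cum_c[w:] - self.cum_c[:-w]
        n_g = self.cum_g[w:] - self.cum_g[:-w]
        n_cpg = self.cum_cpg[w - 1 :] - self.cum_cpg[: self.length - w + 1]
        gc_ok = 100.0 * (n_c + n_g) >= params.min_gc * w
        oe_ok = n_cpg * w >= params.min_oe * n_c * n_g
        if params.min_oe > 0:
            oe_ok &= n_c * n_g > 0
        cpg_ok = n_cpg >= params.min_cpg_factor * w / 16.0
        return gc_ok & oe_ok & cpg_ok


def window_meets_criteria(
    seq: "ChromSequence | str", start: int, window: int, params: TJParams = TJParams()
) -> tuple[bool, dict[str, float]]:
    """Evaluate one window; returns (passes, composition stats)."""
    s = seq.seq if isinstance(seq, ChromSequence) else seq
    if start < 0 or start + window > len(s):
        raise ValueError(f"window [{start}, {start + window}) exceeds sequence length {len(s)}")
    segment = s[start : start + window]
    n_c, n_g = segment.count("C"), segment.count("G")
    n_cpg = segment.count("CG")
    gc = 100.0 * (n_c + n_g) / window
    oe = (n_cpg * window) / (n_c * n_g) if n_c * n_g > 0 else 0.0
    ok = (
        gc >= params.min_gc
        and oe >= params.min_oe
        and n_cpg >= params.min_cpg_factor * window / 16.0
    )
    return ok, {"gc_percent": gc, "oe_ratio": oe, "n_cpg": n_cpg, "length": window}


def _trim(a: int, b: int, ci: _CompositionIndex, params: TJParams) -> tuple[int, int] | None:
    """Shrink [a, b) until the whole segment passes and both ends sit on a CpG."""
    cpg = ci.cpg_starts
    while True:
        lo = int(np.searchsorted(cpg, a, side="left"))
        hi = int(np.searchsorted(cpg, b - 1, side="left")) - 1
        if hi < lo:
            return None
        a2, b2 = int(cpg[lo]), int(cpg[hi]) + 2
        if b2 - a2 < params.min_length:
            return None  # further trimming can only shorten it
        if ci.meets(a2, b2, params):
            return a2, b2
        a, b = a2 + 1, b2 - 1


def tj_predict(chrom: ChromSequence, params: TJParams = TJParams()) -> list[Island]:
    """Run the sliding-window detector on one chromosome.

    Returns disjoint islands sorted by start; every island satisfies all
    criteria over its full extent and is at least min_length long. Islands
    are not merged across a gap consisting entirely of Ns of merge_gap bp
    or more.
    """
    seq = chrom.seq
    length = len(seq)
    w = params.effective_window
    if length < w or length < params.min_length:
        return []
    ci = _CompositionIndex(seq)
    ok = ci.window_ok(w, params)
    qual = np.flatnonzero(ok)
    max_start = length - w

    candidates: list[tuple[int, int]] = []
    qp = 0
    resume = 0
    while qp < qual.size:
        a = int(qual[qp])
        if a < resume:
            qp = int(np.searchsorted(qual, resume, side="left"))
            continue
        # jump forward by whole windows while they qualify
        k = a
        while k + w <= max_start and ok[k + w]:
            k += w
        # roll the failing window back to the last qualifying start
        m = min(k + w, max_start)
        while m > k and not ok[m]:
            m -= 1
        cand = _trim(a, m + w, ci, params)
        if cand is not None:
            candidates.append(cand)
        resume = m + w
        qp = int(np.searchsorted(qual, resume, side="left"))

    # merge nearby islands when the merged segment still qualifies
    merged: list[list[int]] = []
    for a, b in candidates:
        if merged:
            pa, pb = merged[-1]
            gap = a - pb
            all_n_gap = gap > 0 and ci.n_count(pb, a) == gap and gap >= params.merge_gap
            if 0 <= gap <= params.merge_gap and not all_n_gap and ci.meets(pa, b, params):
                merged[-1][1] = b
                continue
        merged.append([a, b])

    islands = []
    for a, b in merged:
        if b - a < params.min_length:
            continue
        st = ci.stats(a, b)
        islands.append(
            Island(
                chrom=chrom.name, start=a, end=b, n_cpg=int(st["n_cpg"]),
                gc_percent=st["gc_percent"], oe_ratio=st["oe_ratio"],
                cpg_density=st["n_cpg"] / (b - a), p_value=None, source="tj",
            )
        )
    return islands
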