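"""Sequence and interval I/O: FASTA reading, CpG scanning, BED reading/writing.

All coordinates, in memory and on disk, are 0-based half-open (BED
convention). Sequences are uppercased on input and any character outside
{A,C,G,T,N} is mapped to N; CpG dinucleotides are never called across an N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

from .errors import FormatError

__all__ = [
    "ChromSequence",
    "GenomicInterval",
    "IntervalSet",
    "read_fasta",
    "write_fasta",
    "scan_cpg_positions",
    "read_bed",
    "write_islands_bed",
    "read_islands_bed",
]

# map every byte outside ACGTN to 'N' (input already uppercased)
_NORMALIZE = bytes.maketrans(
    bytes(range(256)),
    bytes(b if b in b"ACGTN" else ord("N") for b in range(256)),
)


@dataclass(frozen=True)
class ChromSequence:
    """A named DNA sequence over the alphabet {A,C,G,T,N}."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("chromosome name must be non-empty")
        if not self.seq:
            raise FormatError(f"record {self.name!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class IntervalSet:
    """A named collection of genomic intervals, sorted per chromosome on demand."""

    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        for ivs in out.values():
            ivs.sort(key=lambda iv: (iv.start, iv.end))
        return out


def _normalize_seq(raw: str) -> str:
    return raw.upper().encode("ascii", errors="replace").translate(_NORMALIZE).decode("ascii")


def read_fasta(path: str | Path) -> list[ChromSequence]:
    """Read a (multi-record) FASTA file into ChromSequence objects.

    Sequences are uppercased; non-ACGTN characters become N. An empty file
    or a record with an empty sequence raises FormatError.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        seq = _normalize_seq(str(rec.seq))
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        out.append(ChromSequence(name=rec.id, seq=seq))
    return out


def write_fasta(chroms: Iterable[ChromSequence], path: str | Path, width: int = 60) -> None:
    """Write sequences to FASTA with fixed line wrapping (byte-deterministic)."""
    with open(path, "w") as fh:
        for c in chroms:
            fh.write(f">{c.name}\n")
            for i in range(0, len(c.seq), width):
                fh.write(c.seq[i : i + width] + "\n")


def scan_cpg_positions(seq: "ChromSequence | str") -> np.ndarray:
    """Return the 0-based start positions of all CG dimers, strictly increasing.

    Position i is reported iff seq[i] == 'C' and seq[i+1] == 'G'; dimers
    containing N never match.
    """
    s = seq.seq if isinstance(seq, ChromSequence) else seq
    if len(s) < 2:
        return np.empty(0, dtype=np.int64)
    a = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    return np.flatnonzero((a[:-1] == ord("C")) & (a[1:] == ord("G"))).astype(np.int64)


def _parse_bed_line(line: str, lineno: int, path: str) -> GenomicInterval | None:
    stripped = line.strip()
    if not stripped or stripped.startswith(("#", "track", "browser")):
        return None
    fields = stripped.split("\t") if "\t" in stripped else stripped.split()
    if len(fields) < 3:
        raise FormatError(f"{path}, line {lineno}: expected >= 3 BED columns")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise FormatError(f"{path}, line {lineno}: non-integer coordinates") from exc
    if start < 0 or start >= end:
        raise FormatError(
            f"{path}, line {lineno}: invalid interval {chrom}:{start}-{end}"
        )
    label = fields[3] if len(fields) > 3 else ""
    strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
    return GenomicInterval(chrom=chrom, start=start, end=end, strand=strand, label=label)


def read_bed(path: str | Path, name: str | None = None) -> IntervalSet:
    """Read a BED3+ file (0-based half-open) into an IntervalSet.

    Malformed lines raise FormatError naming the line number. Column 4 is
    kept as the label, column 6 (if +/-) as the strand.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            iv = _parse_bed_line(line, lineno, str(path))
            if iv is not None:
                intervals.append(iv)
    return IntervalSet(name=name or Path(path).stem, intervals=intervals)


def _fmt_float(x: float) -> str:
    return f"{x:.6g}"


def write_islands_bed(islands: Sequence, path: str | Path,
                      header_comments: Sequence[str] = ()) -> None:
    """Write islands as BED6+4: name, score, strand, then n_cpg, gc_percent,
    oe_ratio, p_value (scientific notation, 6 significant digits; '.' when the
    island carries no p-value, e.g. sliding-window predictions)."""
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        for i, isl in enumerate(islands, start=1):
            pv = "." if isl.p_value is None else f"{isl.p_value:.5e}"
            fh.write(
                "\t".join(
                    [
                        isl.chrom,
                        str(isl.start),
                        str(isl.end),
                        f"{isl.source}_{i}",
                        "0",
                        ".",
                        str(isl.n_cpg),
                        _fmt_float(isl.gc_percent),
                        _fmt_float(isl.oe_ratio),
                        pv,
                    ]
                )
                + "\n"
            )


def read_islands_bed(path: str | Path) -> list:
    """Read a BED6+4 island file written by :func:`write_islands_bed`."""
    from .cluster import Island  # local import to avoid a cycle

    islands = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split("\t")
            if len(fields) < 10:
                raise FormatError(f"{path}, line {lineno}: expected 10 island columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start < 0 or start >= end:
                raise FormatError(f"{path}, line {lineno}: invalid interval")
            n_cpg = int(fields[6])
            gc, oe = float(fields[7]), float(fields[8])
            pv = None if fields[9] == "." else float(fields[9])
            source = fields[3].rsplit("_", 1)[0]
            islands.append(
                Island(
                    chrom=chrom, start=start, end=end, n_cpg=n_cpg,
                    gc_percent=gc, oe_ratio=oe,
                    cpg_density=n_cpg / (end - start),
                    p_value=pv, source=source,
                )
            )
    return islands
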