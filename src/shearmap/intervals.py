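"""Genomic interval algebra.

All coordinates are 0-based half-open (BED convention). 1-based inclusive
inputs (GTF) are converted at the I/O layer, never here. These primitives —
overlap, merge, summit-centred resize, nearest-TSS — underpin every
downstream stage (peak annotation, co-occupancy intersections, candidate
enhancer construction, loop-anchor classification).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic region [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return self.start + (self.end - self.start) // 2


@dataclass(frozen=True)
class Peak:
    """An interval with a summit (offset relative to start) and a signal value."""

    interval: GenomicInterval
    summit_offset: int
    signal: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.summit_offset < len(self.interval)):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside interval of length "
                f"{len(self.interval)} for peak {self.name!r}"
            )
        if self.signal < 0:
            raise ValueError("signal must be non-negative")

    @property
    def summit(self) -> int:
        """Absolute genomic position of the summit."""
        return self.interval.start + self.summit_offset


@dataclass(frozen=True)
class Gene:
    gene_id: str
    symbol: str
    interval: GenomicInterval
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")

    @property
    def tss(self) -> int:
        """Transcription start site: interval start on +, end-1 on -."""
        if self.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def tes(self) -> int:
        """Transcription end site (last transcribed base)."""
        if self.strand == "+":
            return self.interval.end - 1
        return self.interval.start


def overlaps(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    """True iff a and b share >= min_bp bases under half-open semantics."""
    if min_bp < 0:
        raise ValueError("min_bp must be >= 0")
    if a.chrom != b.chrom:
        return False
    return min(a.end, b.end) - max(a.start, b.start) >= min_bp


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_intervals(regions: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals.

    Returns a sorted, pairwise non-overlapping list covering exactly the
    union of input bases. Book-ended inputs (end == start) merge, matching
    bedtools-merge with distance 0.
    """
    regs = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    out: list[GenomicInterval] = []
    for r in regs:
        if out and out[-1].chrom == r.chrom and r.start <= out[-1].end:
            last = out[-1]
            if r.end > last.end:
                out[-1] = GenomicInterval(last.chrom, last.start, r.end)
        else:
            out.append(GenomicInterval(r.chrom, r.start, r.end))
    return out


def resize_to_summit(p: Peak, width: int) -> GenomicInterval:
    """Resize a peak to a fixed-width window centred on its summit.

    The returned interval satisfies start + width//2 == summit, except when
    that would place start below 0, in which case the window is clipped to
    begin at the chromosome start while preserving its width.
    """
    if width <= 0:
        raise ValueError("width must be >= 1")
    start = p.summit - width // 2
    if start < 0:
        start = 0
    return GenomicInterval(p.interval.chrom, start, start + width)


def nearest_tss(
    r: GenomicInterval, genes: Sequence[Gene]
) -> tuple[Optional[Gene], Optional[int]]:
    """Nearest gene by |region midpoint - TSS| on the same chromosome.

    Returns (gene, signed distance) with distance = midpoint - TSS (genomic
    sign convention). Ties broken by lexicographically smallest gene_id.
    Returns (None, None) when no gene shares the chromosome.
    """
    if not genes:
        raise ValueError("genes must be non-empty")
    mid = r.midpoint
    best: Optional[Gene] = None
    best_d: Optional[int] = None
    for g in genes:
        if g.interval.chrom != r.chrom:
            continue
        d = mid - g.tss
        if (
            best_d is None
            or abs(d) < abs(best_d)
            or (abs(d) == abs(best_d) and best is not None and g.gene_id < best.gene_id)
        ):
            best, best_d = g, d
    return best, best_d
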