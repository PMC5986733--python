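"""Genomic intervals with 1-based inclusive coordinates.

All coordinates inside the package follow the VCF convention (1-based,
both endpoints included); conversion to BED's 0-based half-open scheme
happens only at the I/O boundary (:mod:`founderhap.variant_io`).

Interval length is defined as ``end - start``, the difference of the
printed coordinate pair. This matches how region sizes are conventionally
quoted from coordinate pairs (an 800,000 bp difference is reported as
"800 kb"); the one-basepair discrepancy with an inclusive marker count is
immaterial at the scales involved and is deliberate.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

__all__ = [
    "GenomicInterval",
    "interval_length",
    "format_length",
    "intersect_all",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A chromosome span, 1-based with both endpoints inclusive."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chromosome must be non-empty")
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(
                f"interval start {self.start} exceeds end {self.end} "
                f"on {self.chrom}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def intersect(self, other: "GenomicInterval") -> Optional["GenomicInterval"]:
        """Overlap with ``other``, or None if disjoint or on another chromosome."""
        if self.chrom != other.chrom:
            return None
        lo = max(self.start, other.start)
        hi = min(self.end, other.end)
        if lo > hi:
            return None
        return GenomicInterval(self.chrom, lo, hi)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start:,}-{self.end:,}"


def interval_length(interval: GenomicInterval) -> int:
    """Span of an interval in base pairs (``end - start``)."""
    return interval.length_bp


def format_length(bp: int) -> str:
    """Human-readable length: Mb to one decimal, kb as an integer, else bp.

    Rounding is half-up so that, e.g., 13,995,505 bp renders as "14.0 Mb".
    """
    if bp < 0:
        raise ValueError("length must be non-negative")
    if bp >= 1_000_000:
        mb = (Decimal(bp) / Decimal(1_000_000)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
        return f"{mb} Mb"
    if bp >= 1_000:
        kb = (Decimal(bp) / Decimal(1_000)).quantize(
            Decimal("1"), rounding=ROUND_HALF_UP
        )
        return f"{kb} kb"
    return f"{bp} bp"


def intersect_all(intervals: Sequence[GenomicInterval] | Iterable[GenomicInterval]) -> GenomicInterval:
    """Common overlap of a collection of intervals (max start, min end).

    Raises ValueError on an empty collection, mixed chromosomes, or an
    empty intersection.
    """
    ivs = list(intervals)
    if not ivs:
        raise ValueError("cannot intersect an empty interval collection")
    chroms = {iv.chrom for iv in ivs}
    if len(chroms) > 1:
        raise ValueError(f"intervals span multiple chromosomes: {sorted(chroms)}")
    lo = max(iv.start for iv in ivs)
    hi = min(iv.end for iv in ivs)
    if lo > hi:
        raise ValueError("intervals have an empty common intersection")
    return GenomicInterval(ivs[0].chrom, lo, hi)
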