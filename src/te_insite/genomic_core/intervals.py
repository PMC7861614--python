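"""Genomic interval primitives.

All coordinates are 0-based, half-open (BED convention) throughout the
package, including TSS positions (stored as the start of a width-1
interval).
"""

from __future__ import annotations

from dataclasses import dataclass

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Integer midpoint (floor) of the interval."""
        return (self.start + self.end) // 2

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 if different chromosomes).

    Symmetric; half-open convention means touching intervals overlap by 0.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def gap_to_point(interval: GenomicInterval, position: int) -> int:
    """Distance from a point to the nearest edge of an interval.

    Returns 0 when the point lies inside the interval (or exactly at its
    exclusive end coordinate, which is distance zero from the edge).
    """
    return max(0, interval.start - position, position - interval.end)
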