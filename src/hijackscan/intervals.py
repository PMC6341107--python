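"""Genomic coordinate primitives.

Every coordinate in this package is 0-based, half-open ``[start, end)``,
matching BED. Positions written to FISH/SV tables are 0-based as well,
which the file headers state explicitly.
"""
from __future__ import annotations

from dataclasses import dataclass

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    """An interval on a named sequence; the universal coordinate atom."""

    chrom: str
    start: int
    end: int
    strand: str | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand is not None and self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def gap_to(self, other: "GenomicInterval") -> int:
        """Gap in bp to another interval on the same chromosome.

        Zero when the intervals overlap or touch (end-exclusive semantics:
        ``[0, 500)`` and ``[500, 600)`` have gap 0, ``[0, 500)`` and
        ``[600, 700)`` have gap 100).
        """
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        return max(0, max(self.start, other.start) - min(self.end, other.end))


def sort_key(iv: GenomicInterval) -> tuple[str, int, int]:
    return (iv.chrom, iv.start, iv.end)
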