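"""Genomic interval primitives.

All coordinates in this package are 0-based half-open ``[start, end)``.
External formats that use other conventions (WIG: 1-based; GTF: 1-based
closed) are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A half-open genomic interval ``[start, end)`` on a named chromosome.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded); ``name`` is an
    optional label carried through BED round-trips.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomeInterval") -> int:
        """Number of bases shared with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance(self, other: "GenomeInterval") -> int | None:
        """Gap in bases between the two intervals; 0 when they overlap or abut.

        Returns None for intervals on different chromosomes.
        """
        if self.chrom != other.chrom:
            return None
        if self.overlap(other) > 0:
            return 0
        return max(self.start, other.start) - min(self.end, other.end)

    def expand(self, flank: int, chrom_length: int | None = None) -> "GenomeInterval":
        """Extend by ``flank`` bp on each side, clipped to ``[0, chrom_length)``."""
        start = max(0, self.start - flank)
        end = self.end + flank
        if chrom_length is not None:
            end = min(end, chrom_length)
        return GenomeInterval(self.chrom, start, end, self.strand, self.name)


def merge_intervals(intervals: Iterable[GenomeInterval]) -> list[GenomeInterval]:
    """Collapse a collection of intervals into a sorted, non-overlapping union.

    Abutting intervals (shared boundary under the half-open convention)
    are merged. Names and strands are dropped from merged output.
    """
    by_pos = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomeInterval] = []
    for iv in by_pos:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            last = out[-1]
            if iv.end > last.end:
                out[-1] = GenomeInterval(last.chrom, last.start, iv.end)
        else:
            out.append(GenomeInterval(iv.chrom, iv.start, iv.end))
    return out


def match_by_reciprocal_overlap(
    called: Sequence[GenomeInterval],
    truth: Sequence[GenomeInterval],
    min_frac: float = 0.5,
) -> tuple[set[int], set[int]]:
    """Pair called intervals with truth intervals by reciprocal overlap.

    A called interval matches a truth interval when their shared bases cover
    at least ``min_frac`` of EACH interval. Returns index sets
    ``(matched_called, matched_truth)``. Used to score recovery of planted
    islands by the peak caller.
    """
    matched_called: set[int] = set()
    matched_truth: set[int] = set()
    truth_sorted = sorted(range(len(truth)), key=lambda j: (truth[j].chrom, truth[j].start))
    for i, c in enumerate(called):
        for j in truth_sorted:
            t = truth[j]
            ov = c.overlap(t)
            if ov >= min_frac * len(c) and ov >= min_frac * len(t):
                matched_called.add(i)
                matched_truth.add(j)
    return matched_called, matched_truth
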