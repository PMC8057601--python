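"""Genomic interval primitives and arithmetic.

Internal convention everywhere in this package: 0-based, half-open
``[start, end)`` coordinates. GFF3 I/O converts from/to the 1-based closed
convention of that format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = ["Interval", "merge_intervals", "subtract_intervals", "total_length"]

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class Interval:
    """A half-open genomic interval on a named sequence.

    ``start`` is 0-based inclusive, ``end`` exclusive, so the interval
    covers ``end - start`` bases (at least one).
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end}: "
                "start must be < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r} on {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def _by_chrom(intervals: Iterable[Interval]) -> dict[str, list[Interval]]:
    out: dict[str, list[Interval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    for ivs in out.values():
        ivs.sort(key=lambda x: (x.start, x.end))
    return out


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Collapse overlapping or touching intervals into maximal disjoint ones.

    Strand is dropped (merged intervals carry '.'); output is sorted by
    (chrom, start).
    """
    merged: list[Interval] = []
    groups = _by_chrom(intervals)
    for chrom in sorted(groups):
        cur_start = cur_end = None
        for iv in groups[chrom]:
            if cur_start is None:
                cur_start, cur_end = iv.start, iv.end
            elif iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(Interval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        if cur_start is not None:
            merged.append(Interval(chrom, cur_start, cur_end))
    return merged


def subtract_intervals(
    minuend: Sequence[Interval], subtrahend: Sequence[Interval]
) -> list[Interval]:
    """Base positions of ``minuend`` not covered by ``subtrahend``.

    Both operands may span multiple sequences; subtraction only applies
    within a sequence. The result is the set difference expressed as
    maximal disjoint intervals, sorted by (chrom, start).
    """
    minu = merge_intervals(minuend)
    sub_groups = _by_chrom(merge_intervals(subtrahend))
    out: list[Interval] = []
    for iv in minu:
        cursor = iv.start
        for s in sub_groups.get(iv.chrom, []):
            if s.end <= cursor:
                continue
            if s.start >= iv.end:
                break
            if s.start > cursor:
                out.append(Interval(iv.chrom, cursor, s.start))
            cursor = max(cursor, s.end)
            if cursor >= iv.end:
                break
        if cursor < iv.end:
            out.append(Interval(iv.chrom, cursor, iv.end))
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    """Number of distinct bases covered (overlaps counted once)."""
    return sum(len(iv) for iv in merge_intervals(intervals))
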