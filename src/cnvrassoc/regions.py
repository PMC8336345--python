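"""Genomic interval sets in BED convention (0-based, half-open)."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

from intervaltree import IntervalTree

__all__ = ["RegionSet"]


class RegionSet:
    """A union of half-open genomic intervals keyed by chromosome.

    Intervals are merged on construction, so membership and overlap queries
    see the union of the input regions.
    """

    def __init__(self, intervals: Iterable[tuple[int, int, int]] = ()):
        self._trees: dict[int, IntervalTree] = {}
        for chrom, start, end in intervals:
            if start > end:
                raise ValueError(f"inverted interval {start}>{end} on chr{chrom}")
            if start == end:
                continue  # empty in half-open convention
            self._trees.setdefault(int(chrom), IntervalTree()).addi(int(start), int(end))
        for tree in self._trees.values():
            tree.merge_overlaps(strict=False)

    def __iter__(self) -> Iterator[tuple[int, int, int]]:
        for chrom in sorted(self._trees):
            for iv in sorted(self._trees[chrom]):
                yield (chrom, iv.begin, iv.end)

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return list(self) == list(other)

    def overlap_bp(self, chrom: int, start: int, end: int) -> int:
        """Total bp of [start, end) covered by the region union."""
        tree = self._trees.get(int(chrom))
        if tree is None:
            return 0
        total = 0
        for iv in tree.overlap(start, end):
            total += min(end, iv.end) - max(start, iv.begin)
        return total

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self:
                fh.write(f"chr{chrom}\t{start}\t{end}\n")

    @classmethod
    def from_bed(cls, path: str | Path) -> "RegionSet":
        intervals = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: not a BED line: {line!r}")
                chrom = fields[0].removeprefix("chr")
                try:
                    intervals.append((int(chrom), int(fields[1]), int(fields[2])))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from None
        return cls(intervals)
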