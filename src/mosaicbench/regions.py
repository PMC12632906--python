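"""Genome interval sets (masks, confident regions, negative-control regions).

Intervals are held per-chromosome in interval trees. The on-disk format is
BED (0-based, half-open); in memory, membership queries take 1-based VCF
positions, converted at this boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from intervaltree import IntervalTree

__all__ = ["GenomeRegions"]


@dataclass
class GenomeRegions:
    """A set of genomic intervals with 1-based point-membership queries."""

    trees: dict[str, IntervalTree] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[str, int, int]]) -> "GenomeRegions":
        """Build from (chrom, start, end) triples in BED coordinates
        (0-based start, exclusive end)."""
        regions = cls()
        for chrom, start, end in intervals:
            if end <= start:
                raise ValueError(f"empty/negative interval {chrom}:{start}-{end}")
            regions.trees.setdefault(chrom, IntervalTree()).addi(start, end)
        for tree in regions.trees.values():
            tree.merge_overlaps(strict=False)
        return regions

    @classmethod
    def from_bed(cls, path: str | Path) -> "GenomeRegions":
        intervals = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
                intervals.append((parts[0], int(parts[1]), int(parts[2])))
        return cls.from_intervals(intervals)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self.intervals():
                fh.write(f"{chrom}\t{start}\t{end}\n")

    def intervals(self) -> Iterator[tuple[str, int, int]]:
        """Yield merged (chrom, start0, end0) sorted by chrom then start."""
        for chrom in sorted(self.trees):
            for iv in sorted(self.trees[chrom]):
                yield chrom, iv.begin, iv.end

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        tree = self.trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos - 1))

    def total_length(self) -> int:
        return sum(iv.end - iv.begin for tree in self.trees.values() for iv in tree)

    def is_empty(self) -> bool:
        return all(len(t) == 0 for t in self.trees.values())

    def __contains__(self, locus: tuple[str, int]) -> bool:
        return self.contains(*locus)
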