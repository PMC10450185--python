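"""Genomic interval primitives.

All coordinates package-wide are 0-based half-open ([start, end)), the BED
convention; the GTF reader/writer converts at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval on one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome / contig name.
    start : int
        0-based inclusive start.
    end : int
        Exclusive end; must satisfy ``start < end``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strand-agnostic overlap test (shared chromosome, >=1 shared base)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def expand(self, flank: int) -> "GenomicInterval":
        """Widen by ``flank`` bases on both sides, clipped at 0."""
        return GenomicInterval(
            self.chrom, max(0, self.start - flank), self.end + flank, self.strand
        )


def merge_intervals(
    intervals: Iterable[GenomicInterval], bookended: bool = True
) -> list[GenomicInterval]:
    """Union of intervals: overlapping (and, by default, bookended) runs merge.

    Input may span several chromosomes; strand is dropped in favour of the
    first interval's strand within each merged run only when all members
    agree, else ``.``.
    """
    ivs = sorted(intervals, key=lambda g: (g.chrom, g.start, g.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out:
            last = out[-1]
            joined = iv.start <= last.end if bookended else iv.start < last.end
            if iv.chrom == last.chrom and joined:
                strand = last.strand if last.strand == iv.strand else "."
                out[-1] = GenomicInterval(
                    last.chrom, last.start, max(last.end, iv.end), strand
                )
                continue
        out.append(iv)
    return out


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    """Number of distinct bases covered (merges internally)."""
    return sum(len(iv) for iv in merge_intervals(intervals))


def intersect_length(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> int:
    """Bases covered by both interval sets (each merged first)."""
    ma, mb = merge_intervals(a), merge_intervals(b)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in mb:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    covered = 0
    for iv in ma:
        for other in by_chrom.get(iv.chrom, ()):
            lo = max(iv.start, other.start)
            hi = min(iv.end, other.end)
            if lo < hi:
                covered += hi - lo
    return covered


def coverage_fraction(
    target: Sequence[GenomicInterval], track: Sequence[GenomicInterval]
) -> float:
    """Fraction of ``target`` bases covered by ``track`` intervals, in [0, 1]."""
    denom = total_length(target)
    if denom == 0:
        raise ValueError("empty target intervals")
    return intersect_length(target, track) / denom


def span(intervals: Sequence[GenomicInterval]) -> GenomicInterval:
    """Genomic extent (first start to last end) of a one-chromosome set."""
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) != 1:
        raise ValueError(f"span requires one chromosome, got {sorted(chroms)}")
    strands = {iv.strand for iv in intervals}
    strand = strands.pop() if len(strands) == 1 else "."
    return GenomicInterval(
        next(iter(chroms)),
        min(iv.start for iv in intervals),
        max(iv.end for iv in intervals),
        strand,
    )
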