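"""Core in-memory domain types shared across the pipeline stages."""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .intervals import GenomicInterval, merge_intervals, span

KINDS = ("representative", "intron_retaining", "intergenic")

CONDITIONS = ("conventional", "improved")

_SAMPLE_RE = re.compile(r"^(?P<cell>[A-Za-z0-9]+)_(?P<cond>conventional|improved)_rep(?P<rep>\d+)$")


@dataclass(frozen=True)
class SampleInfo:
    """Sample metadata decoded from a ``<cellline>_<condition>_rep<k>`` column name."""

    name: str
    cell_line: str
    condition: str
    replicate: int

    @classmethod
    def parse(cls, name: str) -> "SampleInfo":
        m = _SAMPLE_RE.match(name)
        if m is None:
            raise ValueError(
                f"sample name {name!r} does not follow <cellline>_<condition>_rep<k> "
                f"with condition in {CONDITIONS}"
            )
        return cls(name, m.group("cell"), m.group("cond"), int(m.group("rep")))


@dataclass
class TranscriptModel:
    """A strand-aware chain of exon intervals.

    ``kind`` distinguishes the three classes making up the reference
    transcriptome: per-gene exon-union models (``representative``), those
    models merged with their retained introns (``intron_retaining``), and
    assembled transcripts surviving the genomic-distance filter
    (``intergenic``).
    """

    id: str
    gene_id: str
    exons: list[GenomicInterval]
    kind: str = "representative"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown transcript kind {self.kind!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"transcript {self.id} mixes chromosomes or strands")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"transcript {self.id} has overlapping exons")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length(self) -> int:
        """Spliced length: the summed exon lengths, in nt."""
        return sum(len(e) for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        """Genomic extent from first exon start to last exon end."""
        return span(self.exons)

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, 5'->3' in genomic order."""
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if a.end < b.start
        ]


@dataclass
class IntronRecord:
    """One intron of a representative transcript with the FPKM evidence
    needed for its retention score.

    ``index`` is 1-based: intron i sits between exon i and exon i+1.
    ``intron_fpkm`` / ``exon5_fpkm`` / ``exon3_fpkm`` map the improved-
    extraction sample (one per cell line, replicate-averaged) to FPKM.
    """

    gene_id: str
    index: int
    interval: GenomicInterval
    intron_fpkm: dict[str, float]
    exon5_fpkm: dict[str, float]
    exon3_fpkm: dict[str, float]
    rs: float | None = None

    def __post_init__(self) -> None:
        for m in (self.intron_fpkm, self.exon5_fpkm, self.exon3_fpkm):
            for k, v in m.items():
                if v < 0:
                    raise ValueError(
                        f"negative FPKM {v} for {self.gene_id} intron {self.index} ({k})"
                    )


class ExpressionTable:
    """Per-feature abundance matrix (counts or FPKM) with decoded samples.

    A thin wrapper over a feature x sample ``pandas.DataFrame`` whose column
    names follow the ``<cellline>_<condition>_rep<k>`` scheme.
    """

    def __init__(self, data: pd.DataFrame, kind: str = "counts"):
        if data.index.duplicated().any():
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        self.data = data
        self.kind = kind
        self.samples = [SampleInfo.parse(c) for c in data.columns]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_lines(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.cell_line not in seen:
                seen.append(s.cell_line)
        return seen

    def columns_for(self, cell_line: str, condition: str | None = None) -> list[str]:
        return [
            s.name
            for s in self.samples
            if s.cell_line == cell_line and (condition is None or s.condition == condition)
        ]

    def subset(self, cell_line: str, condition: str | None = None) -> pd.DataFrame:
        cols = self.columns_for(cell_line, condition)
        if not cols:
            raise ValueError(f"no samples for {cell_line}/{condition}")
        return self.data[cols]


@dataclass
class TrackAnnotation:
    """A named set of labeled genomic intervals (repeats, chromatin states,
    RNA-end contacts)."""

    name: str
    records: list[tuple[GenomicInterval, str]]

    def intervals(self, label: str | None = None) -> list[GenomicInterval]:
        return [iv for iv, lab in self.records if label is None or lab == label]

    def labels(self) -> list[str]:
        seen: list[str] = []
        for _, lab in self.records:
            if lab not in seen:
                seen.append(lab)
        return seen


@dataclass
class DifferentialResult:
    """Per-transcript differential outcome for one cell line."""

    transcript_id: str
    cell_line: str
    avg_fpkm: float
    log2fc: float
    pvalue: float
    category: str  # Low | Up | Down | NS
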