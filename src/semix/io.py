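"""Readers and writers for the external formats the pipeline touches.

Every other module consumes and produces in-memory domain types only; all
format knowledge (GTF's 1-based closed coordinates, BED's 0-based half-open,
MEME motif blocks, TSV matrices) lives here.
"""

from __future__ import annotations

import gzip
import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval
from .models import ExpressionTable, TranscriptModel, TrackAnnotation

log = logging.getLogger("semix")

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class ParseError(ValueError):
    pass


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


# ---------------------------------------------------------------------------
# GTF


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon features of a GTF file into transcript models.

    GTF is 1-based with closed ends; coordinates are converted to the
    package-wide 0-based half-open convention. Exons are grouped by
    ``transcript_id`` and sorted by start. A ``transcript_kind`` attribute,
    when present, is honoured (written by :func:`write_gtf`).
    """
    exons: dict[str, list[GenomicInterval]] = {}
    gene_of: dict[str, str] = {}
    kind_of: dict[str, str] = {}
    bounds: dict[str, tuple[int, int]] = {}
    order: list[str] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start_i < 1 or end_i < start_i:
                raise ParseError(f"{path}:{lineno}: invalid GTF coordinates {start}-{end}")
            attr = dict(_ATTR_RE.findall(attrs))
            tid = attr.get("transcript_id")
            gid = attr.get("gene_id", tid)
            if feature == "transcript" and tid:
                bounds[tid] = (start_i - 1, end_i)
                continue
            if feature != "exon":
                continue
            if tid is None:
                raise ParseError(f"{path}:{lineno}: exon without transcript_id")
            iv = GenomicInterval(chrom, start_i - 1, end_i, strand)
            tb = bounds.get(tid)
            if tb is not None and (iv.start < tb[0] or iv.end > tb[1]):
                log.warning(
                    "%s:%d: exon outside declared transcript bounds for %s; kept",
                    path,
                    lineno,
                    tid,
                )
            if tid not in exons:
                order.append(tid)
            exons.setdefault(tid, []).append(iv)
            gene_of[tid] = gid
            if "transcript_kind" in attr:
                kind_of[tid] = attr["transcript_kind"]
    models = [
        TranscriptModel(
            id=tid,
            gene_id=gene_of[tid],
            exons=sorted(exons[tid], key=lambda e: e.start),
            kind=kind_of.get(tid, "representative"),
        )
        for tid in order
    ]
    log.info("read_gtf: %s -> %d transcripts", path, len(models))
    return models


def write_gtf(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as GTF exon lines (plus transcript lines)."""
    with open(path, "w") as fh:
        for m in models:
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.id}"; '
                f'transcript_kind "{m.kind}";'
            )
            s = m.span
            fh.write(
                f"{m.chrom}\tsemix\ttranscript\t{s.start + 1}\t{s.end}\t.\t"
                f"{m.strand}\t.\t{attrs}\n"
            )
            for e in m.exons:
                fh.write(
                    f"{m.chrom}\tsemix\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """Read a (possibly gzipped) BED3+ file; name column kept as the label.

    Records with ``start >= end`` are rejected with a warning rather than
    silently coerced.
    """
    records: list[tuple[GenomicInterval, str]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer BED coordinate") from exc
            if start >= end or start < 0:
                log.warning("%s:%d: rejected BED record with start >= end", path, lineno)
                continue
            label = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-." else "."
            records.append((GenomicInterval(chrom, start, end, strand), label))
    log.info("read_bed: %s -> %d records", path, len(records))
    return records


def read_track(path: str | Path, name: str) -> TrackAnnotation:
    return TrackAnnotation(name=name, records=read_bed(path))


def write_bed(records: Iterable[tuple[GenomicInterval, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv, label in records:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label or '.'}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# TSV matrices


def read_counts(path: str | Path) -> ExpressionTable:
    """Read an integer count matrix (feature_id + sample columns).

    Non-integer or missing cells are errors, never coerced to zero.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][:5].tolist()
        raise ParseError(f"{path}: missing count cells for features {bad}")
    float_view = df.astype(float)
    if not (float_view == np.floor(float_view)).all().all():
        raise ParseError(f"{path}: non-integer counts present")
    if (float_view < 0).any().any():
        raise ParseError(f"{path}: negative counts present")
    int_view = float_view.astype(np.int64)
    int_view.index.name = None
    table = ExpressionTable(int_view, kind="counts")
    log.info("read_counts: %s -> %d features x %d samples", path, *df.shape)
    return table


def read_fpkm(path: str | Path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ParseError(f"{path}: missing FPKM cells")
    df = df.astype(float)
    df.index.name = None
    return ExpressionTable(df, kind="fpkm")


def write_table(df: pd.DataFrame, path: str | Path, index_label: str = "feature_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, lineterminator="\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Motif files

_ALPHABET = "ACGU"


def read_meme_motifs(path: str | Path) -> dict[str, np.ndarray]:
    """Parse a minimal MEME-format motif file into name -> (w, 4) matrices.

    Columns follow the file's declared alphabet order, remapped to ACGU
    (T treated as U).
    """
    motifs: dict[str, np.ndarray] = {}
    name = None
    rows: list[list[float]] = []
    expect = 0
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                if name is not None and rows:
                    motifs[name] = np.array(rows)
                parts = line.split()
                name = parts[1]
                rows = []
                expect = 0
            elif line.startswith("letter-probability matrix"):
                m = re.search(r"w=\s*(\d+)", line)
                expect = int(m.group(1)) if m else 0
            elif name is not None and line and (line[0].isdigit() or line[0] == "."):
                vals = [float(x) for x in line.split()]
                if len(vals) == 4:
                    rows.append(vals)
        if name is not None and rows:
            motifs[name] = np.array(rows)
    for nm, mat in motifs.items():
        if not np.allclose(mat.sum(axis=1), 1.0, atol=5e-2):
            raise ParseError(f"{path}: motif {nm} rows do not sum to ~1")
    return motifs


def write_meme_motifs(motifs: dict[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGU\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 U 0.25\n\n")
        for name, mat in motifs.items():
            fh.write(f"MOTIF {name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {len(mat)} nsites= 20 E= 0\n")
            for row in mat:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_cisbp_tsv(path: str | Path) -> np.ndarray:
    """Read a CIS-BP-style 4-column probability matrix TSV (Pos A C G U)."""
    df = pd.read_csv(path, sep="\t")
    cols = [c for c in df.columns if c.upper() in ("A", "C", "G", "U", "T")]
    if len(cols) != 4:
        raise ParseError(f"{path}: expected 4 base columns, found {cols}")
    ordered = sorted(cols, key=lambda c: _ALPHABET.index(c.upper().replace("T", "U")))
    return df[ordered].to_numpy(dtype=float)
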