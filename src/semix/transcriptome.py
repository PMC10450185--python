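"""Reference transcriptome construction.

Three transcript classes are assembled into the reference used for
semi-extractability calling:

* **representative** — per gene, the union of all annotated exons collapsed
  into a single exon chain;
* **intron-retaining** — a representative transcript merged with every
  intron whose expression evidence supports retention (mean intron FPKM
  > 0.1 and retention score > 0.1 across the improved-extraction samples);
* **intergenic** — assembled transcripts whose genomic span stays clear of
  every representative transcript extended by 5000 nt on both sides.

The retention score of intron i pools the improved-extraction samples j
(one per cell line):

    RS_i = 2 * sum_j I_i^j / (sum_j E_i^j + sum_j E_{i+1}^j)

where I is the intron FPKM and E the FPKM of the flanking exons. A zero
denominator leaves RS undefined and the intron is treated as not retained.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

from .config import RunConfig
from .intervals import GenomicInterval, merge_intervals
from .models import ExpressionTable, IntronRecord, TranscriptModel

log = logging.getLogger("semix")


def collapse_exons(
    gene_id: str, exons: Sequence[GenomicInterval], transcript_id: str | None = None
) -> TranscriptModel:
    """Collapse all annotated exons of one gene into a representative model.

    The output exon chain is the base-set union of the inputs; overlapping
    and bookended exons merge (bookended exons define no intron). Idempotent
    and input-order invariant.
    """
    if not exons:
        raise ValueError(f"gene {gene_id}: no exons to collapse")
    strands = {e.strand for e in exons}
    chroms = {e.chrom for e in exons}
    if len(strands) > 1:
        raise ValueError(f"gene {gene_id}: mixed strands {sorted(strands)}")
    if len(chroms) > 1:
        raise ValueError(f"gene {gene_id}: mixed chromosomes {sorted(chroms)}")
    merged = merge_intervals(exons, bookended=True)
    return TranscriptModel(
        id=transcript_id or f"{gene_id}.rep",
        gene_id=gene_id,
        exons=merged,
        kind="representative",
    )


def retention_score(intron: IntronRecord) -> float | None:
    """Retention score pooled over the improved-extraction samples.

    Returns ``None`` when the flanking-exon denominator is zero (no
    expression evidence; the intron is then treated as not retained).
    """
    samples = sorted(intron.intron_fpkm)
    missing = [s for s in samples if s not in intron.exon5_fpkm or s not in intron.exon3_fpkm]
    if missing:
        raise ValueError(
            f"{intron.gene_id} intron {intron.index}: flanking exon FPKM missing for {missing}"
        )
    num = 2.0 * sum(intron.intron_fpkm[s] for s in samples)
    den = sum(intron.exon5_fpkm[s] for s in samples) + sum(
        intron.exon3_fpkm[s] for s in samples
    )
    if den == 0.0:
        return None
    return num / den


def call_retained_introns(
    introns: Iterable[IntronRecord], config: RunConfig | None = None
) -> list[IntronRecord]:
    """Keep introns with mean FPKM > threshold AND RS > threshold (strict).

    The FPKM criterion is the mean intron FPKM across the improved-
    extraction samples. Scores are computed (and stored on the record) if
    not already present.
    """
    config = config or RunConfig()
    kept: list[IntronRecord] = []
    n_undefined = 0
    for intron in introns:
        rs = intron.rs if intron.rs is not None else retention_score(intron)
        if rs is None:
            n_undefined += 1
            continue
        intron.rs = rs
        mean_fpkm = sum(intron.intron_fpkm.values()) / max(1, len(intron.intron_fpkm))
        if mean_fpkm > config.intron_fpkm_min and rs > config.rs_min:
            kept.append(intron)
    if n_undefined:
        log.info("call_retained_introns: %d introns had undefined RS (zero denominator)", n_undefined)
    return kept


def intron_records_from_tables(
    representatives: Sequence[TranscriptModel],
    exon_fpkm: "ExpressionTable",
    intron_fpkm: "ExpressionTable",
) -> list[IntronRecord]:
    """Join per-exon / per-intron FPKM tables onto representative models.

    Feature ids follow ``<gene>:exon<i>`` / ``<gene>:intron<i>`` (1-based,
    genomic order); intron i is flanked by exons i and i+1. Only the
    improved-extraction samples enter the evidence, replicates averaged to
    one value per cell line. Introns without a row in the intron table are
    skipped (no retention evidence).
    """
    by_cell_e = _per_cell_improved_means(exon_fpkm)
    by_cell_i = _per_cell_improved_means(intron_fpkm)
    records: list[IntronRecord] = []
    for rep in representatives:
        for i, iv in enumerate(rep.introns(), start=1):
            ikey = f"{rep.gene_id}:intron{i}"
            if ikey not in by_cell_i.index:
                continue
            e5, e3 = f"{rep.gene_id}:exon{i}", f"{rep.gene_id}:exon{i + 1}"
            missing = [k for k in (e5, e3) if k not in by_cell_e.index]
            if missing:
                raise ValueError(f"exon FPKM rows missing: {missing}")
            records.append(
                IntronRecord(
                    gene_id=rep.gene_id,
                    index=i,
                    interval=iv,
                    intron_fpkm=by_cell_i.loc[ikey].to_dict(),
                    exon5_fpkm=by_cell_e.loc[e5].to_dict(),
                    exon3_fpkm=by_cell_e.loc[e3].to_dict(),
                )
            )
    return records


def _per_cell_improved_means(table: "ExpressionTable"):
    """Feature x cell-line means over the improved-extraction samples."""
    import pandas as pd

    cols = [s for s in table.samples if s.condition == "improved"]
    if not cols:
        raise ValueError("no improved-extraction samples in table")
    groups: dict[str, list[str]] = {}
    for s in cols:
        groups.setdefault(s.cell_line, []).append(s.name)
    return pd.DataFrame(
        {cell: table.data[names].mean(axis=1) for cell, names in groups.items()}
    )


def build_intron_retaining(
    representative: TranscriptModel, retained: Sequence[IntronRecord]
) -> TranscriptModel | None:
    """Merge retained introns into the representative exon chain.

    Returns ``None`` when no intron is retained (no sibling model is
    created). The representative model itself is left untouched; a gene may
    hold both models in the reference.
    """
    if not retained:
        return None
    intron_gaps = {(iv.start, iv.end) for iv in representative.introns()}
    pieces: list[GenomicInterval] = list(representative.exons)
    for rec in retained:
        if rec.gene_id != representative.gene_id:
            raise ValueError(
                f"intron of gene {rec.gene_id} offered to {representative.gene_id}"
            )
        if (rec.interval.start, rec.interval.end) not in intron_gaps:
            raise ValueError(
                f"intron [{rec.interval.start},{rec.interval.end}) of {rec.gene_id} "
                "is not flanked by representative exons"
            )
        pieces.append(
            GenomicInterval(
                representative.chrom,
                rec.interval.start,
                rec.interval.end,
                representative.strand,
            )
        )
    return TranscriptModel(
        id=f"{representative.gene_id}.ir",
        gene_id=representative.gene_id,
        exons=merge_intervals(pieces, bookended=True),
        kind="intron_retaining",
    )


def filter_intergenic(
    assembled: Iterable[TranscriptModel],
    representatives: Sequence[TranscriptModel],
    flank: int = 5000,
) -> list[TranscriptModel]:
    """Keep assembled transcripts clear of every representative span +/- flank.

    The comparison is strand-agnostic: proximity to a gene on either strand
    excludes a transcript. Survivors are re-kinded ``intergenic``.
    """
    exclusion = [rep.span.expand(flank) for rep in representatives]
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in exclusion:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    kept: list[TranscriptModel] = []
    n_in = 0
    for t in assembled:
        n_in += 1
        s = t.span
        if any(s.overlaps(iv) for iv in by_chrom.get(s.chrom, ())):
            continue
        kept.append(
            TranscriptModel(id=t.id, gene_id=t.gene_id, exons=t.exons, kind="intergenic")
        )
    log.info("filter_intergenic: %d assembled -> %d intergenic (flank %d nt)", n_in, len(kept), flank)
    return kept


def assemble_reference(
    representatives: Sequence[TranscriptModel],
    intron_retaining: Sequence[TranscriptModel],
    intergenic: Sequence[TranscriptModel],
) -> list[TranscriptModel]:
    """Concatenate the three transcript classes; ids must be unique."""
    reference = list(representatives) + list(intron_retaining) + list(intergenic)
    seen: set[str] = set()
    for t in reference:
        if t.id in seen:
            raise ValueError(f"duplicate transcript id {t.id} in reference")
        seen.add(t.id)
    log.info(
        "assemble_reference: %d representative + %d intron-retaining + %d intergenic = %d",
        len(representatives),
        len(intron_retaining),
        len(intergenic),
        len(reference),
    )
    return reference


def build_reference(
    annotation: Sequence[TranscriptModel],
    introns: Iterable[IntronRecord],
    assembled: Sequence[TranscriptModel],
    config: RunConfig | None = None,
) -> list[TranscriptModel]:
    """Full reference construction from annotation + FPKM evidence + assembly.

    Collapses annotated exons per gene, calls retained introns, forms
    intron-retaining siblings, filters assembled transcripts to intergenic
    ones, and concatenates.
    """
    config = config or RunConfig()
    by_gene: dict[str, list[GenomicInterval]] = {}
    for t in annotation:
        by_gene.setdefault(t.gene_id, []).extend(t.exons)
    representatives = [collapse_exons(g, exs) for g, exs in by_gene.items()]
    rep_of = {r.gene_id: r for r in representatives}

    retained = call_retained_introns(introns, config)
    by_gene_introns: dict[str, list[IntronRecord]] = {}
    for rec in retained:
        by_gene_introns.setdefault(rec.gene_id, []).append(rec)
    ir_models = []
    for gid, recs in by_gene_introns.items():
        model = build_intron_retaining(rep_of[gid], recs)
        if model is not None:
            ir_models.append(model)

    intergenic = filter_intergenic(assembled, representatives, config.intergenic_flank_nt)
    return assemble_reference(representatives, ir_models, intergenic)
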