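"""Self-consistent synthetic dataset with known ground truth.

The generator emulates the study design end to end on one synthetic
chromosome: multi-exon genes on both strands with annotated isoforms,
planted intron retention at known levels, intergenic transcripts both near
(< 5000 nt) and far (>= 5000 nt) from genes, negative-binomial counts for
the conventional and improved extraction conditions in every cell line
(library sizes deliberately varying up to 2x), exon/intron FPKM tables
consistent with the same expression state, repeat / chromatin-state /
RNA-end interval tracks with planted SE-vs-EX differences, transcript
sequences whose k-mer composition encodes planted communities (one of
which carries AU-rich motif sites in its 5' regions), subcellular
localization abundances, and a hub-RNA list enriched in the SE set.

Counts are generated at transcript level directly (no read simulation);
the pipeline's inputs are tables, so alignment realism is out of scope.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io
from .config import DEFAULT_CELL_LINES
from .intervals import GenomicInterval, merge_intervals
from .models import ExpressionTable, TrackAnnotation, TranscriptModel
from .transcriptome import collapse_exons

CHROM = "chrS"

COMPARTMENTS = ("NU", "NC", "NL", "NP", "CY", "EM", "OM", "MM", "EL")
_NUCLEAR = ("NU", "NC", "NL", "NP")

# community base compositions (A, C, G, U); community 2 is the
# paraspeckle-like AU-rich group that also carries planted motif sites.
# Compositions are far apart so 6-mer profiles separate cleanly at
# transcript-scale sampling noise (strong planted structure).
COMMUNITY_COMPOSITION = {
    1: (0.10, 0.40, 0.40, 0.10),
    2: (0.40, 0.10, 0.10, 0.40),
    3: (0.45, 0.10, 0.35, 0.10),
    4: (0.10, 0.35, 0.10, 0.45),
}

# generator-defined RBP motifs (consensus-peaked PWMs)
MOTIF_CONSENSUS = {
    "AUrich_RBP": "AUUUAUU",
    "PS_RBP": "UGUAAUA",
    "GC_RBP": "GCCGGCC",
}
PLANTED_MOTIFS = ("AUrich_RBP", "PS_RBP")  # planted in community-2 5' regions


def consensus_pwm(consensus: str, peak: float = 0.85) -> np.ndarray:
    """A (w, 4) probability matrix peaked on a consensus over ACGU."""
    alph = "ACGU"
    mat = np.full((len(consensus), 4), (1.0 - peak) / 3.0)
    for i, c in enumerate(consensus.upper().replace("T", "U")):
        mat[i, alph.index(c)] = peak
    return mat


@dataclass
class SimulationParams:
    """Study-condition knobs for the generator (defaults = study scale)."""

    n_genes: int = 500
    cell_lines: tuple[str, ...] = DEFAULT_CELL_LINES
    replicates: int = 2  # per condition
    mean_depth: int = 2_000_000  # reads per library before the up-to-2x spread
    nb_dispersion: float = 0.125
    fraction_semi_extractable: float = 0.05
    effect_size_log2fc: float = 2.0
    fraction_low: float = 0.1
    fraction_introns_retained: float = 0.25
    retention_level_range: tuple[float, float] = (0.3, 1.0)
    n_exons_range: tuple[int, int] = (2, 6)
    exon_len_range: tuple[int, int] = (200, 800)
    intron_len_range: tuple[int, int] = (200, 2000)
    intergenic_len_range: tuple[int, int] = (600, 3000)
    n_intergenic_far: int = 8
    n_intergenic_near: int = 8
    repeat_fraction_se: float = 0.4
    repeat_fraction_other: float = 0.1
    rna_end_coverage_se: float = 0.15
    rna_end_coverage_ex: float = 0.45
    n_communities: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fraction_semi_extractable",
            "fraction_low",
            "fraction_introns_retained",
            "repeat_fraction_se",
            "repeat_fraction_other",
            "rna_end_coverage_se",
            "rna_end_coverage_ex",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.nb_dispersion > 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.n_genes < 2:
            raise ValueError("need >= 2 genes")
        self.cell_lines = tuple(self.cell_lines)


@dataclass
class SimulationTruth:
    """Ground truth planted by the generator."""

    is_semi_extractable: dict[str, bool]  # transcript id -> SE flag
    planted_log2fc: dict[str, float]
    category_per_cell_line: dict[str, dict[str, str]]
    intron_retention: dict[tuple[str, int], float]  # (gene, 1-based idx) -> level
    community: dict[str, int | None]  # transcript id -> planted community
    repeat_fraction_targets: dict[str, float]  # "se"/"other" -> fraction
    expected_representative: list[str] = field(default_factory=list)
    expected_intron_retaining: list[str] = field(default_factory=list)
    expected_intergenic: list[str] = field(default_factory=list)

    def expected_reference_ids(self) -> list[str]:
        return (
            self.expected_representative
            + self.expected_intron_retaining
            + self.expected_intergenic
        )

    def expected_se_ids(self) -> list[str]:
        """Planted SE set after representative/intron-retaining dedup."""
        ir_genes = {t.rsplit(".", 1)[0] for t in self.expected_intron_retaining}
        out = []
        for tid, flag in self.is_semi_extractable.items():
            if not flag:
                continue
            if tid.endswith(".rep") and tid.rsplit(".", 1)[0] in ir_genes:
                continue
            out.append(tid)
        return out


@dataclass
class SyntheticDataset:
    params: SimulationParams
    truth: SimulationTruth
    annotation: list[TranscriptModel]  # annotated isoforms (GTF input)
    assembled: list[TranscriptModel]  # assembled transcripts (GTF input)
    reference: list[TranscriptModel]  # planted reference (ground truth)
    tracks: dict[str, TrackAnnotation]
    counts: ExpressionTable
    exon_fpkm: ExpressionTable
    intron_fpkm: ExpressionTable
    sequences: dict[str, str]
    localization: pd.DataFrame
    hubs: pd.DataFrame
    expressed_genes: list[str]
    motifs: dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(
    params: SimulationParams, rng: np.random.Generator | None = None
) -> tuple[list[TranscriptModel], list[TranscriptModel], dict[str, TrackAnnotation], SimulationTruth]:
    """Gene models, assembled transcripts, interval tracks and ground truth.

    Returns ``(annotation_isoforms, assembled, tracks, truth)``; the
    reference implied by the planted retention levels is recorded in the
    truth (id scheme: ``<gene>.rep`` / ``<gene>.ir``; intergenic keep their
    assembled ``STRG.<n>.1`` ids).
    """
    rng = rng or np.random.default_rng(params.rng_seed)
    n = params.n_genes
    n_se = int(round(n * params.fraction_semi_extractable))
    n_low = int(round(n * params.fraction_low))
    flags = ["se"] * n_se + ["low"] * n_low + ["bulk"] * (n - n_se - n_low)
    if len(flags) != n:
        raise ValueError("fraction_semi_extractable + fraction_low exceed 1")
    rng.shuffle(flags)

    truth = SimulationTruth(
        is_semi_extractable={},
        planted_log2fc={},
        category_per_cell_line={},
        intron_retention={},
        community={},
        repeat_fraction_targets={
            "se": params.repeat_fraction_se,
            "other": params.repeat_fraction_other,
        },
    )

    annotation: list[TranscriptModel] = []
    gene_exons: dict[str, list[GenomicInterval]] = {}
    gene_flag: dict[str, str] = {}
    pos = 10_000
    se_counter = 0
    gap_slots: list[tuple[int, int]] = []  # usable gaps for intergenic placement
    for g in range(n):
        gid = f"G{g:04d}"
        flag = flags[g]
        gene_flag[gid] = flag
        strand = "+" if rng.random() < 0.5 else "-"
        # SE transcripts are markedly longer than extractable ones (a
        # reported hallmark of the class): more and longer exons
        lo_e, hi_e = params.n_exons_range
        len_scale = 2 if flag == "se" else 1
        n_ex = int(rng.integers(lo_e + (2 if flag == "se" else 0), hi_e + 1 + (2 if flag == "se" else 0)))
        exons: list[GenomicInterval] = []
        cur = pos
        for e in range(n_ex):
            elen = len_scale * int(rng.integers(*params.exon_len_range))
            exons.append(GenomicInterval(CHROM, cur, cur + elen, strand))
            cur += elen
            if e < n_ex - 1:
                cur += int(rng.integers(*params.intron_len_range))
        gene_exons[gid] = exons
        # isoform 1 spans all exons; isoform 2 (when present) drops one
        # internal exon so collapapsing is exercised
        annotation.append(
            TranscriptModel(id=f"{gid}.t1", gene_id=gid, exons=list(exons), kind="representative")
        )
        if n_ex >= 3 and rng.random() < 0.5:
            drop = int(rng.integers(1, n_ex - 1))
            iso2 = [e for i, e in enumerate(exons) if i != drop]
            annotation.append(
                TranscriptModel(id=f"{gid}.t2", gene_id=gid, exons=iso2, kind="representative")
            )
        gap = int(rng.integers(12_000, 30_000))
        gap_slots.append((cur, cur + gap))
        pos = cur + gap

    chrom_len = pos + 10_000

    # ground-truth categories and effects
    se_gene_ids = [g for g, f in gene_flag.items() if f == "se"]
    for gid, flag in gene_flag.items():
        if flag == "se":
            cat = "Up"
            lfc = params.effect_size_log2fc
        elif flag == "low":
            cat, lfc = "Low", 0.0
        else:
            cat, lfc = "NS", 0.0
        community = None
        if flag == "se":
            community = 1 + se_counter % params.n_communities
            se_counter += 1
        rep_id = f"{gid}.rep"
        truth.expected_representative.append(rep_id)
        for tid in (rep_id, f"{gid}.ir"):
            truth.is_semi_extractable[tid] = flag == "se"
            truth.planted_log2fc[tid] = lfc if flag == "se" else 0.0
            truth.category_per_cell_line[tid] = {c: cat for c in params.cell_lines}
            truth.community[tid] = community

    # planted intron retention (only in expressed genes so threshold
    # crossings are unambiguous); background retention is a low level well
    # under the RS cutoff
    for gid, exons in gene_exons.items():
        rep = collapse_exons(gid, exons)
        n_introns = len(rep.introns())
        retained_any = False
        for i in range(1, n_introns + 1):
            if gene_flag[gid] != "low" and rng.random() < params.fraction_introns_retained:
                level = float(rng.uniform(*params.retention_level_range))
                retained_any = True
            else:
                level = float(rng.uniform(0.0, 0.02))
            truth.intron_retention[(gid, i)] = level
        if retained_any and gene_flag[gid] != "low":
            truth.expected_intron_retaining.append(f"{gid}.ir")
        else:
            # no sibling model: forget the provisional .ir truth entries
            for d in (
                truth.is_semi_extractable,
                truth.planted_log2fc,
                truth.category_per_cell_line,
                truth.community,
            ):
                d.pop(f"{gid}.ir", None)

    # intergenic transcripts: far (>= 5000 nt clearance, kept) and near
    # (< 5000 nt, filtered out by the pipeline)
    assembled: list[TranscriptModel] = []
    far_slots = [s for s in gap_slots if s[1] - s[0] >= 14_000]
    n_wanted = params.n_intergenic_far + params.n_intergenic_near
    if len(far_slots) < n_wanted:
        raise ValueError(
            "infeasible intergenic packing on the synthetic chromosome; "
            "increase n_genes (more gaps) or reduce the intergenic counts"
        )
    picks = rng.choice(len(far_slots), size=n_wanted, replace=False)
    for j, slot_idx in enumerate(picks):
        lo, hi = far_slots[int(slot_idx)]
        tid_root = f"STRG.{j + 1}"
        tid = f"{tid_root}.1"
        strand = "+" if rng.random() < 0.5 else "-"
        far = j < params.n_intergenic_far
        max_len = (hi - lo) - 2 * 5001 if far else 4_000
        length = int(min(max_len, rng.integers(*params.intergenic_len_range)))
        length = max(length, 300)
        if far:
            start = lo + 5001
        else:
            start = lo + int(rng.integers(500, 4_000))  # < 5000 nt from gene end
        model = TranscriptModel(
            id=tid,
            gene_id=tid_root,
            exons=[GenomicInterval(CHROM, start, start + length, strand)],
            kind="intergenic",
        )
        assembled.append(model)
        if far:
            truth.expected_intergenic.append(tid)
            truth.is_semi_extractable[tid] = False
            truth.planted_log2fc[tid] = 0.0
            truth.category_per_cell_line[tid] = {c: "NS" for c in params.cell_lines}
            truth.community[tid] = None

    tracks = _simulate_tracks(params, rng, gene_exons, gene_flag, assembled, truth, chrom_len)
    return annotation, assembled, tracks, truth


def _simulate_tracks(
    params: SimulationParams,
    rng: np.random.Generator,
    gene_exons: Mapping[str, list[GenomicInterval]],
    gene_flag: Mapping[str, str],
    assembled: Sequence[TranscriptModel],
    truth: SimulationTruth,
    chrom_len: int,
) -> dict[str, TrackAnnotation]:
    repeats: list[tuple[GenomicInterval, str]] = []
    ends: list[tuple[GenomicInterval, str]] = []
    states: list[tuple[GenomicInterval, str]] = []

    def cover(exons: Sequence[GenomicInterval], fraction: float, label: str, out: list) -> None:
        """Cover ~fraction of each exon's bases with one interval."""
        for e in exons:
            n_cov = int(round(len(e) * fraction))
            if n_cov >= 1:
                start = e.start + int(rng.integers(0, len(e) - n_cov + 1))
                out.append((GenomicInterval(e.chrom, start, start + n_cov, "."), label))

    repressed = ("Quies", "ReprD", "Low", "Elon")
    active = ("Elon", "Tss", "Low", "Quies", "Enh")
    repeat_classes = ("LINE", "SINE", "LTR", "DNA")
    for gid, exons in gene_exons.items():
        flag = gene_flag[gid]
        se = flag == "se"
        rep_frac = params.repeat_fraction_se if se else params.repeat_fraction_other
        jitter = float(rng.uniform(-0.02, 0.02))
        cover(exons, min(1.0, max(0.0, rep_frac + jitter)), str(rng.choice(repeat_classes)), repeats)
        end_frac = params.rna_end_coverage_se if se else params.rna_end_coverage_ex
        cover(exons, min(1.0, max(0.0, end_frac + float(rng.uniform(-0.05, 0.05)))), "rna_end", ends)
        # tile the gene span with chromatin-state segments
        span_lo, span_hi = exons[0].start, exons[-1].end
        pool = repressed if se else active
        weights = (0.45, 0.2, 0.2, 0.15) if se else (0.4, 0.2, 0.2, 0.1, 0.1)
        cur = span_lo
        while cur < span_hi:
            seg = int(rng.integers(400, 2_000))
            lab = str(rng.choice(pool, p=np.array(weights) / sum(weights)))
            states.append((GenomicInterval(CHROM, cur, min(cur + seg, span_hi), "."), lab))
            cur += seg
    for t in assembled:
        cover(t.exons, params.repeat_fraction_other, "SINE", repeats)
        cover(t.exons, 0.3, "rna_end", ends)
        states.append((t.span, "Low"))
    return {
        "repeats": TrackAnnotation("repeats", repeats),
        "chromatin_states": TrackAnnotation("chromatin_states", states),
        "rna_ends": TrackAnnotation("rna_ends", ends),
    }


# ---------------------------------------------------------------------------
# reference implied by the planted truth


def planted_reference(
    annotation: Sequence[TranscriptModel],
    assembled: Sequence[TranscriptModel],
    truth: SimulationTruth,
) -> list[TranscriptModel]:
    """The reference transcriptome implied by the planted ground truth."""
    by_gene: dict[str, list[GenomicInterval]] = {}
    for t in annotation:
        by_gene.setdefault(t.gene_id, []).extend(t.exons)
    reps = {g: collapse_exons(g, exs) for g, exs in by_gene.items()}
    reference: list[TranscriptModel] = [reps[g] for g in sorted(reps)]
    for ir_id in truth.expected_intron_retaining:
        gid = ir_id.rsplit(".", 1)[0]
        rep = reps[gid]
        introns = rep.introns()
        pieces = list(rep.exons)
        for i, iv in enumerate(introns, start=1):
            if truth.intron_retention.get((gid, i), 0.0) > 0.1:
                pieces.append(iv)
        reference.append(
            TranscriptModel(id=ir_id, gene_id=gid, exons=merge_intervals(pieces), kind="intron_retaining")
        )
    far_ids = set(truth.expected_intergenic)
    reference.extend(t for t in assembled if t.id in far_ids)
    return reference


# ---------------------------------------------------------------------------
# counts and FPKM


def simulate_counts(
    reference: Sequence[TranscriptModel],
    truth: SimulationTruth,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionTable, ExpressionTable, ExpressionTable]:
    """NB counts plus exon/intron FPKM tables consistent with them.

    Counts follow NB(mean = library size x relative expression, dispersion
    = ``nb_dispersion``); improved-condition means of SE transcripts are
    multiplied by 2^planted_log2fc. Exon and intron FPKM (features
    ``<gene>:exon<i>`` / ``<gene>:intron<i>``) derive from the same
    expression state, intron FPKM = retention level x flanking expression.
    """
    rng = rng or np.random.default_rng(params.rng_seed + 1)
    ids = [t.id for t in reference]
    lens = np.array([t.length for t in reference], dtype=float)
    n_t = len(ids)

    # relative expression (per cell line it is identical; semi-extractability
    # is the only condition effect). Low transcripts target FPKM ~0.05-0.2.
    rel = np.zeros(n_t)
    for i, t in enumerate(reference):
        cat = truth.category_per_cell_line.get(t.id, {}).get(params.cell_lines[0], "NS")
        if cat == "Low":
            target_fpkm = float(rng.uniform(0.05, 0.2))
            rel[i] = target_fpkm * (lens[i] / 1e3) / 1e6
        else:
            rel[i] = float(rng.lognormal(0.0, 1.0)) * (lens[i] / 1e3)
        if t.kind == "intron_retaining":
            rel[i] *= 0.5
    rel = rel / rel.sum()

    effect = np.array([2.0 ** truth.planted_log2fc.get(t, 0.0) for t in ids])
    columns: dict[str, np.ndarray] = {}
    fpkm_by_sample: dict[str, np.ndarray] = {}
    for cell in params.cell_lines:
        for cond in ("conventional", "improved"):
            w = rel * (effect if cond == "improved" else 1.0)
            frac = w / w.sum()
            for r in range(1, params.replicates + 1):
                lib = params.mean_depth * float(rng.uniform(1.0, 2.0))
                mu = lib * frac
                size = 1.0 / params.nb_dispersion
                counts = np.where(
                    mu > 0, rng.negative_binomial(size, size / (size + mu)), 0
                )
                name = f"{cell}_{cond}_rep{r}"
                columns[name] = counts.astype(np.int64)
                fpkm_by_sample[name] = 1e6 * frac / (lens / 1e3)

    counts_df = pd.DataFrame(columns, index=ids)
    counts_table = ExpressionTable(counts_df, kind="counts")

    # exon / intron FPKM for representative transcripts, improved samples
    exon_rows: dict[str, dict[str, float]] = {}
    intron_rows: dict[str, dict[str, float]] = {}
    improved = [c for c in counts_df.columns if "_improved_" in c]
    rep_models = {t.gene_id: t for t in reference if t.kind == "representative"}
    idx_of = {t: i for i, t in enumerate(ids)}
    for gid, rep in rep_models.items():
        base_idx = idx_of[rep.id]
        n_introns = len(rep.introns())
        for s in improved:
            e_fpkm = fpkm_by_sample[s][base_idx]
            for i in range(1, len(rep.exons) + 1):
                exon_rows.setdefault(f"{gid}:exon{i}", {})[s] = e_fpkm * float(
                    rng.lognormal(0.0, 0.03)
                )
            for i in range(1, n_introns + 1):
                level = truth.intron_retention.get((gid, i), 0.0)
                intron_rows.setdefault(f"{gid}:intron{i}", {})[s] = (
                    level * e_fpkm * float(rng.lognormal(0.0, 0.03))
                )
    exon_fpkm = ExpressionTable(pd.DataFrame(exon_rows).T[improved].fillna(0.0), kind="fpkm")
    if intron_rows:
        intron_df = pd.DataFrame(intron_rows).T[improved].fillna(0.0)
    else:
        intron_df = pd.DataFrame(columns=improved)
    intron_fpkm = ExpressionTable(intron_df, kind="fpkm") if len(intron_df) else ExpressionTable(
        pd.DataFrame(np.zeros((0, len(improved))), columns=improved), kind="fpkm"
    )
    return counts_table, exon_fpkm, intron_fpkm


# ---------------------------------------------------------------------------
# sequences


def plant_sites(
    sequence: list[str], consensus: str, n_sites: int, region: tuple[int, int], rng: np.random.Generator
) -> None:
    """Overwrite ``n_sites`` non-overlapping stretches inside ``region`` with
    the consensus word (in place)."""
    w = len(consensus)
    lo, hi = region
    hi = min(hi, len(sequence)) - w
    if hi <= lo:
        return
    taken: list[int] = []
    tries = 0
    while len(taken) < n_sites and tries < 200:
        pos = int(rng.integers(lo, hi + 1))
        if all(abs(pos - p) >= w for p in taken):
            sequence[pos : pos + w] = list(consensus)
            taken.append(pos)
        tries += 1


def simulate_sequences(
    reference: Sequence[TranscriptModel],
    truth: SimulationTruth,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Transcript sequences encoding the planted community structure.

    Community members draw bases from their community's composition;
    community 2 additionally receives AU-rich and paraspeckle-like motif
    sites in its first 300 nt. Non-SE transcripts draw from a mildly
    GC-leaning background.
    """
    rng = rng or np.random.default_rng(params.rng_seed + 2)
    alph = np.array(list("ACGU"))
    seqs: dict[str, str] = {}
    for t in reference:
        com = truth.community.get(t.id)
        if com is not None:
            probs = np.array(COMMUNITY_COMPOSITION[1 + (com - 1) % len(COMMUNITY_COMPOSITION)])
        else:
            base = np.array([0.22, 0.28, 0.28, 0.22])
            probs = rng.dirichlet(base * 60.0)
        letters = list(rng.choice(alph, size=t.length, p=probs))
        if com == 2:
            for name in PLANTED_MOTIFS:
                plant_sites(letters, MOTIF_CONSENSUS[name], 8, (0, 300), rng)
        seqs[t.id] = "".join(letters)
    return seqs


# ---------------------------------------------------------------------------
# localization, hubs, full dataset


def _simulate_localization(
    reference: Sequence[TranscriptModel],
    truth: SimulationTruth,
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = {}
    for t in reference:
        se = truth.is_semi_extractable.get(t.id, False)
        base = float(rng.lognormal(3.0, 0.5))
        row = {}
        for comp in COMPARTMENTS:
            if comp in _NUCLEAR:
                shift = 1.0 if se else 0.0
            else:
                shift = -0.5 if se else 0.2
            row[f"{comp}_labeled"] = base * 2.0 ** (shift + float(rng.normal(0, 0.3)))
            row[f"{comp}_unlabeled"] = base * 2.0 ** float(rng.normal(0, 0.3))
        rows[t.id] = row
    return pd.DataFrame(rows).T


def _simulate_hubs(
    truth: SimulationTruth,
    params: SimulationParams,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[str]]:
    """Hub gene table (gene_id, n_partners) enriched in SE genes, plus the
    expressed-gene background."""
    gene_cat = {
        t.rsplit(".", 1)[0]: cats[params.cell_lines[0]]
        for t, cats in truth.category_per_cell_line.items()
        if t.endswith(".rep")
    }
    expressed = sorted(g for g, c in gene_cat.items() if c != "Low")
    se_genes = [g for g, c in gene_cat.items() if c == "Up"]
    other = [g for g in expressed if g not in se_genes]
    n_hub_se = min(len(se_genes), 25)
    n_hub_other = min(len(other), 25)
    hubs = (
        list(rng.choice(se_genes, n_hub_se, replace=False)) if n_hub_se else []
    ) + (list(rng.choice(other, n_hub_other, replace=False)) if n_hub_other else [])
    n_partners = rng.integers(5, 120, size=len(hubs))
    return (
        pd.DataFrame({"gene_id": hubs, "n_partners": n_partners}),
        expressed,
    )


def simulate_dataset(params: SimulationParams | None = None) -> SyntheticDataset:
    """Generate the complete, mutually consistent synthetic dataset."""
    params = params or SimulationParams()
    rng = np.random.default_rng(params.rng_seed)
    annotation, assembled, tracks, truth = simulate_annotation(params, rng)
    reference = planted_reference(annotation, assembled, truth)
    counts, exon_fpkm, intron_fpkm = simulate_counts(reference, truth, params, rng)
    sequences = simulate_sequences(reference, truth, params, rng)
    localization = _simulate_localization(reference, truth, rng)
    hubs, expressed = _simulate_hubs(truth, params, rng)
    motifs = {name: consensus_pwm(cons) for name, cons in MOTIF_CONSENSUS.items()}
    return SyntheticDataset(
        params=params,
        truth=truth,
        annotation=annotation,
        assembled=assembled,
        reference=reference,
        tracks=tracks,
        counts=counts,
        exon_fpkm=exon_fpkm,
        intron_fpkm=intron_fpkm,
        sequences=sequences,
        localization=localization,
        hubs=hubs,
        expressed_genes=expressed,
        motifs=motifs,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write every input file the pipeline stages consume, plus truth tables."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_gtf(ds.annotation, out / "annotation.gtf")
    io.write_gtf(ds.assembled, out / "assembled.gtf")
    io.write_table(ds.counts.data, out / "counts.tsv")
    io.write_table(ds.exon_fpkm.data, out / "exon_fpkm.tsv")
    io.write_table(ds.intron_fpkm.data, out / "intron_fpkm.tsv")
    for name, track in ds.tracks.items():
        io.write_bed(track.records, out / f"{name}.bed")
    io.write_fasta(ds.sequences, out / "sequences.fasta")
    io.write_table(ds.localization, out / "localization.tsv", index_label="transcript_id")
    ds.hubs.to_csv(out / "hubs.tsv", sep="\t", index=False, lineterminator="\n")
    pd.DataFrame({"gene_id": ds.expressed_genes}).to_csv(
        out / "expressed_genes.tsv", sep="\t", index=False, lineterminator="\n"
    )
    io.write_meme_motifs(ds.motifs, out / "motifs.meme")
    rows = []
    for tid, se in sorted(ds.truth.is_semi_extractable.items()):
        rows.append(
            {
                "transcript_id": tid,
                "is_semi_extractable": int(se),
                "planted_log2fc": ds.truth.planted_log2fc[tid],
                "community": ds.truth.community.get(tid) or "N",
            }
        )
    pd.DataFrame(rows).to_csv(out / "truth_transcripts.tsv", sep="\t", index=False, lineterminator="\n")
    pd.DataFrame(
        [
            {"gene_id": g, "intron_index": i, "retention_level": lvl}
            for (g, i), lvl in sorted(ds.truth.intron_retention.items())
        ]
    ).to_csv(out / "truth_introns.tsv", sep="\t", index=False, lineterminator="\n")
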