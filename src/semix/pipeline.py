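"""End-to-end orchestration of the discovery and characterization stages.

Each stage reads plain-text inputs from a run directory and writes its
outputs back there, so stages can be run individually (the CLI subcommands
map 1:1 onto the ``stage_*`` functions) or end to end with :func:`run_all`.
Every run emits the fully resolved configuration and one log line per
stage with input/output record counts.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import characterize as chz
from . import io, kmer, motif as motif_mod, semiextract as se_mod
from . import transcriptome as tx
from .config import RunConfig
from .models import ExpressionTable, TranscriptModel
from .simulate import SimulationParams, simulate_dataset, write_dataset

log = logging.getLogger("semix")


def stage_simulate(params: SimulationParams, rundir: str | Path) -> Path:
    """Generate the synthetic dataset into ``<rundir>/input``."""
    indir = Path(rundir) / "input"
    ds = simulate_dataset(params)
    write_dataset(ds, indir)
    log.info("simulate: %d genes -> %s", params.n_genes, indir)
    return indir


def stage_build_ref(rundir: str | Path, config: RunConfig) -> list[TranscriptModel]:
    """Build the reference transcriptome from annotation + FPKM evidence."""
    rundir = Path(rundir)
    indir = rundir / "input"
    annotation = io.read_gtf(indir / "annotation.gtf")
    assembled = io.read_gtf(indir / "assembled.gtf")
    exon_fpkm = io.read_fpkm(indir / "exon_fpkm.tsv")
    intron_fpkm = io.read_fpkm(indir / "intron_fpkm.tsv")

    by_gene: dict[str, list] = {}
    for t in annotation:
        by_gene.setdefault(t.gene_id, []).extend(t.exons)
    representatives = [tx.collapse_exons(g, exs) for g, exs in by_gene.items()]
    introns = tx.intron_records_from_tables(representatives, exon_fpkm, intron_fpkm)
    reference = tx.build_reference(annotation, introns, assembled, config)
    io.write_gtf(reference, rundir / "reference.gtf")
    return reference


def stage_call_se(
    rundir: str | Path, config: RunConfig
) -> tuple[pd.DataFrame, pd.Series, tuple[list[str], list[str], list[str]]]:
    """Differential testing, categorization, labeling and SE/EX/BG sets."""
    rundir = Path(rundir)
    reference = io.read_gtf(rundir / "reference.gtf")
    counts = io.read_counts(rundir / "input" / "counts.tsv")
    ref_ids = [t.id for t in reference]
    missing = [t for t in ref_ids if t not in set(counts.feature_ids)]
    if missing:
        raise ValueError(f"counts table lacks reference transcripts {missing[:5]}")
    counts = ExpressionTable(counts.data.loc[ref_ids], kind="counts")
    lengths = {t.id: t.length for t in reference}
    diff = se_mod.run_differential(counts, lengths, config)
    labels = se_mod.label_table(diff, config)
    sets = se_mod.build_sets(labels.to_dict(), reference)
    diff.to_csv(rundir / "differential.tsv", sep="\t", index=False, lineterminator="\n")
    labels.rename("label").to_frame().to_csv(
        rundir / "labels.tsv", sep="\t", index_label="transcript_id", lineterminator="\n"
    )
    for name, ids in zip(("se", "ex", "bg"), sets):
        (rundir / f"{name}_ids.txt").write_text("".join(i + "\n" for i in ids))
    return diff, labels, sets


def _read_sets(rundir: Path) -> dict[str, list[str]]:
    return {
        name: (rundir / f"{name}_ids.txt").read_text().split()
        for name in ("se", "ex", "bg")
    }


def stage_characterize(rundir: str | Path, config: RunConfig) -> dict[str, object]:
    """Chromatin states, repeat density, contact coverage, localization,
    hub overlap and end-region extraction for the called sets."""
    rundir = Path(rundir)
    indir = rundir / "input"
    reference = {t.id: t for t in io.read_gtf(rundir / "reference.gtf")}
    sets = _read_sets(rundir)
    states = io.read_track(indir / "chromatin_states.bed", "chromatin_states")
    repeats = io.read_track(indir / "repeats.bed", "repeats")
    rna_ends = io.read_track(indir / "rna_ends.bed", "rna_ends")

    spans = {k: [reference[i].span for i in ids] for k, ids in sets.items()}
    enrichment = chz.chromatin_enrichment(spans["se"], spans["ex"], spans["bg"], states)
    enrichment.to_csv(rundir / "chromatin_enrichment.tsv", sep="\t", index=False, lineterminator="\n")

    dens_rows = []
    for name in ("se", "ex"):
        for tid in sets[name]:
            t = reference[tid]
            dens_rows.append(
                {
                    "transcript_id": tid,
                    "set": name.upper(),
                    "repeat_density": chz.repeat_density(t, repeats),
                    "rna_end_coverage": chz.rna_end_coverage(t, rna_ends),
                    "length": t.length,
                }
            )
    density = pd.DataFrame(dens_rows)
    density.to_csv(rundir / "set_densities.tsv", sep="\t", index=False, lineterminator="\n")

    loc = pd.read_csv(indir / "localization.tsv", sep="\t", index_col=0)
    loc_fc = chz.localization_table(loc)
    loc_fc.to_csv(rundir / "localization_fc.tsv", sep="\t", index_label="transcript_id", lineterminator="\n")

    seqs = io.read_fasta(indir / "sequences.fasta")
    ends: dict[str, str] = {}
    for tid in sets["se"]:
        pair = chz.extract_end_regions(
            seqs[tid], config.end_region_nt, config.min_transcript_nt_for_mfe
        )
        if pair is not None:
            ends[f"{tid}|5p"], ends[f"{tid}|3p"] = pair
    io.write_fasta(ends, rundir / "end_regions.fasta")

    hubs = pd.read_csv(indir / "hubs.tsv", sep="\t")
    hubs = hubs[hubs["n_partners"] > config.hub_min_partners]
    expressed = pd.read_csv(indir / "expressed_genes.tsv", sep="\t")["gene_id"].tolist()
    se_genes = sorted({reference[i].gene_id for i in sets["se"]})
    n_overlap, pct, hub_p = chz.hub_overlap(se_genes, hubs["gene_id"], expressed)

    comp_rows = []

    def compare(metric: str, se_vals, ex_vals) -> None:
        stat, p, stars = chz.compare_sets(se_vals, ex_vals)
        comp_rows.append(
            {
                "metric": metric,
                "mean_se": float(np.mean(se_vals)),
                "mean_ex": float(np.mean(ex_vals)),
                "statistic": stat,
                "pvalue": p,
                "stars": stars,
            }
        )

    se_mask = density["set"] == "SE"
    compare("repeat_density", density.loc[se_mask, "repeat_density"], density.loc[~se_mask, "repeat_density"])
    compare("rna_end_coverage", density.loc[se_mask, "rna_end_coverage"], density.loc[~se_mask, "rna_end_coverage"])
    compare("length", density.loc[se_mask, "length"], density.loc[~se_mask, "length"])

    def gc(s: str) -> float:
        return (s.count("G") + s.count("C")) / len(s)

    compare("gc_content", [gc(seqs[i]) for i in sets["se"]], [gc(seqs[i]) for i in sets["ex"]])
    for comp in loc_fc.columns:
        compare(
            f"localization_{comp}",
            loc_fc.loc[[i for i in sets["se"] if i in loc_fc.index], comp],
            loc_fc.loc[[i for i in sets["ex"] if i in loc_fc.index], comp],
        )
    comparisons = pd.DataFrame(comp_rows)
    comparisons.to_csv(rundir / "set_comparisons.tsv", sep="\t", index=False, lineterminator="\n")

    hub_df = pd.DataFrame(
        [{"n_overlap": n_overlap, "pct_of_hubs": pct, "pvalue": hub_p, "n_hubs": len(set(hubs["gene_id"]) & set(expressed))}]
    )
    hub_df.to_csv(rundir / "hub_overlap.tsv", sep="\t", index=False, lineterminator="\n")
    return {
        "enrichment": enrichment,
        "density": density,
        "comparisons": comparisons,
        "hub": (n_overlap, pct, hub_p),
    }


def stage_motif(rundir: str | Path, config: RunConfig) -> pd.DataFrame:
    """RBP binding preference (five regions + avg) of SE over EX."""
    rundir = Path(rundir)
    indir = rundir / "input"
    sets = _read_sets(rundir)
    seqs = io.read_fasta(indir / "sequences.fasta")
    raw = io.read_meme_motifs(indir / "motifs.meme")
    motifs = []
    for name, mat in raw.items():
        m = motif_mod.prepare_motif(mat, name, config.motif_pseudocount)
        motif_mod.threshold_from_pvalue(m, config.motif_pvalue)
        motifs.append(m)
    table = motif_mod.preference_table(
        motifs,
        {i: seqs[i] for i in sets["se"]},
        {i: seqs[i] for i in sets["ex"]},
    )
    table.to_csv(rundir / "motif_preference.tsv", sep="\t", index=False, lineterminator="\n")
    log.info("motif: %d RBPs x (%d SE, %d EX)", len(motifs), len(sets["se"]), len(sets["ex"]))
    return table


def stage_cluster(rundir: str | Path, config: RunConfig) -> tuple[dict[str, int | None], pd.DataFrame]:
    """k-mer profiles, similarity graph, Louvain communities, per-community
    RBP preference."""
    rundir = Path(rundir)
    indir = rundir / "input"
    sets = _read_sets(rundir)
    seqs = io.read_fasta(indir / "sequences.fasta")
    counts = {i: kmer.count_kmers(seqs[i], config.kmer_k) for i in sets["se"]}
    lengths = {i: len(seqs[i]) for i in sets["se"]}
    normalized = kmer.normalize_profiles(counts, lengths)
    graph = kmer.similarity_graph(normalized, config.kmer_similarity_threshold)
    assignment = kmer.louvain_communities(graph, config.rng_seed)
    kmer.assignment_table(assignment).to_csv(
        rundir / "kmer_communities.tsv", sep="\t", index=False, lineterminator="\n"
    )
    edges = pd.DataFrame(
        [(u, v, d["weight"]) for u, v, d in graph.edges(data=True)],
        columns=["source", "target", "weight"],
    )
    edges.to_csv(rundir / "kmer_edges.tsv", sep="\t", index=False, lineterminator="\n")

    raw = io.read_meme_motifs(indir / "motifs.meme")
    motifs = []
    for name, mat in raw.items():
        m = motif_mod.prepare_motif(mat, name, config.motif_pseudocount)
        motif_mod.threshold_from_pvalue(m, config.motif_pvalue)
        motifs.append(m)
    if any(c is not None for c in assignment.values()):
        pref = kmer.community_rbp_preference(
            assignment,
            motifs,
            {i: seqs[i] for i in sets["se"]},
            {i: seqs[i] for i in sets["ex"]},
        )
    else:
        log.warning("cluster: every SE transcript is in the null community")
        pref = pd.DataFrame(columns=[m.rbp_name for m in motifs])
    pref.to_csv(rundir / "community_rbp_preference.tsv", sep="\t", index_label="community", lineterminator="\n")
    return assignment, pref


def run_all(
    config: RunConfig | None = None,
    rundir: str | Path = "semix_run",
    params: SimulationParams | None = None,
) -> dict[str, object]:
    """Simulate (unless ``<rundir>/input`` already exists) and run every stage."""
    config = config or RunConfig()
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(rundir / "config.yaml")
    if not (rundir / "input" / "counts.tsv").exists():
        params = params or SimulationParams(
            rng_seed=config.rng_seed, cell_lines=config.cell_line_names
        )
        stage_simulate(params, rundir)
    reference = stage_build_ref(rundir, config)
    diff, labels, sets = stage_call_se(rundir, config)
    character = stage_characterize(rundir, config)
    motif_table = stage_motif(rundir, config)
    assignment, community_pref = stage_cluster(rundir, config)
    return {
        "reference": reference,
        "differential": diff,
        "labels": labels,
        "sets": sets,
        "characterize": character,
        "motif_preference": motif_table,
        "communities": assignment,
        "community_rbp_preference": community_pref,
    }
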