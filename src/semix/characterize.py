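"""Descriptive comparisons of the SE / EX / BG transcript sets.

Covers chromatin-state composition (ChromHMM mnemonics grouped into ten
functional classes), repeat density, RNA-end (RNA-chromatin contact)
coverage, subcellular localization fold changes, hub-RNA overlap
enrichment, and extraction of 5'/3' end regions for external RNA folding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, intersect_length, merge_intervals
from .models import TrackAnnotation, TranscriptModel

log = logging.getLogger("semix")

# ChromHMM mnemonic -> 10-class functional group. "CtrcfO" is accepted as an
# alternate spelling of CtcfO seen in some distributions of the table.
STATE_GROUPS: dict[str, str] = {
    "Tss": "Active Promoter",
    "TssF": "Active Promoter",
    "PromF": "Promoter Flanking",
    "PromP": "Inactive Promoter",
    "Enh": "Candidate Strong Enhancer",
    "EnhF": "Candidate Strong Enhancer",
    "EnhWF": "Candidate Weak Enhancer/DNase",
    "EnhW": "Candidate Weak Enhancer/DNase",
    "DNaseU": "Candidate Weak Enhancer/DNase",
    "DNaseD": "Candidate Weak Enhancer/DNase",
    "CtcfO": "Distal CTCF/Candidate Insulator",
    "CtrcfO": "Distal CTCF/Candidate Insulator",
    "Ctcf": "Distal CTCF/Candidate Insulator",
    "Gen5'": "Transcription Associated",
    "Gen5": "Transcription Associated",
    "Elon": "Transcription Associated",
    "ElonW": "Transcription Associated",
    "Gen3'": "Transcription Associated",
    "Gen3": "Transcription Associated",
    "Pol2": "Transcription Associated",
    "H4K20": "Transcription Associated",
    "Low": "Low Activity Proximal to Active States",
    "ReprD": "Polycomb Repressed",
    "Repr": "Polycomb Repressed",
    "ReprW": "Polycomb Repressed",
    "Quies": "Heterochromatin/Repetitive/Copy Number Variation",
    "Art": "Heterochromatin/Repetitive/Copy Number Variation",
}

STATE_GROUP_NAMES = list(dict.fromkeys(STATE_GROUPS.values()))


def reannotate_states(raw_label: str) -> str:
    """Map a ChromHMM mnemonic (optionally numbered, e.g. ``12_Low``) to its
    functional group; unknown mnemonics map to ``unmapped`` with a warning."""
    label = raw_label.split("_", 1)[1] if "_" in raw_label and raw_label.split("_", 1)[0].isdigit() else raw_label
    group = STATE_GROUPS.get(label)
    if group is None:
        log.warning("reannotate_states: unknown ChromHMM label %r", raw_label)
        return "unmapped"
    return group


@dataclass
class EnrichmentRow:
    state: str
    pct_se: float
    pct_ex: float
    pct_bg: float
    ratio_se_ex: float
    ratio_se_bg: float


def _ratio(num: float, den: float) -> float:
    """Percentage ratio; absent-everywhere states give NaN, not inf."""
    if den > 0:
        return num / den
    return np.nan if num == 0 else np.inf


def _set_state_bases(
    spans: Sequence[GenomicInterval], states: TrackAnnotation
) -> dict[str, int]:
    merged = merge_intervals(spans)
    by_group: dict[str, list[GenomicInterval]] = {}
    for iv, lab in states.records:
        by_group.setdefault(reannotate_states(lab), []).append(iv)
    return {g: intersect_length(merged, ivs) for g, ivs in by_group.items() if g != "unmapped"}


def chromatin_enrichment(
    se_spans: Sequence[GenomicInterval],
    ex_spans: Sequence[GenomicInterval],
    bg_spans: Sequence[GenomicInterval],
    states: TrackAnnotation,
) -> pd.DataFrame:
    """Per-state composition of the three sets and SE/EX, SE/BG ratios.

    For each set, %state = 100 x (bases of the set's merged spans overlapped
    by that state group) / (total state-overlapped bases of the set), so the
    column sums to 100. Rows are sorted by SE/EX descending; ratios are
    computed from unrounded percentages.
    """
    if not states.records:
        raise ValueError("empty chromatin-state track")
    if not (se_spans and ex_spans and bg_spans):
        raise ValueError("SE/EX/BG span sets must be nonempty")
    pct = {}
    for name, spans in (("se", se_spans), ("ex", ex_spans), ("bg", bg_spans)):
        bases = _set_state_bases(spans, states)
        total = sum(bases.values())
        if total == 0:
            raise ValueError(f"{name} spans share no bases with the state track")
        pct[name] = {g: 100.0 * bases.get(g, 0) / total for g in STATE_GROUP_NAMES}
    rows = []
    for g in STATE_GROUP_NAMES:
        p_se, p_ex, p_bg = pct["se"][g], pct["ex"][g], pct["bg"][g]
        rows.append(
            {
                "state": g,
                "pct_se": p_se,
                "pct_ex": p_ex,
                "pct_bg": p_bg,
                "ratio_se_ex": _ratio(p_se, p_ex),
                "ratio_se_bg": _ratio(p_se, p_bg),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        "ratio_se_ex", ascending=False, kind="mergesort", na_position="last"
    )
    return df.reset_index(drop=True)


def _fraction_covered(transcript: TranscriptModel, track: TrackAnnotation) -> float:
    covered = intersect_length(transcript.exons, [iv for iv, _ in track.records])
    return covered / transcript.length


def repeat_density(transcript: TranscriptModel, repeats: TrackAnnotation) -> float:
    """Fraction of exonic bases overlapping any repeat interval, in [0, 1]."""
    return _fraction_covered(transcript, repeats)


def rna_end_coverage(transcript: TranscriptModel, rna_ends: TrackAnnotation) -> float:
    """Fraction of exonic bases covered by RNA-end contact intervals."""
    return _fraction_covered(transcript, rna_ends)


def localization_fc(
    labeled_abundance: float, unlabeled_abundance: float, pseudocount: float = 1.0
) -> float:
    """log2 labeled/unlabeled abundance ratio for one compartment."""
    if labeled_abundance < 0 or unlabeled_abundance < 0:
        raise ValueError("abundances must be >= 0")
    return float(
        np.log2(labeled_abundance + pseudocount) - np.log2(unlabeled_abundance + pseudocount)
    )


def localization_table(
    abundance: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-transcript localization fold change for every compartment.

    ``abundance`` columns follow ``<compartment>_labeled`` /
    ``<compartment>_unlabeled``.
    """
    compartments = sorted(
        {c.rsplit("_", 1)[0] for c in abundance.columns if c.endswith("_labeled")}
    )
    out = {}
    for comp in compartments:
        lab, unlab = f"{comp}_labeled", f"{comp}_unlabeled"
        if unlab not in abundance.columns:
            raise ValueError(f"compartment {comp} lacks an unlabeled column")
        out[comp] = np.log2(abundance[lab] + pseudocount) - np.log2(
            abundance[unlab] + pseudocount
        )
    return pd.DataFrame(out, index=abundance.index)


def hub_overlap(
    se_genes: Iterable[str],
    hub_genes: Iterable[str],
    expressed_background: Iterable[str],
) -> tuple[int, float, float]:
    """Overlap of the SE gene set with hub RNAs within an expressed background.

    Returns ``(n_overlap, pct_of_hubs, pvalue)`` where the p-value is the
    hypergeometric upper tail of drawing >= n_overlap hubs when sampling
    |SE| genes from the background.
    """
    bg = set(expressed_background)
    hubs = set(hub_genes)
    dropped = hubs - bg
    if dropped:
        log.warning("hub_overlap: %d hub genes outside the expressed background dropped", len(dropped))
    hubs &= bg
    se = set(se_genes) & bg
    if not hubs:
        raise ValueError("no hub genes within the expressed background")
    overlap = len(se & hubs)
    pct = 100.0 * overlap / len(hubs)
    pvalue = float(stats.hypergeom.sf(overlap - 1, len(bg), len(hubs), len(se)))
    return overlap, pct, pvalue


def extract_end_regions(
    sequence: str, region_nt: int = 300, min_len: int = 600
) -> tuple[str, str] | None:
    """First and last ``region_nt`` nt of a transcript sequence.

    Transcripts shorter than ``min_len`` are rejected (returns ``None``);
    these regions feed an external RNA-folding tool for MFE comparison.
    """
    bad = set(sequence.upper()) - set("ACGUTN")
    if bad:
        raise ValueError(f"non-nucleotide characters {sorted(bad)}")
    if len(sequence) < min_len:
        return None
    return sequence[:region_nt], sequence[-region_nt:]


def compare_sets(
    values_se: Sequence[float], values_ex: Sequence[float]
) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum comparison with significance stars."""
    a = np.asarray(values_se, dtype=float)
    b = np.asarray(values_ex, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each set needs >= 2 values")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    p = float(res.pvalue)
    stars = "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else "ns"
    return float(res.statistic), p, stars
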