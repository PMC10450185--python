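"""Semi-extractability quantification.

For each cell line, improved-extraction counts are compared with
conventional-extraction counts per transcript using the classic conditional
negative-binomial exact test at a fixed common dispersion (0.125, the
empirical average reported for these libraries). Transcripts are then
categorized per cell line:

* ``Low``  — average FPKM < 0.5;
* ``Up``   — average FPKM >= 0.5, p < 0.05 and log2FC > 0 (semi-extractable
  in that cell line);
* ``Down`` — average FPKM >= 0.5, p < 0.05 and log2FC < 0;
* ``NS``   — everything else.

Cross-cell-line labels (``common`` / ``specific`` / ``switch``) combine the
five per-line categories; SE = {Up common} U {Up specific}, EX = {NS common},
BG = the whole reference. p-values are raw (no multiple-testing correction),
matching the published procedure.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .config import RunConfig
from .models import ExpressionTable, TranscriptModel

log = logging.getLogger("semix")

CATEGORIES = ("Low", "Up", "Down", "NS")
_SWITCH_ORDER = ("Up", "Down", "NS")


# ---------------------------------------------------------------------------
# FPKM


def compute_fpkm(
    counts: ExpressionTable, lengths: Mapping[str, int]
) -> ExpressionTable:
    """FPKM = count / (length_kb x library_size_millions), per sample.

    Library size is the raw column sum of the count matrix.
    """
    missing = [t for t in counts.feature_ids if t not in lengths]
    if missing:
        raise ValueError(f"lengths missing for {missing[:5]}")
    lens = np.array([lengths[t] for t in counts.feature_ids], dtype=float)
    if (lens <= 0).any():
        raise ValueError("non-positive transcript length")
    lib = counts.data.sum(axis=0).to_numpy(dtype=float)
    if (lib == 0).any():
        raise ValueError("zero library size column")
    fpkm = counts.data.to_numpy(dtype=float) / (lens[:, None] / 1e3) / (lib[None, :] / 1e6)
    return ExpressionTable(
        pd.DataFrame(fpkm, index=counts.data.index, columns=counts.data.columns),
        kind="fpkm",
    )


# ---------------------------------------------------------------------------
# Normalization


def tmm_factors(
    counts: pd.DataFrame, logratio_trim: float = 0.3, sum_trim: float = 0.05
) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors (product-normalized).

    The reference sample is the column whose 75th count percentile is
    closest to the mean; factors for degenerate columns fall back to 1.
    """
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("zero library size column")
    f75 = np.quantile(mat / lib, 0.75, axis=0)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.ones(mat.shape[1])
    for i in range(mat.shape[1]):
        obs, refc = mat[:, i], mat[:, ref]
        keep = (obs > 0) & (refc > 0)
        if keep.sum() < 10:
            continue
        o, r = obs[keep], refc[keep]
        m = np.log2((o / lib[i]) / (r / lib[ref]))
        a = 0.5 * np.log2((o / lib[i]) * (r / lib[ref]))
        v = (lib[i] - o) / (lib[i] * o) + (lib[ref] - r) / (lib[ref] * r)
        w = 1.0 / v  # inverse delta-method variance of M
        n = m.size
        lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
        lo_a, hi_a = np.floor(n * sum_trim) + 1, n - np.floor(n * sum_trim)
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not sel.any() or w[sel].sum() == 0:
            continue
        f = 2.0 ** (np.sum(w[sel] * m[sel]) / np.sum(w[sel]))
        if np.isfinite(f) and f > 0:
            factors[i] = f
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def effective_lib_sizes(counts: pd.DataFrame, method: str = "tmm") -> np.ndarray:
    """Raw column sums, optionally scaled by TMM factors."""
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if method == "tmm":
        return lib * tmm_factors(counts)
    if method == "libsize":
        return lib
    raise ValueError(f"unknown normalization {method!r}")


# ---------------------------------------------------------------------------
# Exact test


def _conditional_pvalue(s1: int, s2: int, n1: int, n2: int, dispersion: float) -> float:
    """Two-sided conditional NB exact test p-value.

    Conditions on the total T = s1 + s2 of per-condition sums of library-
    size-adjusted counts; under H0 the conditional law of s2 is a
    beta-negative-binomial with shape parameters r2 = n2/phi and r1 = n1/phi.
    The two-sided p sums the probabilities of all outcomes no more likely
    than the observed one.
    """
    r1, r2 = n1 / dispersion, n2 / dispersion
    total = s1 + s2
    if total == 0:
        return 1.0
    x = np.arange(total + 1, dtype=float)
    logp = (
        gammaln(x + r2)
        - gammaln(x + 1.0)
        + gammaln(total - x + r1)
        - gammaln(total - x + 1.0)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[s2]
    return float(min(1.0, p[p <= p_obs * (1.0 + 1e-10)].sum()))


def nb_exact_test(
    counts_conventional: Sequence[int],
    counts_improved: Sequence[int],
    dispersion: float = 0.125,
    lib_sizes_conventional: Sequence[float] | None = None,
    lib_sizes_improved: Sequence[float] | None = None,
    prior_count: float = 0.125,
) -> tuple[float, float]:
    """Exact test for equal NB means between the two extraction conditions.

    Counts are first adjusted to a common effective library size (the
    geometric mean of the supplied — or unit — effective sizes), summed per
    condition and rounded; the conditional exact test is then applied at the
    given common dispersion. ``log2fc`` (improved over conventional) uses the
    normalized condition means with a ``prior_count`` offset per sample so
    zero counts yield finite fold changes.

    Returns ``(log2fc, pvalue)``; an all-zero transcript gives ``(0.0, 1.0)``.
    """
    conv = np.asarray(counts_conventional, dtype=float)
    impr = np.asarray(counts_improved, dtype=float)
    if conv.ndim != 1 or impr.ndim != 1 or conv.size == 0 or impr.size == 0:
        raise ValueError("need >= 1 sample per condition")
    if (conv < 0).any() or (impr < 0).any():
        raise ValueError("negative counts")
    if not dispersion > 0:
        raise ValueError("dispersion must be > 0")
    libs_c = (
        np.ones_like(conv)
        if lib_sizes_conventional is None
        else np.asarray(lib_sizes_conventional, dtype=float)
    )
    libs_i = (
        np.ones_like(impr)
        if lib_sizes_improved is None
        else np.asarray(lib_sizes_improved, dtype=float)
    )
    all_libs = np.concatenate([libs_c, libs_i])
    if (all_libs <= 0).any():
        raise ValueError("non-positive library size")
    ref = float(np.exp(np.mean(np.log(all_libs))))
    adj_c = conv * (ref / libs_c)
    adj_i = impr * (ref / libs_i)
    mean_c = adj_c.mean()
    mean_i = adj_i.mean()
    log2fc = float(np.log2(mean_i + prior_count) - np.log2(mean_c + prior_count))
    if conv.sum() == 0 and impr.sum() == 0:
        return 0.0, 1.0
    s1 = int(round(adj_c.sum()))
    s2 = int(round(adj_i.sum()))
    pvalue = _conditional_pvalue(s1, s2, conv.size, impr.size, dispersion)
    return log2fc, pvalue


# ---------------------------------------------------------------------------
# Categorization and labeling


def categorize(
    avg_fpkm: float, pvalue: float, log2fc: float, config: RunConfig | None = None
) -> str:
    """Low / Up / Down / NS per-cell-line category (strict inequalities)."""
    config = config or RunConfig()
    if avg_fpkm < config.expr_fpkm_min:
        return "Low"
    if pvalue < config.pvalue_max and log2fc > 0:
        return "Up"
    if pvalue < config.pvalue_max and log2fc < 0:
        return "Down"
    return "NS"


def cross_cell_label(categories: Mapping[str, str], config: RunConfig | None = None) -> str:
    """Combine the per-cell-line categories into one label.

    One distinct category -> "<Cat> common"; exactly two with one of them
    Low -> "<Other> specific"; anything else -> the distinct non-Low
    categories joined in Up/Down/NS order, suffixed " switch".
    """
    config = config or RunConfig()
    expected = set(config.cell_line_names)
    if set(categories) != expected:
        raise ValueError(
            f"categories for cell lines {sorted(categories)} != configured {sorted(expected)}"
        )
    bad = {c for c in categories.values() if c not in CATEGORIES}
    if bad:
        raise ValueError(f"unknown categories {sorted(bad)}")
    distinct = set(categories.values())
    if len(distinct) == 1:
        return f"{distinct.pop()} common"
    if len(distinct) == 2 and "Low" in distinct:
        other = (distinct - {"Low"}).pop()
        return f"{other} specific"
    non_low = [c for c in _SWITCH_ORDER if c in distinct]
    return "–".join(non_low) + " switch"


def build_sets(
    labels: Mapping[str, str], reference: Sequence[TranscriptModel]
) -> tuple[list[str], list[str], list[str]]:
    """SE / EX / BG transcript id sets.

    SE = Up common + Up specific; EX = NS common; BG = the full reference.
    Within SE and within EX, when a gene contributes both its representative
    and intron-retaining transcript, the representative is dropped.
    """
    by_id = {t.id: t for t in reference}
    missing = [tid for tid in by_id if tid not in labels]
    if missing:
        raise ValueError(f"labels missing for reference transcripts {missing[:5]}")

    def dedup(ids: list[str]) -> list[str]:
        ir_genes = {by_id[i].gene_id for i in ids if by_id[i].kind == "intron_retaining"}
        return [
            i
            for i in ids
            if not (by_id[i].kind == "representative" and by_id[i].gene_id in ir_genes)
        ]

    se = dedup([t.id for t in reference if labels[t.id] in ("Up common", "Up specific")])
    ex = dedup([t.id for t in reference if labels[t.id] == "NS common"])
    bg = [t.id for t in reference]
    log.info("build_sets: |SE|=%d |EX|=%d |BG|=%d", len(se), len(ex), len(bg))
    return se, ex, bg


# ---------------------------------------------------------------------------
# Orchestration


def run_differential(
    counts: ExpressionTable,
    lengths: Mapping[str, int],
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Per-transcript, per-cell-line differential table.

    Columns: transcript_id, cell_line, avg_fpkm, log2fc, pvalue, category.
    ``avg_fpkm`` averages FPKM over all samples of the cell line (both
    conditions).
    """
    config = config or RunConfig()
    fpkm = compute_fpkm(counts, lengths)
    rows: list[dict] = []
    for cell in counts.cell_lines:
        conv_cols = counts.columns_for(cell, "conventional")
        impr_cols = counts.columns_for(cell, "improved")
        if not conv_cols or not impr_cols:
            raise ValueError(f"cell line {cell} lacks one of the two conditions")
        pair = counts.data[conv_cols + impr_cols]
        eff = effective_lib_sizes(pair, config.normalization)
        eff_c, eff_i = eff[: len(conv_cols)], eff[len(conv_cols):]
        conv_mat = counts.data[conv_cols].to_numpy()
        impr_mat = counts.data[impr_cols].to_numpy()
        avg = fpkm.data[conv_cols + impr_cols].mean(axis=1).to_numpy()
        for idx, tid in enumerate(counts.feature_ids):
            lfc, p = nb_exact_test(
                conv_mat[idx],
                impr_mat[idx],
                dispersion=config.dispersion,
                lib_sizes_conventional=eff_c,
                lib_sizes_improved=eff_i,
                prior_count=config.prior_count,
            )
            rows.append(
                {
                    "transcript_id": tid,
                    "cell_line": cell,
                    "avg_fpkm": avg[idx],
                    "log2fc": lfc,
                    "pvalue": p,
                    "category": categorize(avg[idx], p, lfc, config),
                }
            )
        log.info("run_differential: %s done (%d transcripts)", cell, len(counts.feature_ids))
    return pd.DataFrame(rows)


def label_table(differential: pd.DataFrame, config: RunConfig | None = None) -> pd.Series:
    """Cross-cell-line label per transcript from the differential table."""
    config = config or RunConfig()
    pivot = differential.pivot(index="transcript_id", columns="cell_line", values="category")
    return pivot.apply(lambda row: cross_cell_label(row.to_dict(), config), axis=1)
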