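"""Simplified PWM scanning for RBP binding sites.

The scanner mirrors the published scanning setup: forward strand only, a
0.1 pseudocount on the probability matrix, and a score threshold set so
that a random background word reaches it with probability <= 0.01. Scores
are log2 odds against the background, discretized to 1/1000 of the motif's
score range (the standard trick that makes the exact score distribution
computable by dynamic programming); scanning and the threshold share the
same discretization, so site calls are exactly reproducible.

A transcript's binding score for an RBP is its number of sites divided by
the transcript length; the binding preference of an RBP for the SE set is
the log2 ratio of its mean binding score over SE to that over EX.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ALPHABET = "ACGU"
_INDEX = {**{b: i for i, b in enumerate(ALPHABET)}, "T": ALPHABET.index("U")}
_NBINS = 1000  # score-range discretization for the threshold DP


@dataclass
class MotifModel:
    """A prepared position weight matrix with its derived scoring pieces."""

    rbp_name: str
    pwm: np.ndarray  # (w, 4) probabilities after pseudocount renormalization
    background: np.ndarray  # (4,)
    pseudocount: float
    log_odds: np.ndarray  # (w, 4) log2(p / background)
    iscores: np.ndarray  # (w, 4) discretized integer scores
    scale: float  # integer units per log2-odds unit (0 for flat motifs)
    col_min: np.ndarray  # (w,) per-column real log-odds minima
    score_threshold: float | None = None  # real-valued, set by threshold_from_pvalue
    ithreshold: int | None = None

    @property
    def width(self) -> int:
        return len(self.pwm)

    def int_to_real(self, t: int) -> float:
        if self.scale == 0:
            return float(self.col_min.sum())
        return t / self.scale + float(self.col_min.sum())

    def neutral_iscore(self, i: int) -> int:
        """Integer score of a background-neutral (N) base at column i."""
        if self.scale == 0:
            return 0
        return int(round((0.0 - self.col_min[i]) * self.scale))


def prepare_motif(
    raw: np.ndarray,
    rbp_name: str = "motif",
    pseudocount: float = 0.1,
    background: Sequence[float] | None = None,
) -> MotifModel:
    """Renormalize a raw probability matrix and derive the scoring matrices.

    Each column (position) becomes ``(p + pseudocount * background) /
    (1 + pseudocount)``; T and U inputs are interchangeable upstream (the
    readers already map to ACGU order).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != 4:
        raise ValueError("expected a (w, 4) probability matrix")
    if len(raw) < 3:
        raise ValueError("motif width must be >= 3")
    if (raw < 0).any():
        raise ValueError("negative probabilities")
    if (raw.sum(axis=1) == 0).any():
        raise ValueError("zero probability column")
    if not np.allclose(raw.sum(axis=1), 1.0, atol=0.1):
        raise ValueError("probability columns must roughly sum to 1")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if not np.isclose(bg.sum(), 1.0) or (bg <= 0).any():
        raise ValueError("background must be a positive distribution")
    pwm = (raw + pseudocount * bg[None, :]) / (raw.sum(axis=1, keepdims=True) + pseudocount)
    log_odds = np.log2(pwm / bg[None, :])
    col_min = log_odds.min(axis=1)
    col_max = log_odds.max(axis=1)
    rng = float((col_max - col_min).sum())
    if rng == 0:
        scale = 0.0
        iscores = np.zeros_like(log_odds, dtype=np.int64)
    else:
        scale = _NBINS / rng
        iscores = np.rint((log_odds - col_min[:, None]) * scale).astype(np.int64)
    return MotifModel(
        rbp_name=rbp_name,
        pwm=pwm,
        background=bg,
        pseudocount=pseudocount,
        log_odds=log_odds,
        iscores=iscores,
        scale=scale,
        col_min=col_min,
    )


def _int_score_tail(motif: MotifModel, method: str) -> np.ndarray:
    """P(integer word score >= t) for every t, under the background model."""
    max_total = int(motif.iscores.max(axis=1).sum())
    if method == "dp":
        dist = np.zeros(max_total + 1)
        dist[0] = 1.0
        top = 0
        for i in range(motif.width):
            new = np.zeros(max_total + 1)
            for b in range(4):
                s = int(motif.iscores[i, b])
                new[s : top + s + 1] += motif.background[b] * dist[: top + 1]
            dist = new
            top += int(motif.iscores[i].max())
        probs = dist
    elif method == "enumerate":
        if motif.width > 8:
            raise ValueError("enumeration limited to width <= 8")
        probs = np.zeros(max_total + 1)
        totals = np.zeros(1, dtype=np.int64)
        ws = np.ones(1)
        for i in range(motif.width):
            totals = (totals[:, None] + motif.iscores[i][None, :]).ravel()
            ws = (ws[:, None] * motif.background[None, :]).ravel()
        np.add.at(probs, totals, ws)
    else:
        raise ValueError(f"unknown method {method!r}")
    return np.cumsum(probs[::-1])[::-1]


def threshold_from_pvalue(
    motif: MotifModel, pvalue: float = 0.01, method: str = "dp"
) -> float:
    """Smallest score whose background tail probability is <= pvalue.

    Computed on the discretized score distribution either by dynamic
    programming over positions (default) or by brute-force enumeration of
    all 4^w words (cross-check, w <= 8). Sets ``score_threshold`` /
    ``ithreshold`` on the motif and returns the real-valued threshold. When
    no achievable score qualifies, the threshold is set above the maximum
    so that nothing matches.
    """
    if not 0 < pvalue <= 1:
        raise ValueError("pvalue must be in (0, 1]")
    tail = _int_score_tail(motif, method)
    qualifying = np.nonzero(tail <= pvalue + 1e-12)[0]
    ithr = int(qualifying[0]) if qualifying.size else len(tail)
    motif.ithreshold = ithr
    motif.score_threshold = motif.int_to_real(ithr)
    return motif.score_threshold


def scan(sequence: str, motif: MotifModel) -> list[int]:
    """All 0-based positions whose window score reaches the threshold.

    Forward strand only (no reverse-complement scan); overlapping sites are
    all reported; unknown bases (N) contribute a background-neutral score.
    """
    if motif.ithreshold is None:
        threshold_from_pvalue(motif)
    w = motif.width
    seq = sequence.upper().replace("T", "U")
    if len(seq) < w:
        raise ValueError("sequence shorter than motif width")
    codes = np.array([_INDEX.get(c, -1) for c in seq], dtype=np.int64)
    neutral = np.array([motif.neutral_iscore(i) for i in range(w)], dtype=np.int64)
    total = np.zeros(len(seq) - w + 1, dtype=np.int64)
    for i in range(w):
        col = codes[i : len(seq) - w + 1 + i]
        scores = np.where(col >= 0, motif.iscores[i][np.clip(col, 0, 3)], neutral[i])
        total += scores
    return np.nonzero(total >= motif.ithreshold)[0].tolist()


@dataclass
class BindingProfile:
    """Site statistics of one RBP on one transcript."""

    transcript_id: str
    rbp_name: str
    length: int
    n_sites: int
    region_sites: np.ndarray  # (5,) site counts per fifth
    region_scores: np.ndarray  # (5,) per-region site densities

    @property
    def binding_score(self) -> float:
        return self.n_sites / self.length


def positional_profile(sites: Sequence[int], length: int) -> np.ndarray:
    """Site density in each of five equal transcript regions.

    Region r (1..5) covers bases [floor((r-1)L/5), floor(rL/5)); the density
    is the number of sites starting in the region divided by the region
    length.
    """
    if length < 5:
        raise ValueError("transcript too short to split into five regions")
    bounds = [length * r // 5 for r in range(6)]
    dens = np.zeros(5)
    arr = np.asarray(sites, dtype=int)
    for r in range(5):
        n = int(((arr >= bounds[r]) & (arr < bounds[r + 1])).sum()) if arr.size else 0
        dens[r] = n / (bounds[r + 1] - bounds[r])
    return dens


def binding_profile(transcript_id: str, sequence: str, motif: MotifModel) -> BindingProfile:
    sites = scan(sequence, motif)
    length = len(sequence)
    bounds = [length * r // 5 for r in range(6)]
    arr = np.asarray(sites, dtype=int)
    counts = np.array(
        [((arr >= bounds[r]) & (arr < bounds[r + 1])).sum() if arr.size else 0 for r in range(5)]
    )
    return BindingProfile(
        transcript_id=transcript_id,
        rbp_name=motif.rbp_name,
        length=length,
        n_sites=len(sites),
        region_sites=counts,
        region_scores=positional_profile(sites, length),
    )


def binding_preference(
    se_profiles: Sequence[BindingProfile], ex_profiles: Sequence[BindingProfile]
) -> float:
    """log2 ratio of mean binding score over SE to mean over EX.

    A pseudo-score of 1/(total length of both sets) guards zero means while
    keeping the value antisymmetric under swapping the sets.
    """
    if not se_profiles or not ex_profiles:
        raise ValueError("both profile sets must be nonempty")
    eps = 1.0 / (
        sum(p.length for p in se_profiles) + sum(p.length for p in ex_profiles)
    )
    mean_se = float(np.mean([p.binding_score for p in se_profiles]))
    mean_ex = float(np.mean([p.binding_score for p in ex_profiles]))
    return float(np.log2(mean_se + eps) - np.log2(mean_ex + eps))


def preference_table(
    motifs: Sequence[MotifModel],
    se_seqs: Mapping[str, str],
    ex_seqs: Mapping[str, str],
) -> pd.DataFrame:
    """Figure-style per-RBP preference matrix: five regions plus ``avg``.

    Per region, the preference is the log2 ratio of the mean SE region
    density to the mean EX region density (same pseudo-score guard); the
    ``avg`` column is the whole-transcript binding preference. Sorted by
    ``avg`` descending.
    """
    rows = []
    for m in motifs:
        se_p = [binding_profile(t, s, m) for t, s in se_seqs.items()]
        ex_p = [binding_profile(t, s, m) for t, s in ex_seqs.items()]
        eps = 1.0 / (sum(p.length for p in se_p) + sum(p.length for p in ex_p))
        row = {"rbp": m.rbp_name}
        for r in range(5):
            mean_se = float(np.mean([p.region_scores[r] for p in se_p]))
            mean_ex = float(np.mean([p.region_scores[r] for p in ex_p]))
            row[f"region{r + 1}"] = float(np.log2(mean_se + eps) - np.log2(mean_ex + eps))
        row["avg"] = binding_preference(se_p, ex_p)
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("avg", ascending=False, kind="mergesort")
    return df.reset_index(drop=True)
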