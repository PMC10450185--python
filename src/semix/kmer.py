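"""k-mer content profiling and community detection (SEEKR-style).

Transcripts are represented by length-normalized, log-transformed,
column-standardized 6-mer count profiles; pairwise Pearson correlation
above a threshold (0.19) defines the edges of an undirected similarity
graph whose Louvain communities group RNAs of similar sequence
composition. Isolated transcripts fall into the null community.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .motif import MotifModel, BindingProfile, binding_preference, binding_profile

_BASES = "ACGU"
_CODE = {**{b: i for i, b in enumerate(_BASES)}, "T": _BASES.index("U")}


def kmer_order(k: int) -> list[str]:
    """Lexicographic ACGU k-mer order used by all count vectors."""
    return ["".join(p) for p in product(_BASES, repeat=k)]


def count_kmers(sequence: str, k: int = 6) -> np.ndarray:
    """Overlapping k-mer window counts; windows containing N are skipped."""
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = sequence.upper().replace("T", "U")
    codes = np.array([_CODE.get(c, -1) for c in seq], dtype=np.int64)
    counts = np.zeros(4**k, dtype=np.int64)
    if codes.size < k:
        return counts
    n_win = codes.size - k + 1
    idx = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for i in range(k):
        col = codes[i : i + n_win]
        valid &= col >= 0
        idx = idx * 4 + np.clip(col, 0, 3)
    np.add.at(counts, idx[valid], 1)
    return counts


@dataclass
class KmerProfile:
    transcript_id: str
    k: int
    counts: np.ndarray
    normalized: np.ndarray | None = None


def normalize_profiles(
    counts: Mapping[str, np.ndarray], lengths: Mapping[str, int]
) -> pd.DataFrame:
    """Per-kilobase rates, log2(x+1), then per-k-mer column z-scores.

    Zero-variance columns are left at 0 after centering. Returns a
    transcript x k-mer matrix.
    """
    ids = list(counts)
    if len(ids) < 2:
        raise ValueError("need >= 2 transcripts to normalize")
    mat = np.stack([counts[t] for t in ids]).astype(float)
    lens = np.array([lengths[t] for t in ids], dtype=float)
    if (lens <= 0).any():
        raise ValueError("non-positive transcript length")
    rates = mat / (lens[:, None] / 1000.0)
    logged = np.log2(rates + 1.0)
    mean = logged.mean(axis=0)
    std = logged.std(axis=0)
    z = np.where(std > 0, (logged - mean) / np.where(std > 0, std, 1.0), logged - mean)
    k = int(round(np.log(mat.shape[1]) / np.log(4)))
    return pd.DataFrame(z, index=ids, columns=kmer_order(k))


def similarity_graph(normalized: pd.DataFrame, threshold: float = 0.19) -> nx.Graph:
    """Graph with an edge wherever the row Pearson correlation exceeds the
    threshold (strict); every transcript is a node, no self-edges."""
    if len(normalized) < 2:
        raise ValueError("need >= 2 profiles")
    corr = np.corrcoef(normalized.to_numpy())
    graph = nx.Graph()
    ids = list(normalized.index)
    graph.add_nodes_from(ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if corr[i, j] > threshold:
                graph.add_edge(ids[i], ids[j], weight=float(corr[i, j]))
    return graph


def louvain_communities(graph: nx.Graph, rng_seed: int = 0) -> dict[str, int | None]:
    """Louvain partition; singletons and isolated nodes get the null
    community (``None``); communities are renumbered 1.. by descending size.

    Deterministic for a fixed seed and node insertion order.
    """
    connected = [n for n in graph.nodes if graph.degree(n) > 0]
    assignment: dict[str, int | None] = {n: None for n in graph.nodes}
    if connected:
        sub = graph.subgraph(connected)
        parts = nx.community.louvain_communities(sub, seed=rng_seed)
        parts = [sorted(p) for p in parts if len(p) > 1]
        parts.sort(key=lambda p: (-len(p), p[0]))
        for rank, part in enumerate(parts, start=1):
            for node in part:
                assignment[node] = rank
    return assignment


def assignment_table(assignment: Mapping[str, int | None]) -> pd.DataFrame:
    """Community assignment as a table; the null community is written ``N``."""
    return pd.DataFrame(
        {
            "transcript_id": list(assignment),
            "community": ["N" if c is None else str(c) for c in assignment.values()],
        }
    )


def community_rbp_preference(
    assignment: Mapping[str, int | None],
    motifs: Sequence[MotifModel],
    se_seqs: Mapping[str, str],
    ex_seqs: Mapping[str, str],
) -> pd.DataFrame:
    """Binding preference of each RBP for each community (vs the common EX set).

    Each non-null community plays the role of the SE set in the preference
    ratio. Returns a community x RBP matrix.
    """
    communities = sorted({c for c in assignment.values() if c is not None})
    if not communities:
        raise ValueError("no non-null community")
    ex_profiles: dict[str, list[BindingProfile]] = {
        m.rbp_name: [binding_profile(t, s, m) for t, s in ex_seqs.items()] for m in motifs
    }
    rows = {}
    for com in communities:
        members = [t for t, c in assignment.items() if c == com and t in se_seqs]
        if not members:
            raise ValueError(f"community {com} has no sequences")
        row = {}
        for m in motifs:
            se_profiles = [binding_profile(t, se_seqs[t], m) for t in members]
            row[m.rbp_name] = binding_preference(se_profiles, ex_profiles[m.rbp_name])
        rows[com] = row
    return pd.DataFrame.from_dict(rows, orient="index")
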