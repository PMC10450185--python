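"""Run configuration: every tunable threshold of the pipeline in one place.

Defaults are the published analysis values; a YAML file may override any
subset, and every run writes back the fully resolved configuration so that a
result can always be traced to the thresholds that produced it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

DEFAULT_CELL_LINES = ("A10", "A549", "HAP1", "HEK", "HeLa")


@dataclass
class RunConfig:
    # reference transcriptome
    intron_fpkm_min: float = 0.1  # mean intron FPKM must exceed this
    rs_min: float = 0.1  # retention score must exceed this
    intergenic_flank_nt: int = 5000
    # semi-extractability calling
    expr_fpkm_min: float = 0.5  # below this a transcript is "Low"
    pvalue_max: float = 0.05
    dispersion: float = 0.125  # common NB dispersion for the exact test
    prior_count: float = 0.125  # fold-change shrinkage offset per sample
    normalization: str = "tmm"  # "tmm" | "libsize"
    # motif scanning
    motif_pvalue: float = 0.01
    motif_pseudocount: float = 0.1
    # k-mer communities
    kmer_k: int = 6
    kmer_similarity_threshold: float = 0.19
    # end regions / MFE export
    end_region_nt: int = 300
    min_transcript_nt_for_mfe: int = 600
    # hub RNAs
    hub_min_partners: int = 20
    # bookkeeping
    rng_seed: int = 0
    cell_line_names: tuple[str, ...] = DEFAULT_CELL_LINES

    _POSITIVE = (
        "intron_fpkm_min",
        "rs_min",
        "intergenic_flank_nt",
        "expr_fpkm_min",
        "pvalue_max",
        "dispersion",
        "motif_pvalue",
        "motif_pseudocount",
        "kmer_k",
        "kmer_similarity_threshold",
        "end_region_nt",
        "min_transcript_nt_for_mfe",
        "hub_min_partners",
    )

    def __post_init__(self) -> None:
        for name in self._POSITIVE:
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"config threshold {name} must be > 0, got {value}")
        if self.normalization not in ("tmm", "libsize"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        self.cell_line_names = tuple(self.cell_line_names)
        if not self.cell_line_names:
            raise ValueError("cell_line_names must be nonempty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["cell_line_names"] = list(self.cell_line_names)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
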