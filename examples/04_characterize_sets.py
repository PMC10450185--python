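"""Chromatin-state composition and hub-RNA overlap of a called SE set.

Runs the pipeline on a small synthetic dataset and prints the Table-style
state composition (percentages sum to 100 per set; SE/EX > 1 marks states
over-represented among semi-extractable RNAs) and the hub overlap with
its hypergeometric enrichment p-value.
"""

import tempfile
from pathlib import Path

from semix import RunConfig, SimulationParams
from semix.pipeline import run_all

with tempfile.TemporaryDirectory() as tmp:
    results = run_all(
        RunConfig(rng_seed=7),
        Path(tmp) / "run",
        SimulationParams(n_genes=120, mean_depth=400_000, rng_seed=7),
    )
    enr = results["characterize"]["enrichment"]
    print(enr.round(2).to_string(index=False))
    n, pct, p = results["characterize"]["hub"]
    print(f"\nhub RNAs inside SE: {n} ({pct:.2f}% of hubs), hypergeometric p = {p:.3g}")
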