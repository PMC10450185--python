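"""Retention score of an intron from exon/intron FPKM evidence.

RS = 2 * sum_j I_j / (sum_j E5_j + sum_j E3_j), pooling the improved-
extraction sample of each cell line; an intron with mean FPKM > 0.1 and
RS > 0.1 is merged into the intron-retaining transcript.
"""

from semix.config import RunConfig
from semix.intervals import GenomicInterval
from semix.models import IntronRecord
from semix.transcriptome import call_retained_introns, retention_score

cells = ["A10", "A549", "HAP1", "HEK", "HeLa"]
intron = IntronRecord(
    gene_id="G0001",
    index=1,
    interval=GenomicInterval("chr1", 1000, 1600),
    intron_fpkm={c: 0.5 for c in cells},
    exon5_fpkm={c: 1.0 for c in cells},
    exon3_fpkm={c: 3.0 for c in cells},
)
rs = retention_score(intron)
print(f"RS = 2*{0.5 * 5} / ({1.0 * 5} + {3.0 * 5}) = {rs}")
kept = call_retained_introns([intron], RunConfig())
print("retained:", bool(kept), "(mean intron FPKM 0.5 > 0.1 and RS 0.25 > 0.1)")
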