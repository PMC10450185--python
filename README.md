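# semix — semi-extractable RNA discovery and characterization

RNAs that scaffold phase-separated nuclear bodies (the paraspeckle lncRNA
NEAT1 is the canonical case) are poorly recovered by conventional AGPC
(TRIzol-type) extraction: they stay trapped in the protein interphase and
only appear in the aqueous phase after the condensates are disrupted by
needle shearing or heating. RNA-seq libraries made with the conventional
vs the improved extraction therefore differ precisely for this class of
**semi-extractable RNAs**, and calling transcripts significantly
up-regulated under improved extraction is a genome-wide screen for
condensate-associated RNA.

`semix` implements that screen and the downstream characterization as a
tested Python library, with a synthetic-data generator (known ground
truth) standing in for the sequencing data. It is aimed at computational
RNA biologists who want to run, adapt or stress-test the pipeline without
the original raw libraries.

## What it computes

**Reference transcriptome** (`semix.transcriptome`)
- *representative transcripts*: all annotated exons of a gene collapsed
  into one exon-union model;
- *intron-retaining transcripts*: the representative model merged with
  every intron whose retention score

  `RS_i = 2 Σ_j I_i^j / (Σ_j E_i^j + Σ_j E_{i+1}^j)`

  exceeds 0.1 with mean intron FPKM > 0.1 (I = intron FPKM, E = flanking
  exon FPKM, j runs over the improved-extraction sample of each cell line);
- *intergenic transcripts*: assembled transcripts whose span stays ≥ 5000 nt
  away from every representative transcript, on either strand.

**Semi-extractability calling** (`semix.semiextract`)
- per cell line, a conditional negative-binomial exact test at a fixed
  common dispersion φ = 0.125 (counts adjusted to a common effective
  library size with TMM normalization) gives log2FC and a two-sided p;
- categories: `Low` (avg FPKM < 0.5), `Up` (p < 0.05, log2FC > 0),
  `Down` (p < 0.05, log2FC < 0), else `NS`;
- cross-cell-line labels (`Up common`, `Up specific`, `NS common`,
  `Up–NS switch`, …); **SE** = Up common ∪ Up specific, **EX** = NS common,
  **BG** = the whole reference (dropping a gene's representative model when
  its intron-retaining sibling is also selected).

**Characterization** (`semix.characterize`, `semix.motif`, `semix.kmer`)
- ChromHMM state composition of the SE/EX/BG transcribed regions (ten
  functional state groups, SE/EX and SE/BG ratios);
- repeat density and RNA–chromatin contact coverage per transcript;
- subcellular localization fold changes (labeled/unlabeled abundance);
- hub-RNA overlap with hypergeometric enrichment;
- 5′/3′ 300-nt end-region extraction for external RNA folding (RNAfold);
- PWM scanning at a p ≤ 0.01 score threshold (forward strand, pseudocount
  0.1), binding scores (sites / length) and SE-vs-EX binding preference;
- SEEKR-style 6-mer profiles, Pearson similarity graph at 0.19, Louvain
  communities, and per-community RBP preference.

## Worked example

```
$ python examples/01_simulate_and_call.py
reference transcripts by kind:
representative      100
intron_retaining     49
intergenic            8

|SE| = 5  |EX| = 85  |BG| = 157
planted SE genes recovered: 5 of 5
```

The generator planted 5 semi-extractable genes (4-fold up under improved
extraction in all five cell lines) among 100; the pipeline rebuilt the
reference (49 genes carried a retained intron, 8 assembled transcripts
passed the intergenic distance filter), and the exact test recovered all
5 planted genes into the SE set with no false members. The remaining
examples (`examples/02`–`06`) walk through the retention score, the exact
test, the chromatin-state/hub characterization, PWM scanning and the
k-mer communities, each printing the quantity it computes.

There is also a thin CLI over the same stages:

```
semix run-all --seed 1 --out myrun        # simulate + all stages
semix build-ref --out myrun               # or stage by stage
semix call-se --out myrun
```

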