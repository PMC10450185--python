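"""The conditional NB exact test behind per-cell-line Up/Down calls.

Counts from the two extraction conditions are compared at a fixed common
dispersion of 0.125; the printed p-value is the two-sided conditional
tail and log2FC is improved over conventional.
"""

from semix.semiextract import categorize, nb_exact_test

conventional = [120, 95]
improved = [480, 510]
lfc, p = nb_exact_test(conventional, improved, dispersion=0.125)
print(f"conventional={conventional} improved={improved}")
print(f"log2FC = {lfc:.3f}   p = {p:.4g}")
print("category at avg FPKM 12.0:", categorize(12.0, p, lfc))

# a transcript with no change
lfc0, p0 = nb_exact_test([200, 180], [205, 175])
print(f"\nno-change transcript: log2FC = {lfc0:.3f}, p = {p0:.3f} -> ",
      categorize(8.0, p0, lfc0))
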