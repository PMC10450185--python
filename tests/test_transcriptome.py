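"""Reference transcriptome construction: exon collapsing, retention
scoring, intron-retaining models and the intergenic distance filter."""

import numpy as np
import pytest

from semix.config import RunConfig
from semix.intervals import GenomicInterval
from semix.models import IntronRecord, TranscriptModel
from semix.transcriptome import (
    assemble_reference,
    build_intron_retaining,
    call_retained_introns,
    collapse_exons,
    filter_intergenic,
    retention_score,
)


def iv(start, end, strand="+", chrom="c"):
    return GenomicInterval(chrom, start, end, strand)


def make_intron(i_fpkm, e5_fpkm, e3_fpkm, gene="g", index=1, interval=None):
    cells = [f"L{j}" for j in range(len(i_fpkm))]
    return IntronRecord(
        gene_id=gene,
        index=index,
        interval=interval or iv(100, 200),
        intron_fpkm=dict(zip(cells, i_fpkm)),
        exon5_fpkm=dict(zip(cells, e5_fpkm)),
        exon3_fpkm=dict(zip(cells, e3_fpkm)),
    )


class TestCollapseExons:
    def test_overlapping_exons_union(self):
        rep = collapse_exons("g", [iv(0, 100), iv(50, 150)])
        assert [(e.start, e.end) for e in rep.exons] == [(0, 150)]

    def test_disjoint_exons_leave_an_intron(self):
        rep = collapse_exons("g", [iv(0, 100), iv(200, 300)])
        assert [(e.start, e.end) for e in rep.exons] == [(0, 100), (200, 300)]
        assert [(i.start, i.end) for i in rep.introns()] == [(100, 200)]

    def test_mixed_strands_error(self):
        with pytest.raises(ValueError, match="strand"):
            collapse_exons("g", [iv(0, 100, "+"), iv(200, 300, "-")])

    def test_idempotent_order_invariant_and_matches_base_union(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            exons = [
                iv(s, s + int(rng.integers(1, 60)))
                for s in rng.integers(0, 500, size=20)
            ]
            rep = collapse_exons("g", exons)
            expected = set()
            for e in exons:
                expected.update(range(e.start, e.end))
            got = set()
            for e in rep.exons:
                got.update(range(e.start, e.end))
            assert got == expected
            # bookended runs must be merged, so gaps are real
            assert all(b.start > a.end for a, b in zip(rep.exons, rep.exons[1:]))
            shuffled = list(exons)
            rng.shuffle(shuffled)
            again = collapse_exons("g", shuffled)
            assert [(e.start, e.end) for e in again.exons] == [
                (e.start, e.end) for e in rep.exons
            ]
            twice = collapse_exons("g", rep.exons)
            assert [(e.start, e.end) for e in twice.exons] == [
                (e.start, e.end) for e in rep.exons
            ]


class TestRetentionScore:
    def test_equal_expression_gives_one(self):
        assert retention_score(make_intron([2], [2], [2])) == pytest.approx(1.0)

    def test_zero_intron_gives_zero(self):
        assert retention_score(make_intron([0] * 5, [1] * 5, [1] * 5)) == 0.0

    def test_five_sample_pooling(self):
        rs = retention_score(make_intron([0.5] * 5, [1.0] * 5, [3.0] * 5))
        assert rs == pytest.approx(2 * 2.5 / (5 + 15))

    def test_zero_denominator_is_undefined(self):
        assert retention_score(make_intron([1.0], [0.0], [0.0])) is None

    def test_negative_fpkm_rejected(self):
        with pytest.raises(ValueError):
            make_intron([-1.0], [1.0], [1.0])


class TestCallRetainedIntrons:
    @pytest.mark.parametrize(
        "i_fpkm,e_fpkm,retained",
        [
            (0.2, 1.0, True),  # RS = 0.2 > 0.1, FPKM 0.2 > 0.1
            (0.1, 1.0, False),  # FPKM boundary: strict >
            (0.5, 10.0, False),  # RS = 0.1 boundary: strict >
        ],
    )
    def test_strict_thresholds(self, i_fpkm, e_fpkm, retained):
        rec = make_intron([i_fpkm] * 5, [e_fpkm] * 5, [e_fpkm] * 5)
        kept = call_retained_introns([rec], RunConfig())
        assert (len(kept) == 1) is retained

    def test_undefined_rs_not_retained(self):
        rec = make_intron([1.0], [0.0], [0.0])
        assert call_retained_introns([rec], RunConfig()) == []


class TestIntronRetaining:
    def rep(self):
        return collapse_exons("g", [iv(0, 100), iv(200, 300), iv(400, 500)])

    def test_merge_closes_the_gap(self):
        rep = collapse_exons("g", [iv(0, 100), iv(200, 300)])
        model = build_intron_retaining(rep, [make_intron([1], [1], [1], interval=iv(100, 200))])
        assert [(e.start, e.end) for e in model.exons] == [(0, 300)]
        assert model.kind == "intron_retaining"
        assert model.length > rep.length

    def test_no_retained_introns_no_model(self):
        assert build_intron_retaining(self.rep(), []) is None

    def test_partial_retention_keeps_other_intron(self):
        model = build_intron_retaining(
            self.rep(), [make_intron([1], [1], [1], interval=iv(100, 200))]
        )
        assert [(e.start, e.end) for e in model.exons] == [(0, 300), (400, 500)]

    def test_foreign_intron_rejected(self):
        with pytest.raises(ValueError):
            build_intron_retaining(
                self.rep(), [make_intron([1], [1], [1], interval=iv(120, 180))]
            )


class TestIntergenicFilter:
    def gene(self):
        return collapse_exons("g", [iv(10_000, 15_000), iv(19_000, 20_000)])

    def t(self, start, end, tid="a"):
        return TranscriptModel(id=tid, gene_id=tid, exons=[iv(start, end)])

    def test_far_transcript_kept(self):
        kept = filter_intergenic([self.t(25_001, 26_000)], [self.gene()], flank=5000)
        assert len(kept) == 1 and kept[0].kind == "intergenic"

    def test_near_transcript_removed(self):
        assert filter_intergenic([self.t(24_000, 24_500)], [self.gene()], flank=5000) == []

    def test_strand_agnostic(self):
        minus = TranscriptModel(id="m", gene_id="m", exons=[iv(24_000, 24_500, "-")])
        assert filter_intergenic([minus], [self.gene()], flank=5000) == []

    def test_matches_brute_force_distance_check(self):
        rng = np.random.default_rng(9)
        genes = [
            collapse_exons(f"g{i}", [iv(s, s + 2000)])
            for i, s in enumerate(rng.integers(0, 200_000, size=8))
        ]
        cands = [self.t(int(s), int(s) + 500, tid=f"c{i}") for i, s in enumerate(rng.integers(0, 210_000, size=60))]
        kept = {t.id for t in filter_intergenic(cands, genes, flank=5000)}
        expected = set()
        for c in cands:
            s = c.span
            if all(
                s.end <= g.span.start - 5000 or s.start >= g.span.end + 5000
                for g in genes
            ):
                expected.add(c.id)
        assert kept == expected


class TestAssembleReference:
    def test_counts_and_partition(self):
        reps = [collapse_exons(f"g{i}", [iv(0, 100)]) for i in range(3)]
        ir = [
            TranscriptModel(id="g0.ir", gene_id="g0", exons=[iv(0, 150)], kind="intron_retaining")
        ]
        inter = [TranscriptModel(id="s1", gene_id="s1", exons=[iv(0, 50)], kind="intergenic")]
        ref = assemble_reference(reps, ir, inter)
        assert len(ref) == 5
        kinds = {t.kind for t in ref}
        assert kinds == {"representative", "intron_retaining", "intergenic"}
        assert assemble_reference(reps, [], []) is not None

    def test_duplicate_ids_rejected(self):
        reps = [collapse_exons("g", [iv(0, 100)])]
        with pytest.raises(ValueError, match="duplicate"):
            assemble_reference(reps, [], [TranscriptModel(id="g.rep", gene_id="x", exons=[iv(0, 10)], kind="intergenic")])
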