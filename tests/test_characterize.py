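"""Set characterization: state grouping, composition tables, coverage
fractions, localization, hub enrichment, end regions and rank-sum tests."""

import numpy as np
import pytest
from scipy import stats

from semix.characterize import (
    chromatin_enrichment,
    compare_sets,
    extract_end_regions,
    hub_overlap,
    localization_fc,
    reannotate_states,
    repeat_density,
    rna_end_coverage,
)
from semix.intervals import GenomicInterval
from semix.models import TrackAnnotation, TranscriptModel


def iv(start, end, chrom="c"):
    return GenomicInterval(chrom, start, end)


def track(name, triples):
    return TrackAnnotation(name, [(iv(s, e), lab) for s, e, lab in triples])


class TestStateGroups:
    @pytest.mark.parametrize(
        "raw,group",
        [
            ("Tss", "Active Promoter"),
            ("TssF", "Active Promoter"),
            ("Quies", "Heterochromatin/Repetitive/Copy Number Variation"),
            ("Art", "Heterochromatin/Repetitive/Copy Number Variation"),
            ("ReprD", "Polycomb Repressed"),
            ("Elon", "Transcription Associated"),
            ("12_Low", "Low Activity Proximal to Active States"),
        ],
    )
    def test_mapping(self, raw, group):
        assert reannotate_states(raw) == group

    def test_unknown_label_unmapped(self):
        assert reannotate_states("XYZ") == "unmapped"


class TestChromatinEnrichment:
    def test_single_state_is_hundred_percent(self):
        states = track("chromatin_states", [(0, 1000, "Quies")])
        df = chromatin_enrichment([iv(0, 100)], [iv(200, 300)], [iv(0, 300)], states)
        row = df[df.state == "Heterochromatin/Repetitive/Copy Number Variation"].iloc[0]
        assert row.pct_se == pytest.approx(100.0)
        assert row.ratio_se_ex == pytest.approx(1.0)

    def test_matches_per_base_tally_and_sums_to_100(self):
        rng = np.random.default_rng(14)
        labels = ["Tss", "Elon", "Quies", "ReprD", "Low"]
        states = track(
            "chromatin_states",
            [
                (int(s), int(s) + int(rng.integers(5, 60)), str(rng.choice(labels)))
                for s in rng.integers(0, 2000, size=60)
            ],
        )
        spans = {
            k: [iv(int(s), int(s) + 120) for s in rng.integers(0, 1900, size=6)]
            for k in ("se", "ex", "bg")
        }
        df = chromatin_enrichment(spans["se"], spans["ex"], spans["bg"], states)
        for col in ("pct_se", "pct_ex", "pct_bg"):
            assert df[col].sum() == pytest.approx(100.0, abs=0.1)
        # brute force per-base tally for the SE column
        base_label: dict[int, set[str]] = {}
        merged_bases = set()
        for span in spans["se"]:
            merged_bases.update(range(span.start, span.end))
        for (s_iv, lab) in states.records:
            group = reannotate_states(lab)
            for b in merged_bases & set(range(s_iv.start, s_iv.end)):
                base_label.setdefault(b, set()).add(group)
        counts = {
            g: sum(1 for gs in base_label.values() if g in gs)
            for g in {reannotate_states(l) for _, l in states.records}
        }
        total = sum(counts.values())
        for _, row in df.iterrows():
            if row.state in counts:
                assert row.pct_se == pytest.approx(100 * counts[row.state] / total, abs=1e-9)

    def test_printed_ratio_arithmetic(self):
        # Low-activity row: %SE 50.44 / %EX 31.02 -> SE/EX 1.63 at 2 dp
        assert round(50.44 / 31.02, 2) == 1.63

    def test_empty_state_track_errors(self):
        with pytest.raises(ValueError):
            chromatin_enrichment([iv(0, 10)], [iv(0, 10)], [iv(0, 10)], track("s", []))


class TestCoverageFractions:
    def transcript(self, *exons):
        return TranscriptModel(id="t", gene_id="g", exons=[iv(s, e) for s, e in exons])

    def test_full_and_zero_coverage(self):
        t = self.transcript((0, 300))
        assert repeat_density(t, track("repeats", [(0, 300, "LINE")])) == 1.0
        assert repeat_density(t, track("repeats", [(500, 600, "LINE")])) == 0.0

    def test_overlapping_repeats_counted_once(self):
        t = self.transcript((0, 300))
        rpt = track("repeats", [(0, 100, "LINE"), (50, 150, "SINE")])
        assert repeat_density(t, rpt) == pytest.approx(150 / 300)

    def test_monotone_under_added_intervals_and_bounded(self):
        rng = np.random.default_rng(3)
        t = self.transcript((0, 200), (400, 600))
        records = []
        prev = 0.0
        for s in rng.integers(0, 600, size=30):
            records.append((int(s), int(s) + int(rng.integers(1, 80)), "rna_end"))
            cov = rna_end_coverage(t, track("rna_ends", records))
            assert 0.0 <= prev <= cov <= 1.0
            prev = cov

    def test_matches_base_oracle(self):
        rng = np.random.default_rng(4)
        t = self.transcript((0, 150), (300, 450))
        records = [
            (int(s), int(s) + int(rng.integers(1, 60)), "x")
            for s in rng.integers(0, 500, size=15)
        ]
        exon_bases = set(range(0, 150)) | set(range(300, 450))
        covered = set()
        for s, e, _ in records:
            covered.update(range(s, e))
        expected = len(exon_bases & covered) / len(exon_bases)
        assert repeat_density(t, track("repeats", records)) == pytest.approx(expected)


class TestLocalization:
    def test_equal_abundance_zero(self):
        assert localization_fc(5.0, 5.0, 1.0) == 0.0

    def test_fourfold_small_pseudocount(self):
        assert localization_fc(4.0, 1.0, 1e-9) == pytest.approx(2.0, abs=1e-6)

    def test_matches_direct_arithmetic(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            a, b, pc = rng.uniform(0, 50), rng.uniform(0, 50), rng.uniform(0.1, 2)
            assert localization_fc(a, b, pc) == pytest.approx(np.log2((a + pc) / (b + pc)))


class TestHubOverlap:
    def test_printed_fraction_51(self):
        hubs = [f"h{i}" for i in range(109)]
        se = hubs[:56] + [f"s{i}" for i in range(100)]
        bg = hubs + [f"b{i}" for i in range(9000)] + [f"s{i}" for i in range(100)]
        n, pct, p = hub_overlap(se, hubs, bg)
        assert n == 56
        assert round(pct, 2) == 51.38
        assert p < 1e-10

    def test_printed_fraction_paris(self):
        hubs = [f"h{i}" for i in range(109)]
        se = hubs[:5] + [f"s{i}" for i in range(100)]
        bg = hubs + [f"b{i}" for i in range(9000)] + [f"s{i}" for i in range(100)]
        n, pct, _ = hub_overlap(se, hubs, bg)
        assert n == 5 and round(pct, 2) == 4.59

    def test_pvalue_matches_hypergeometric_enumeration(self):
        bg = [f"g{i}" for i in range(30)]
        hubs = bg[:8]
        se = bg[5:15]
        n, _, p = hub_overlap(se, hubs, bg)
        k = len(set(se) & set(hubs))
        # brute-force tail of the hypergeometric mass
        from math import comb

        total = sum(
            comb(8, x) * comb(22, 10 - x)
            for x in range(k, min(8, 10) + 1)
        ) / comb(30, 10)
        assert p == pytest.approx(total, rel=1e-12)

    def test_hubs_outside_background_dropped(self):
        n, pct, _ = hub_overlap(["a"], ["a", "zz"], ["a", "b", "c"])
        assert n == 1 and pct == 100.0


class TestEndRegions:
    def test_exact_600_splits_in_halves(self):
        seq = "A" * 300 + "C" * 300
        five, three = extract_end_regions(seq)
        assert five == "A" * 300 and three == "C" * 300

    def test_under_600_rejected(self):
        assert extract_end_regions("A" * 599) is None

    def test_length_1000_prefix_suffix(self):
        seq = "".join("ACGU"[i % 4] for i in range(1000))
        five, three = extract_end_regions(seq)
        assert five == seq[:300] and three == seq[700:]

    def test_bad_characters_rejected(self):
        with pytest.raises(ValueError):
            extract_end_regions("ACGX" * 200)


class TestCompareSets:
    def test_identical_samples_ns(self):
        _, p, stars = compare_sets([1, 2, 3, 4], [1, 2, 3, 4])
        assert p == pytest.approx(1.0) and stars == "ns"

    def test_disjoint_support_three_stars(self):
        _, p, stars = compare_sets(list(range(20)), list(range(100, 120)))
        assert p < 0.001 and stars == "***"

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1, 15)
        _, p1, _ = compare_sets(a, b)
        _, p2, _ = compare_sets(b, a)
        assert p1 == pytest.approx(p2)
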