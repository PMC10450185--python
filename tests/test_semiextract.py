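"""Differential semi-extractability calling: FPKM arithmetic, the
conditional NB exact test, categorization, cross-cell-line labels and
SE/EX/BG set construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from semix.config import RunConfig
from semix.intervals import GenomicInterval
from semix.models import ExpressionTable, TranscriptModel
from semix.semiextract import (
    build_sets,
    categorize,
    compute_fpkm,
    cross_cell_label,
    nb_exact_test,
    tmm_factors,
)

CELLS = ("A10", "A549", "HAP1", "HEK", "HeLa")


def table(data: dict, ids) -> ExpressionTable:
    return ExpressionTable(pd.DataFrame(data, index=ids), kind="counts")


class TestFpkm:
    def test_definition(self):
        t = table({"A10_improved_rep1": [10, 10**6 - 10]}, ["a", "b"])
        fpkm = compute_fpkm(t, {"a": 1000, "b": 500})
        assert fpkm.data.loc["a"].iloc[0] == pytest.approx(10.0)

    def test_zero_count_zero_fpkm(self):
        t = table({"A10_improved_rep1": [0, 100]}, ["a", "b"])
        assert compute_fpkm(t, {"a": 1000, "b": 500}).data.loc["a"].iloc[0] == 0.0

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 500, size=(20, 4))
        ids = [f"t{i}" for i in range(20)]
        cols = [f"{c}_{cond}_rep1" for c in ("A10", "A549") for cond in ("conventional", "improved")]
        t = ExpressionTable(pd.DataFrame(counts, index=ids, columns=cols))
        lengths = {i: int(l) for i, l in zip(ids, rng.integers(200, 5000, size=20))}
        fpkm = compute_fpkm(t, lengths)
        lib = counts.sum(axis=0)
        for i, tid in enumerate(ids):
            for j in range(4):
                expected = counts[i, j] / (lengths[tid] / 1e3) / (lib[j] / 1e6)
                assert fpkm.data.iloc[i, j] == pytest.approx(expected, rel=1e-12)

    def test_zero_library_errors(self):
        t = table({"A10_improved_rep1": [0, 0]}, ["a", "b"])
        with pytest.raises(ValueError, match="library"):
            compute_fpkm(t, {"a": 100, "b": 100})


def oracle_pvalue(s1, s2, n1, n2, phi, mu=7.3):
    """Independent conditional enumeration via scipy's NB pmf."""
    r1, r2 = n1 / phi, n2 / phi
    total = s1 + s2
    x = np.arange(total + 1)
    pm = stats.nbinom.pmf(x, r2, r2 / (r2 + n2 * mu)) * stats.nbinom.pmf(
        total - x, r1, r1 / (r1 + n1 * mu)
    )
    pm /= pm.sum()
    return min(1.0, pm[pm <= pm[s2] * (1 + 1e-10)].sum())


class TestExactTest:
    def test_identical_counts_are_null(self):
        lfc, p = nb_exact_test([7, 9], [7, 9])
        assert lfc == 0.0 and p == 1.0

    def test_all_zero_flagged(self):
        assert nb_exact_test([0, 0], [0, 0]) == (0.0, 1.0)

    def test_antisymmetry(self):
        l1, p1 = nb_exact_test([3, 5], [10, 14])
        l2, p2 = nb_exact_test([10, 14], [3, 5])
        assert l1 == pytest.approx(-l2)
        assert p1 == pytest.approx(p2)

    def test_monotonic_log2fc_in_improved_count(self):
        lfcs = [nb_exact_test([5, 5], [k, 5])[0] for k in range(0, 40, 3)]
        assert all(b >= a for a, b in zip(lfcs, lfcs[1:]))

    def test_binomial_limit(self):
        _, p = nb_exact_test([5], [20], dispersion=1e-7)
        assert p == pytest.approx(stats.binomtest(20, 25, 0.5).pvalue, rel=1e-4)

    def test_matches_enumeration_oracle_small_totals(self):
        rng = np.random.default_rng(0)
        for _ in range(150):
            n1, n2 = map(int, rng.integers(1, 4, 2))
            c1 = rng.integers(0, 16, n1)
            c2 = rng.integers(0, 16, n2)
            if c1.sum() + c2.sum() == 0:
                continue
            phi = float(rng.uniform(0.05, 1.0))
            _, p = nb_exact_test(c1, c2, dispersion=phi)
            assert p == pytest.approx(
                oracle_pvalue(int(c1.sum()), int(c2.sum()), n1, n2, phi), abs=1e-12
            )

    def test_pvalues_in_unit_interval(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            c1 = rng.integers(0, 1000, 2)
            c2 = rng.integers(0, 1000, 2)
            _, p = nb_exact_test(c1, c2)
            assert 0 < p <= 1


class TestTmm:
    def test_factors_multiply_to_one(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.integers(0, 1000, size=(300, 4)))
        f = tmm_factors(df)
        assert np.prod(f) == pytest.approx(1.0)

    def test_corrects_composition_shift_better_than_libsize(self):
        rng = np.random.default_rng(8)
        n = 500
        rel = rng.lognormal(0, 1, n)
        rel /= rel.sum()
        up = np.zeros(n)
        up[:25] = 4.0  # 5% of transcripts up 4x in the second pair
        cols = {}
        for name, boost in (("a", 1.0), ("b", 1.0), ("c", up), ("d", up)):
            w = rel * np.where(np.asarray(boost) > 1, boost, 1.0)
            frac = w / w.sum()
            mu = 1e6 * frac
            cols[name] = rng.poisson(mu)
        df = pd.DataFrame(cols)
        f = tmm_factors(df)
        eff = df.sum(0).to_numpy() * f
        raw = df.sum(0).to_numpy(float)
        null = slice(25, None)

        def bias(libs):
            a = (df.a[null] / libs[0] + df.b[null] / libs[1]) / 2
            c = (df.c[null] / libs[2] + df.d[null] / libs[3]) / 2
            return abs(np.mean(np.log2((c + 1e-12) / (a + 1e-12))))

        assert bias(eff) < bias(raw)
        assert bias(eff) < 0.05


class TestCategorize:
    @pytest.mark.parametrize(
        "avg,p,lfc,expected",
        [
            (0.4, 0.001, 3.0, "Low"),
            (2.0, 0.01, 1.5, "Up"),
            (2.0, 0.01, -1.5, "Down"),
            (2.0, 0.05, 1.5, "NS"),  # strict p < 0.05
            (0.5, 0.2, 0.3, "NS"),  # avg boundary: 0.5 is not Low
            (2.0, 0.01, 0.0, "NS"),  # zero fold change never Up/Down
        ],
    )
    def test_category_rules(self, avg, p, lfc, expected):
        assert categorize(avg, p, lfc, RunConfig()) == expected


class TestCrossCellLabel:
    def label(self, cats):
        return cross_cell_label(dict(zip(CELLS, cats)), RunConfig())

    def test_common(self):
        assert self.label(["Up"] * 5) == "Up common"
        assert self.label(["NS"] * 5) == "NS common"

    def test_specific(self):
        assert self.label(["Up", "Low", "Up", "Up", "Low"]) == "Up specific"

    def test_switch_naming_order(self):
        assert self.label(["Up", "NS", "Up", "NS", "NS"]) == "Up–NS switch"
        assert self.label(["NS", "Down", "NS", "NS", "NS"]) == "Down–NS switch"
        assert self.label(["Up", "Down", "NS", "NS", "Low"]) == "Up–Down–NS switch"

    def test_missing_cell_line_errors(self):
        with pytest.raises(ValueError):
            cross_cell_label({"A10": "Up"}, RunConfig())


class TestBuildSets:
    def models(self):
        out = []
        for i, kind in enumerate(
            ["representative"] * 4 + ["intron_retaining", "intergenic"]
        ):
            gene = "g0" if kind == "intron_retaining" else f"g{i}"
            out.append(
                TranscriptModel(
                    id=f"t{i}",
                    gene_id=gene,
                    exons=[GenomicInterval("c", 0, 100 + i)],
                    kind=kind,
                )
            )
        return out

    def test_membership_counting(self):
        ref = self.models()
        labels = {
            "t0": "Up common",
            "t1": "Up specific",
            "t2": "Up specific",
            "t3": "NS common",
            "t4": "NS common",
            "t5": "NS common",
        }
        se, ex, bg = build_sets(labels, ref)
        assert len(se) == 3 and len(ex) == 3 and len(bg) == 6
        assert not set(se) & set(ex)

    def test_representative_dropped_when_sibling_present(self):
        ref = self.models()  # t0 is g0.representative, t4 is g0.intron_retaining
        labels = {t.id: "Up common" for t in ref}
        labels["t5"] = "NS common"
        se, ex, _ = build_sets(labels, ref)
        assert "t0" not in se and "t4" in se

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(6)
        ref = self.models()
        options = ["Up common", "Up specific", "NS common", "Down common", "Up–NS switch"]
        for _ in range(20):
            labels = {t.id: str(rng.choice(options)) for t in ref}
            se, ex, bg = build_sets(labels, ref)
            naive_se = [t.id for t in ref if labels[t.id] in ("Up common", "Up specific")]
            naive_ex = [t.id for t in ref if labels[t.id] == "NS common"]
            for naive, got in ((naive_se, se), (naive_ex, ex)):
                ir_genes = {t.gene_id for t in ref if t.id in naive and t.kind == "intron_retaining"}
                expected = [
                    i
                    for i in naive
                    if not any(
                        t.id == i and t.kind == "representative" and t.gene_id in ir_genes
                        for t in ref
                    )
                ]
                assert got == expected
            assert bg == [t.id for t in ref]
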