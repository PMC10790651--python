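from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from scbacteria.analysis import (
    NEGATIVE,
    POSITIVE,
    attach_bacteria_metadata,
    bh_adjust,
    classify_cells,
    differential_expression,
    preranked_gsea,
    volcano_table,
)
from scbacteria.io import GeneSetCollection
from scbacteria.matrix import GenusCellMatrix


def annotations_from(counts: dict[str, dict[str, int]]) -> pd.DataFrame:
    frame = pd.DataFrame(counts).T.fillna(0).astype(int)
    frame["Total"] = frame.sum(axis=1)
    frame.index.name = "cell_id"
    return frame


class TestAttachMetadata:
    def test_missing_cell_gets_zero_row(self):
        m = GenusCellMatrix()
        m.add("s_c1", "Fusobacterium", "U1")
        ann = attach_bacteria_metadata(["s_c1", "s_c2"], m)
        assert ann.loc["s_c2"].sum() == 0
        assert ann.loc["s_c1", "Total"] == 1

    def test_total_is_row_sum(self):
        m = GenusCellMatrix()
        for u in range(5):
            m.add("s_c1", "Fusobacterium", f"U{u}")
        for u in range(2):
            m.add("s_c1", "Treponema", f"V{u}")
        ann = attach_bacteria_metadata(["s_c1"], m)
        assert ann.loc["s_c1", "Total"] == 7

    def test_zero_overlap_is_an_error(self):
        m = GenusCellMatrix()
        m.add("s_c1", "Fusobacterium", "U1")
        with pytest.raises(ValueError, match="overlap"):
            attach_bacteria_metadata(["other_c9"], m)

    def test_thousand_cell_join_equals_dict_join(self):
        rng = np.random.default_rng(51)
        m = GenusCellMatrix()
        genera = ["Fusobacterium", "Treponema", "Prevotella"]
        expected: dict[tuple[str, str], set] = {}
        for i in range(800):  # 800 matrix cells, 1000 expression cells
            cell = f"s_c{i}"
            for g in genera:
                n = int(rng.integers(0, 4))
                for u in range(n):
                    m.add(cell, g, f"U{u}")
                    expected.setdefault((cell, g), set()).add(f"U{u}")
        cells = [f"s_c{i}" for i in range(1000)]
        ann = attach_bacteria_metadata(cells, m)
        assert list(ann.index) == cells
        for cell in cells:
            for g in genera:
                assert ann.loc[cell, g] == len(expected.get((cell, g), ()))
            assert ann.loc[cell, "Total"] == sum(
                len(expected.get((cell, g), ())) for g in genera
            )


class TestClassifyCells:
    def test_threshold_four_grouping(self):
        ann = annotations_from(
            {"c1": {"Fusobacterium": 5}, "c2": {"Fusobacterium": 0},
             "c3": {"Fusobacterium": 2}}
        )
        labels = classify_cells(ann, taxon="Fusobacterium", pos_threshold=4)
        assert labels["c1"] == POSITIVE
        assert labels["c2"] == NEGATIVE
        assert labels["c3"] is pd.NA

    def test_threshold_one_on_total_leaves_no_na(self):
        ann = annotations_from(
            {f"c{i}": {"Fusobacterium": i % 4} for i in range(20)}
        )
        labels = classify_cells(ann, taxon="Total", pos_threshold=1)
        assert labels.notna().all()

    def test_matches_brute_force_predicate(self):
        rng = np.random.default_rng(52)
        ann = annotations_from(
            {
                f"c{i}": {
                    "Fusobacterium": int(rng.integers(0, 8)),
                    "Treponema": int(rng.integers(0, 3)),
                }
                for i in range(200)
            }
        )
        labels = classify_cells(ann, taxon="Fusobacterium", pos_threshold=4)
        for cell in ann.index:
            fuso, total = ann.loc[cell, "Fusobacterium"], ann.loc[cell, "Total"]
            if fuso >= 4:
                assert labels[cell] == POSITIVE
            elif total == 0:
                assert labels[cell] == NEGATIVE
            else:
                assert labels[cell] is pd.NA

    def test_threshold_below_one_rejected(self):
        ann = annotations_from({"c1": {"Fusobacterium": 1}})
        with pytest.raises(ValueError):
            classify_cells(ann, pos_threshold=0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        counts=st.lists(st.integers(min_value=0, max_value=10), min_size=1,
                        max_size=30),
        threshold=st.integers(min_value=1, max_value=9),
    )
    def test_raising_threshold_shrinks_positive_set(self, counts, threshold):
        ann = annotations_from(
            {f"c{i}": {"Fusobacterium": n} for i, n in enumerate(counts)}
        )
        lo = classify_cells(ann, taxon="Fusobacterium", pos_threshold=threshold)
        hi = classify_cells(ann, taxon="Fusobacterium", pos_threshold=threshold + 1)
        assert set(hi[hi == POSITIVE].index) <= set(lo[lo == POSITIVE].index)


def toy_expression(pos_values, neg_values, gene="G1"):
    """A genes x cells DataFrame with one informative gene plus a constant."""
    cells = [f"p{i}" for i in range(len(pos_values))] + [
        f"n{i}" for i in range(len(neg_values))
    ]
    frame = pd.DataFrame(
        {c: [v, 1.0] for c, v in zip(cells, list(pos_values) + list(neg_values))},
        index=[gene, "CONST"],
    )
    labels = pd.Series(
        [POSITIVE] * len(pos_values) + [NEGATIVE] * len(neg_values), index=cells
    )
    return frame, labels


class TestDifferentialExpression:
    def test_constant_gene_has_p_one_and_zero_lfc(self):
        frame, labels = toy_expression([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        de = differential_expression(frame, labels, min_pct=0.0)
        assert de.loc["CONST", "p_value"] == 1.0
        assert de.loc["CONST", "log2_fold_change"] == 0.0

    def test_three_vs_three_matches_exact_enumeration(self):
        """Wilcoxon p for a 3-vs-3 fixture equals the exact enumeration over
        all C(6,3) group assignments of the pooled values."""
        pos, neg = [1.2, 3.4, 2.2], [0.1, 0.5, 4.0]
        frame, labels = toy_expression(pos, neg)
        de = differential_expression(frame, labels, min_pct=0.0)

        pooled = np.array(pos + neg)
        ranks = rankdata(pooled)
        u_obs = ranks[:3].sum() - 3 * 4 / 2
        us = np.array(
            [sum(ranks[list(c)]) - 3 * 4 / 2 for c in combinations(range(6), 3)]
        )
        p_exact = min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
        assert de.loc["G1", "p_value"] == pytest.approx(p_exact, abs=1e-12)

    def test_log2fc_formula(self):
        pos, neg = [np.log1p(3.0)] * 3, [np.log1p(1.0)] * 3
        frame, labels = toy_expression(pos, neg)
        de = differential_expression(frame, labels, min_pct=0.0)
        assert de.loc["G1", "log2_fold_change"] == pytest.approx(np.log2(4 / 2))

    def test_min_pct_filters_untested_genes(self):
        frame, labels = toy_expression([0.0, 0.0, 0.0], [0.0, 0.0, 0.1])
        de = differential_expression(frame, labels, min_pct=0.5)
        assert "G1" not in de.index and "CONST" in de.index

    def test_small_group_rejected(self):
        frame, labels = toy_expression([1.0], [2.0, 3.0])
        with pytest.raises(ValueError, match=">=2 cells"):
            differential_expression(frame, labels)

    def test_invariant_to_cell_order_and_na_cells(self):
        rng = np.random.default_rng(53)
        cells = [f"c{i}" for i in range(30)]
        frame = pd.DataFrame(
            rng.poisson(3.0, size=(10, 30)).astype(float),
            index=[f"G{j}" for j in range(10)], columns=cells,
        )
        labels = pd.Series(
            [POSITIVE] * 10 + [NEGATIVE] * 10 + [pd.NA] * 10, index=cells
        )
        de1 = differential_expression(frame, labels, min_pct=0.0)
        shuffled = list(cells)
        rng.shuffle(shuffled)
        de2 = differential_expression(frame[shuffled], labels, min_pct=0.0)
        pd.testing.assert_frame_equal(de1, de2)
        # NA cells' expression is irrelevant
        frame.loc[:, labels.isna()] = 999.0
        de3 = differential_expression(frame, labels, min_pct=0.0)
        pd.testing.assert_frame_equal(de1, de3)

    def test_volcano_flags(self):
        de = pd.DataFrame(
            {
                "log2_fold_change": [1.0, 0.2, -0.9, 0.9],
                "p_value": [0.01, 0.001, 0.04, 0.2],
            },
            index=["A", "B", "C", "D"],
        )
        flagged = volcano_table(de)
        assert list(flagged["significant"]) == [True, False, True, False]


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.2] * 7) == pytest.approx([0.2] * 7)

    def test_matches_brute_force_step_up(self):
        rng = np.random.default_rng(54)
        for _ in range(10):
            p = rng.random(20)
            got = bh_adjust(p)
            # brute force: sort, scale by n/rank, cumulative min, clamp
            order = np.argsort(p)
            scaled = p[order] * len(p) / np.arange(1, len(p) + 1)
            stepped = np.minimum.accumulate(scaled[::-1])[::-1]
            expected = np.empty_like(p)
            expected[order] = np.minimum(stepped, 1.0)
            assert got == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.2, 1.5])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_adjusted_between_raw_and_one(self, p):
        adjusted = bh_adjust(p)
        assert np.all(adjusted >= np.asarray(p) - 1e-12)
        assert np.all(adjusted <= 1.0)


RANKING = pd.Series([3.0, 2.0, 1.0, -1.0, -2.0], index=list("ABCDE"))


class TestPrerankedGsea:
    def test_hand_enumerated_running_sum(self):
        """5-gene ranking, set {A, D}: running sum is
        +3/4, -1/3, -1/3, +1/4, -1/3 cumulatively."""
        sets = GeneSetCollection({"S": ["A", "D"]})
        (res,) = preranked_gsea(RANKING, sets, n_perm=200, seed=0)
        running = np.cumsum([3 / 4, -1 / 3, -1 / 3, 1 / 4, -1 / 3])
        assert res.enrichment_score == pytest.approx(running[np.abs(running).argmax()])
        assert res.enrichment_score == pytest.approx(0.75)
        assert res.leading_edge == ("A",)
        assert 0 < res.p_value <= 1

    def test_bottom_loaded_set_has_negative_es(self):
        sets = GeneSetCollection({"S": ["D", "E"]})
        (res,) = preranked_gsea(RANKING, sets, n_perm=100, seed=0)
        running = np.cumsum([-1 / 3, -1 / 3, -1 / 3, 1 / 3, 2 / 3])
        assert res.enrichment_score == pytest.approx(running[np.abs(running).argmax()])
        assert res.enrichment_score < 0
        assert set(res.leading_edge) == {"D", "E"}

    def test_reversed_ranking_negates_es(self):
        rng = np.random.default_rng(55)
        genes = [f"G{i}" for i in range(30)]
        ranking = pd.Series(rng.normal(size=30), index=genes)
        sets = GeneSetCollection(
            {f"S{k}": list(rng.choice(genes, size=6, replace=False))
             for k in range(5)}
        )
        fwd = preranked_gsea(ranking, sets, n_perm=10, seed=0)
        rev = preranked_gsea(-ranking, sets, n_perm=10, seed=0)
        for f, r in zip(fwd, rev):
            assert r.enrichment_score == pytest.approx(-f.enrichment_score)

    def test_set_of_all_ranked_genes(self):
        """With every gene a hit there are no miss steps: the running sum
        climbs monotonically to 1."""
        sets = GeneSetCollection({"ALL": list("ABCDE")})
        (res,) = preranked_gsea(RANKING, sets, n_perm=10, seed=0)
        assert res.enrichment_score == pytest.approx(1.0)

    def test_disjoint_set_reported_untestable(self):
        sets = GeneSetCollection({"S": ["ZZZ"], "OK": ["A"]})
        res = preranked_gsea(RANKING, sets, n_perm=10, seed=0)
        assert np.isnan(res[0].enrichment_score) and res[0].n_hits == 0
        assert res[1].n_hits == 1

    def test_es_invariant_to_genes_outside_ranking_and_set(self):
        sets = GeneSetCollection({"S": ["A", "D", "NOT_RANKED"]})
        (res,) = preranked_gsea(RANKING, sets, n_perm=50, seed=3)
        sets2 = GeneSetCollection({"S": ["A", "D"]})
        (res2,) = preranked_gsea(RANKING, sets2, n_perm=50, seed=3)
        assert res.enrichment_score == pytest.approx(res2.enrichment_score)

    def test_seeded_determinism(self):
        sets = GeneSetCollection({"S": ["A", "D"]})
        a = preranked_gsea(RANKING, sets, n_perm=100, seed=7)
        b = preranked_gsea(RANKING, sets, n_perm=100, seed=7)
        assert a == b

    def test_nonfinite_ranking_rejected(self):
        bad = pd.Series([1.0, np.nan], index=["A", "B"])
        with pytest.raises(ValueError):
            preranked_gsea(bad, GeneSetCollection({"S": ["A"]}), n_perm=5, seed=0)
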