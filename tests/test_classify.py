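import numpy as np
import pandas as pd
import pytest

from omicslink import (
    CorrClass,
    DomainError,
    classify_pair,
    classify_pairs,
    cluster_order,
    ratio_of_ratios,
    spearman,
    summarize_classes,
)
from _oracles import average_linkage_brute, rank_then_pearson


class TestClassifyPair:
    @pytest.mark.parametrize(
        "gene, prot, expected",
        [
            ("UP", "UP", CorrClass.SAME_TREND),
            ("DOWN", "DOWN", CorrClass.SAME_TREND),
            ("UP", "DOWN", CorrClass.OPPOSITE),
            ("DOWN", "UP", CorrClass.OPPOSITE),
            ("NOT_DE", "UP", CorrClass.DEP_ONLY),
            ("NOT_DE", "DOWN", CorrClass.DEP_ONLY),
            ("UP", "NOT_DE", CorrClass.DEG_ONLY),
            ("DOWN", "NOT_DE", CorrClass.DEG_ONLY),
            ("NOT_DE", "NOT_DE", CorrClass.NEITHER),
        ],
    )
    def test_truth_table(self, gene, prot, expected):
        assert classify_pair(gene, prot) is expected


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)

    def test_reversed(self):
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    @pytest.mark.parametrize("x, y", [([1.0], [2.0]), ([1, 1, 1], [1, 2, 3])])
    def test_degenerate_inputs_return_nan(self, x, y):
        assert np.isnan(spearman(x, y))

    def test_length_mismatch_raises(self):
        with pytest.raises(DomainError):
            spearman([1, 2], [1, 2, 3])

    def test_matches_midrank_pearson_oracle(self):
        """Agrees with an explicitly constructed rank-then-Pearson computation,
        including heavily tied vectors."""
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(3, 15))
            x = rng.integers(0, 5, n).astype(float)  # many ties
            y = rng.normal(size=n)
            if np.unique(x).size < 2:
                continue
            assert spearman(x, y) == pytest.approx(rank_then_pearson(x, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0.1, 10, 20)
        y = rng.normal(size=20)
        assert spearman(x, y) == pytest.approx(spearman(np.log(x), y), abs=1e-14)


class TestReferenceCorrelation:
    def test_same_trend_spearman(self, reference_table):
        r = spearman(reference_table["protein_ratio"], reference_table["gene_log2fc"])
        assert r == pytest.approx(0.9080, abs=1e-3)

    def test_rank_invariance_linear_vs_log_ratio(self, reference_table):
        """Linear and log2 protein ratios give the identical coefficient."""
        y = reference_table["gene_log2fc"]
        r_lin = spearman(reference_table["protein_ratio"], y)
        r_log = spearman(np.log2(reference_table["protein_ratio"]), y)
        assert r_lin == pytest.approx(r_log, abs=1e-14)

    def test_summary_counts_and_empty_class_sentinel(self, reference_result):
        s = reference_result.class_summary.set_index("corr_class")
        assert s.loc["SAME_TREND", "n"] == 15
        assert s.loc["SAME_TREND", "spearman"] == pytest.approx(0.9080, abs=1e-3)
        assert s.loc["OPPOSITE", "n"] == 0
        assert s.loc["OPPOSITE", "spearman"] == 0.0 and bool(s.loc["OPPOSITE", "degenerate"])
        # partition: class counts sum to the Quant count
        classes = s.drop(index="QUANT")
        assert classes["n"].sum() == s.loc["QUANT", "n"] == 15

    def test_summary_missing_feature_raises(self, reference_inputs):
        transcripts, proteins, hits = reference_inputs
        from omicslink import IntegrityError, run_pipeline

        res = run_pipeline(transcripts, proteins, hits)
        with pytest.raises(IntegrityError):
            summarize_classes(res.classified_pairs, transcripts.iloc[1:], proteins)


class TestRatioOfRatios:
    def test_single_pair(self):
        assert ratio_of_ratios(2.21, 2.28) == pytest.approx(2.03, abs=5e-3)

    def test_identity(self):
        assert ratio_of_ratios(0.0, 1.0) == 1.0

    def test_reference_extremes(self, reference_table):
        rr = ratio_of_ratios(reference_table["gene_log2fc"], reference_table["protein_ratio"])
        up = rr[(reference_table["direction"] == "Up").to_numpy()]
        down = rr[(reference_table["direction"] == "Down").to_numpy()]
        assert (round(up.min(), 2), round(up.max(), 3)) == (2.03, 9.348)
        assert (round(down.min(), 2), round(down.max(), 2)) == (0.08, 0.47)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(DomainError):
            ratio_of_ratios(1.0, 0.0)


class TestClusterOrder:
    def test_identical_rows_merge_at_distance_zero(self):
        order, linkage = cluster_order(np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]]))
        assert linkage[0, 2] == 0.0
        assert set(map(int, linkage[0, :2])) == {0, 1}

    def test_fewer_than_two_rows_warns(self):
        with pytest.warns(UserWarning):
            order, linkage = cluster_order(np.array([[1.0, 2.0]]))
        assert order == [0] and linkage is None

    def test_sign_groups_separate_on_reference(self, reference_table):
        mat = np.column_stack(
            [reference_table["gene_log2fc"], np.log2(reference_table["protein_ratio"])]
        )
        order, linkage = cluster_order(mat)
        up = set(np.flatnonzero((reference_table["direction"] == "Up").to_numpy()))
        ordered = [i in up for i in order]
        # all up rows contiguous, all down rows contiguous in leaf order
        assert sorted(ordered, reverse=ordered[0]) == ordered
        # the two sign groups are the root split
        n = len(mat)
        left = int(linkage[-1, 0])
        members = _subtree_leaves(linkage, n, left)
        assert members == up or members == set(range(n)) - up

    def test_linkage_matches_exhaustive_agglomeration(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.2], [5.0, 4.0]])
        _, linkage = cluster_order(pts)
        oracle = average_linkage_brute(pts)
        assert linkage[0, 2] == pytest.approx(oracle[0][2])
        assert linkage[1, 2] == pytest.approx(oracle[1][2])
        first = {tuple(sorted(oracle[0][0] + oracle[0][1]))}
        assert tuple(sorted(map(int, linkage[0, :2]))) in first

    def test_leaf_order_prefers_lower_original_index(self):
        pts = np.array([[0.0], [10.0], [0.1]])
        order, _ = cluster_order(pts)
        assert order[0] == 0  # 0 and 2 merge first; lower index leads


def _subtree_leaves(linkage, n, node):
    if node < n:
        return {node}
    a, b = linkage[int(node) - n, :2]
    return _subtree_leaves(linkage, n, int(a)) | _subtree_leaves(linkage, n, int(b))


class TestClassifyPairs:
    def test_attaches_statuses_and_classes(self):
        pairs = pd.DataFrame({"protein_id": ["P1", "P2"], "transcript_id": ["T1", "T2"]})
        gene = pd.Series(["UP", "NOT_DE"], index=pd.Index(["T1", "T2"], name="transcript_id"))
        prot = pd.Series(["UP", "DOWN"], index=pd.Index(["P1", "P2"], name="protein_id"))
        out = classify_pairs(pairs, gene, prot)
        assert out["corr_class"].tolist() == ["SAME_TREND", "DEP_ONLY"]

    def test_unknown_feature_raises(self):
        from omicslink import IntegrityError

        pairs = pd.DataFrame({"protein_id": ["P1"], "transcript_id": ["T-missing"]})
        gene = pd.Series(["UP"], index=pd.Index(["T1"], name="transcript_id"))
        prot = pd.Series(["UP"], index=pd.Index(["P1"], name="protein_id"))
        with pytest.raises(IntegrityError):
            classify_pairs(pairs, gene, prot)
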