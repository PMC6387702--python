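import numpy as np
import pandas as pd
import pytest

from omicslink import (
    ConfigError,
    DomainError,
    TermAnnotation,
    enrich_layer,
    hypergeom_upper_tail,
    joint_enrichment,
    read_gmt,
    tabulate_classes,
    write_gmt,
)
from omicslink.enrichment import read_namespace_map
from _oracles import hypergeom_pmf_enum, hypergeom_upper_tail_enum


class TestHypergeomUpperTail:
    def test_all_drawn_from_term(self):
        # drawing all 5 term members in 5 draws from 10: 1/C(10,5)
        assert hypergeom_upper_tail(10, 5, 5, 5) == pytest.approx(1 / 252, rel=1e-12)

    def test_k_zero_is_certain(self):
        for N, K, n in [(10, 3, 4), (50, 0, 10), (7, 7, 0)]:
            assert hypergeom_upper_tail(N, K, n, 0) == 1.0

    def test_matches_factorial_sum(self):
        assert hypergeom_upper_tail(20, 6, 7, 4) == pytest.approx(
            hypergeom_upper_tail_enum(20, 6, 7, 4), abs=1e-12
        )

    def test_matches_enumeration_on_small_universes(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        assert hypergeom_upper_tail(N, K, n, k) == pytest.approx(
                            hypergeom_upper_tail_enum(N, K, n, k), abs=1e-10
                        )

    def test_non_increasing_in_k(self):
        vals = [hypergeom_upper_tail(30, 10, 12, k) for k in range(11)]
        assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))

    def test_point_masses_sum_to_one(self):
        for N, K, n in [(15, 6, 9), (25, 10, 5), (8, 8, 3)]:
            total = sum(hypergeom_pmf_enum(N, K, n, k) for k in range(max(0, n + K - N), min(K, n) + 1))
            assert total == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("args", [(10, 11, 5, 0), (10, 5, 11, 0), (10, 5, 5, 6), (-1, 0, 0, 0)])
    def test_inconsistent_counts_rejected(self, args):
        with pytest.raises(DomainError):
            hypergeom_upper_tail(*args)


def _annotation(**terms):
    return {
        tid: TermAnnotation(tid, f"name {tid}", frozenset(members), ns)
        for tid, (members, ns) in terms.items()
    }


class TestEnrichLayer:
    def test_term_covering_differential_set_is_significant(self):
        universe = [f"g{i}" for i in range(10)]
        diff = ["g0", "g1", "g2"]
        ann = _annotation(T1=(diff, "KEGG"), T2=(["g7", "g8", "g9"], "KEGG"))
        out = enrich_layer(diff, universe, ann, universe="quantified").set_index("term_id")
        assert out.loc["T1", "k"] == 3
        assert out.loc["T1", "pvalue"] == pytest.approx(hypergeom_upper_tail_enum(10, 3, 3, 3), abs=1e-12)
        assert bool(out.loc["T1", "significant"]) and not bool(out.loc["T2", "significant"])

    def test_empty_differential_set_gives_all_ones(self):
        universe = [f"g{i}" for i in range(6)]
        ann = _annotation(T1=(["g0", "g1"], "KEGG"))
        out = enrich_layer([], universe, ann, universe="quantified")
        assert (out["pvalue"] == 1.0).all() and not out["significant"].any()

    def test_annotated_universe_restricts_background(self):
        universe = [f"g{i}" for i in range(100)]
        ann = _annotation(T1=(["g0", "g1", "g2", "g3"], "KEGG"))
        out = enrich_layer(["g0", "g1"], universe, ann, universe="annotated")
        assert out.loc[0, "N"] == 4 and out.loc[0, "n"] == 2

    def test_membership_intersected_with_universe(self):
        ann = _annotation(T1=(["g0", "nonquantified"], "KEGG"))
        out = enrich_layer(["g0"], ["g0", "g1"], ann, universe="quantified")
        assert out.loc[0, "K"] == 1

    def test_empty_universe_rejected(self):
        with pytest.raises(ConfigError):
            enrich_layer([], [], _annotation(T1=(["g0"], "KEGG")))

    def test_differential_must_be_subset_of_universe(self):
        with pytest.raises(ConfigError):
            enrich_layer(["x"], ["g0"], _annotation(T1=(["g0"], "KEGG")), universe="quantified")

    def test_strict_alpha(self):
        """Significance is p < alpha, not <=."""
        universe = ["g0", "g1"]
        ann = _annotation(T1=(["g0"], "KEGG"))
        out = enrich_layer(["g0"], universe, ann, alpha=0.5, universe="quantified")
        assert out.loc[0, "pvalue"] == pytest.approx(0.5)
        assert not bool(out.loc[0, "significant"])

    def test_bh_flag_adds_adjusted_column(self):
        universe = [f"g{i}" for i in range(20)]
        ann = _annotation(**{f"T{j}": ([f"g{j}"], "KEGG") for j in range(5)})
        out = enrich_layer(["g0"], universe, ann, bh=True, universe="quantified")
        assert "pvalue_bh" in out.columns
        assert (out["pvalue_bh"] >= out["pvalue"] - 1e-15).all()


class TestJointEnrichment:
    def _layer(self, rows):
        df = pd.DataFrame(rows, columns=["term_id", "k", "K", "pvalue"])
        df["significant"] = df["pvalue"] < 0.05
        return df

    @pytest.mark.parametrize(
        "p_prot, p_gene, expected",
        [
            (0.0065, 0.0126, True),
            (0.0007, 0.0126, True),
            (0.01, 0.2, False),
            (0.2, 0.01, False),
        ],
    )
    def test_conjunction_rule(self, p_prot, p_gene, expected):
        prot = self._layer([("T1", 2, 5, p_prot)])
        gene = self._layer([("T1", 3, 8, p_gene)])
        pairs = pd.DataFrame(columns=["protein_id", "transcript_id", "corr_class"])
        ann = _annotation(T1=(["x"], "KEGG"))
        out = joint_enrichment(prot, gene, pairs, ann)
        assert bool(out.loc[0, "jointly_significant"]) is expected
        # P-values pass through untouched
        assert out.loc[0, "p_prot"] == p_prot and out.loc[0, "p_gene"] == p_gene

    def test_correlation_counting(self):
        prot = self._layer([("T1", 1, 2, 0.01)])
        gene = self._layer([("T1", 1, 2, 0.01)])
        pairs = pd.DataFrame(
            {
                "protein_id": ["P1", "P2", "P3"],
                "transcript_id": ["G1", "G2", "G3"],
                "corr_class": ["SAME_TREND", "SAME_TREND", "OPPOSITE"],
            }
        )
        # P1/G1 fully inside the term; P2 inside but G2 outside; P3 same-trend? no
        ann = _annotation(T1=(["P1", "G1", "P2", "P3", "G3"], "KEGG"))
        out = joint_enrichment(prot, gene, pairs, ann)
        assert out.loc[0, "n_correlations"] == 1


class TestTabulateClasses:
    def test_percentages_use_annotated_denominator(self):
        members = [f"m{i}" for i in range(13)] + ["unannotated1", "unannotated2"]
        ann = _annotation(
            C1=([f"m{i}" for i in range(3)], "COG"),
            C2=([f"m{i}" for i in range(3, 8)], "COG"),
            C3=([f"m{i}" for i in range(8, 13)], "COG"),
        )
        out = tabulate_classes(members, ann, "COG").set_index("term_id")
        assert out.loc["C1", "count"] == 3
        assert out.loc["C1", "percentage"] == pytest.approx(23.08, abs=0.005)
        assert out.loc["C2", "percentage"] == pytest.approx(38.46, abs=0.005)

    def test_empty_member_set(self):
        ann = _annotation(C1=(["m0"], "COG"))
        assert len(tabulate_classes([], ann, "COG")) == 0

    def test_namespace_filtering(self):
        ann = _annotation(C1=(["m0"], "COG"), K1=(["m0"], "KEGG"))
        out = tabulate_classes(["m0"], ann, "KEGG")
        assert out["term_id"].tolist() == ["K1"]


class TestGmtIO:
    def test_round_trip(self, tmp_path):
        ann = _annotation(T1=(["a", "b"], "KEGG"), T2=(["c"], "KEGG"))
        path = tmp_path / "terms.gmt"
        write_gmt(ann, path)
        back = read_gmt(path)
        assert back.keys() == ann.keys()
        for tid in ann:
            assert back[tid].members == ann[tid].members

    def test_namespace_map_applied(self, tmp_path):
        gmt = tmp_path / "terms.gmt"
        gmt.write_text("T1\tdesc\ta\tb\nT2\tdesc\tc\n")
        nsmap = tmp_path / "ns.tsv"
        nsmap.write_text("T1\tGO_BP\n")
        terms = read_gmt(gmt, namespace_map=read_namespace_map(nsmap), default_namespace="KEGG")
        assert terms["T1"].namespace == "GO_BP" and terms["T2"].namespace == "KEGG"

    def test_short_line_rejected(self, tmp_path):
        gmt = tmp_path / "bad.gmt"
        gmt.write_text("loneterm\n")
        with pytest.raises(ConfigError):
            read_gmt(gmt)
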