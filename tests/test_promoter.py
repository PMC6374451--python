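import numpy as np
import pandas as pd
import pytest

from gcimp.io import BetaMatrix, SampleSheet
from gcimp.promoter import (
    per_probe_promoter_scan,
    promoter_probe_sets,
    select_top_probes,
    starburst_classify,
    summarize_promoter,
    top_fraction_count,
)


def test_promoter_probe_sets_multi_mapping(toy_annotation):
    sets = promoter_probe_sets(toy_annotation)
    assert sets["GENE1"] == ["cg0", "cg1"]
    assert sets["GENE2"] == ["cg1", "cg2"]  # cg1 serves both genes
    assert sets["GENE3"] == ["cg4"]


def test_non_promoter_feature_excluded(toy_annotation):
    sets = promoter_probe_sets(toy_annotation)
    assert all("cg3" not in probes for probes in sets.values())  # no features


def test_grouping_matches_brute_force(toy_annotation):
    sets = promoter_probe_sets(toy_annotation)
    expected = {}
    for probe, pairs in toy_annotation.promoter_map().items():
        for _f, gene in pairs:
            expected.setdefault(gene, set()).add(probe)
    assert {g: set(p) for g, p in sets.items()} == {
        g: set(p) for g, p in expected.items()
    }


@pytest.mark.parametrize("n,expected", [(8, 2), (5, 2), (4, 1), (1, 1), (2, 1)])
def test_top_quarter_count(n, expected):
    assert top_fraction_count(n, 0.25) == expected


def test_select_top_probes_tie_break():
    diff = pd.Series({"cgB": 0.5, "cgA": 0.5, "cgC": 0.1, "cgD": 0.0, "cgE": 0.0})
    assert select_top_probes(diff, 0.25) == ["cgA", "cgB"]  # ceil(1.25)=2


class TestSummarize:
    @pytest.fixture()
    def toy(self):
        # 5 promoter probes, 2+2 samples; per-probe |diff| 0.5, 0.4, 0.1, 0.05, 0
        samples = ["r1", "r2", "c1", "c2"]
        values = pd.DataFrame(
            [
                [0.90, 0.90, 0.40, 0.40],  # diff -0.5
                [0.80, 0.80, 0.40, 0.40],  # diff -0.4
                [0.50, 0.50, 0.40, 0.40],  # diff -0.1
                [0.45, 0.45, 0.40, 0.40],  # diff -0.05
                [0.40, 0.40, 0.40, 0.40],  # diff 0
            ],
            index=[f"p{i}" for i in range(5)],
            columns=samples,
        )
        beta = BetaMatrix(values)
        sheet = SampleSheet(
            pd.DataFrame(
                {"group_label": ["ref", "ref", "cmp", "cmp"]},
                index=pd.Index(samples, name="sample_id"),
            )
        )
        return beta, sheet

    def test_hand_computed_selection_and_delta(self, toy):
        beta, sheet = toy
        out = summarize_promoter(
            beta, sheet, {"G": [f"p{i}" for i in range(5)]}, "ref", "cmp"
        )
        assert out.loc["G", "selected_probes"] == "p0;p1"
        # per-sample score = mean of p0,p1: ref (0.85, 0.85), cmp (0.40, 0.40)
        assert out.loc["G", "promoter_delta"] == pytest.approx(-0.45)

    def test_single_probe_promoter_degenerate(self, toy):
        beta, sheet = toy
        out = summarize_promoter(beta, sheet, {"G": ["p2"]}, "ref", "cmp")
        assert out.loc["G", "selected_probes"] == "p2"
        assert out.loc["G", "promoter_delta"] == pytest.approx(-0.1)

    def test_invariant_to_probe_input_order(self, toy):
        beta, sheet = toy
        a = summarize_promoter(
            beta, sheet, {"G": ["p0", "p1", "p2", "p3", "p4"]}, "ref", "cmp"
        )
        b = summarize_promoter(
            beta, sheet, {"G": ["p4", "p2", "p0", "p3", "p1"]}, "ref", "cmp"
        )
        pd.testing.assert_frame_equal(a, b)


class TestStarburst:
    def make_inputs(self, promoter_q, delta=-0.3, fc=3.0, expr_q=0.01):
        promoters = pd.DataFrame(
            {"promoter_delta": [delta], "promoter_q": [promoter_q]},
            index=pd.Index(["G"], name="gene"),
        )
        expression = pd.DataFrame(
            {
                "fold_change": [fc],
                "log2_fc": [np.log2(fc)],
                "q": [expr_q],
            },
            index=pd.Index(["G"], name="gene_id"),
        )
        return promoters, expression

    def test_all_criteria_met(self):
        prom, expr = self.make_inputs(promoter_q=0.01)
        out = starburst_classify(prom, expr)
        assert out.loc["G", "category"] == "up_with_demethylation"

    def test_promoter_q_gate(self):
        prom, expr = self.make_inputs(promoter_q=0.2)
        out = starburst_classify(prom, expr)
        assert out.loc["G", "category"] == "other"

    def test_down_with_hypermethylation_symmetric(self):
        prom, expr = self.make_inputs(promoter_q=0.01, delta=0.3, fc=0.25)
        out = starburst_classify(prom, expr)
        assert out.loc["G", "category"] == "down_with_hypermethylation"


def test_per_probe_scan_brute_force():
    dm = pd.DataFrame(
        {
            "q": [0.01, 0.01, 0.2, 0.01, 0.01],
            "delta": [-0.5, -0.3, -0.5, -0.1, 0.4],
        },
        index=pd.Index([f"p{i}" for i in range(5)], name="probe_id"),
    )
    gene_probes = {"G1": ["p0", "p1", "p2", "p3", "p4"], "G2": ["p3"]}
    flagged = per_probe_promoter_scan(["G1", "G2"], dm, gene_probes)
    assert flagged == {"G1": ["p0", "p1"]}  # p2 fails q, p3 fails delta, p4 hyper
    # monotonicity: relaxing delta_min can only grow the lists
    relaxed = per_probe_promoter_scan(["G1", "G2"], dm, gene_probes, delta_min=0.0)
    for gene, probes in flagged.items():
        assert set(probes) <= set(relaxed.get(gene, []))


def test_starburst_detected_genes_subset_of_per_probe_scan(default_cohort):
    from gcimp import diffmeth, expression as expr_mod
    from gcimp.promoter import promoter_probe_sets

    beta, annotation, _track, expr, sheet, truth = default_cohort
    gene_probes = promoter_probe_sets(annotation)
    dm = diffmeth.classify_probes(
        diffmeth.differential_methylation(beta, sheet, "gcimp_high", "gcimp_demeth")
    )
    de = expr_mod.de_test(expr, sheet, "gcimp_high", "gcimp_demeth")
    promoters = summarize_promoter(
        beta, sheet, gene_probes, "gcimp_high", "gcimp_demeth"
    )
    sb = starburst_classify(promoters, de)
    sb_up = set(sb.index[sb["category"] == "up_with_demethylation"])
    scan = per_probe_promoter_scan(
        de.index[de["label"] == "up"], dm, gene_probes
    )
    assert sb_up <= set(scan)
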