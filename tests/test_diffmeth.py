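import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from gcimp.diffmeth import (
    bh_adjust,
    classify_probes,
    cpg_context_breakdown,
    differential_methylation,
    welch_test,
)


def hand_welch(ref, cmp_):
    """Textbook Welch formulas, independent of the implementation path."""
    ref, cmp_ = np.asarray(ref, float), np.asarray(cmp_, float)
    m1, m2 = ref.mean(), cmp_.mean()
    v1, v2 = ref.var(ddof=1), cmp_.var(ddof=1)
    n1, n2 = len(ref), len(cmp_)
    se2 = v1 / n1 + v2 / n2
    t = (m2 - m1) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return m2 - m1, t, df, p


class TestWelch:
    def test_identical_groups_give_zero_t_unit_p(self):
        delta, t, df, p = welch_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert delta == 0
        assert t == 0
        assert p == 1

    def test_matches_textbook_formula(self):
        ref = [0.80, 0.82, 0.78, 0.81]
        cmp_ = [0.40, 0.45, 0.38, 0.43]
        delta, t, df, p = welch_test(ref, cmp_)
        e_delta, e_t, e_df, e_p = hand_welch(ref, cmp_)
        assert delta == pytest.approx(-0.3875, abs=1e-12)
        assert t == pytest.approx(e_t, rel=1e-12)
        assert df == pytest.approx(e_df, rel=1e-12)
        assert p == pytest.approx(e_p, rel=1e-12)

    def test_swapping_groups_negates_delta_and_t(self):
        ref = [0.8, 0.82, 0.78, 0.81]
        cmp_ = [0.40, 0.45, 0.38, 0.43]
        d1, t1, df1, p1 = welch_test(ref, cmp_)
        d2, t2, df2, p2 = welch_test(cmp_, ref)
        assert d2 == pytest.approx(-d1)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)
        assert df2 == pytest.approx(df1)

    def test_insufficient_data_flagged_not_dropped(self):
        delta, t, df, p = welch_test([0.5], [0.3, 0.4, 0.5])
        assert np.isnan(p) and np.isnan(t)
        assert delta == pytest.approx(0.4 - 0.5)

    def test_missing_values_excluded(self):
        full = welch_test([0.1, 0.2, 0.3], [0.5, 0.6, 0.7])
        with_nan = welch_test([0.1, 0.2, 0.3, np.nan], [0.5, np.nan, 0.6, 0.7])
        assert with_nan == pytest.approx(full)


class TestBH:
    def test_single_p(self):
        assert bh_adjust([0.02]).tolist() == [0.02]

    def test_hand_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert q.tolist() == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_missing_passthrough(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        # m=2 non-missing
        assert q[0] == pytest.approx(0.02)
        assert q[2] == pytest.approx(0.04)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=60,
        )
    )
    def test_matches_statsmodels_and_is_monotone(self, pvals):
        from statsmodels.stats.multitest import multipletests

        q = bh_adjust(pvals)
        expected = multipletests(pvals, method="fdr_bh")[1]
        assert q == pytest.approx(expected, rel=1e-12, abs=1e-12)
        order = np.argsort(pvals, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q >= np.asarray(pvals) - 1e-15).all()


class TestClassification:
    @pytest.mark.parametrize(
        "q,delta,delta_min,expected",
        [
            (0.01, -0.25, 0.2, "hypo"),
            (0.01, -0.25, 0.4, "ns"),
            (0.2, -0.9, 0.2, "ns"),
            (0.01, 0.25, 0.2, "hyper"),
            (np.nan, -0.9, 0.2, "ns"),
        ],
    )
    def test_threshold_gates(self, q, delta, delta_min, expected):
        df = pd.DataFrame({"q": [q], "delta": [delta]}, index=["cg0"])
        out = classify_probes(df, q_max=0.05, delta_min=delta_min)
        assert out["label"].iloc[0] == expected

    def test_labels_partition_testable_probes(self, toy_beta, toy_sheet):
        res = differential_methylation(toy_beta, toy_sheet, "ref", "cmp")
        labeled = classify_probes(res)
        assert set(labeled["label"]) <= {"hypo", "hyper", "ns"}
        assert len(labeled) == toy_beta.n_probes


def test_differential_methylation_orientation(toy_beta, toy_sheet):
    res = differential_methylation(toy_beta, toy_sheet, "ref", "cmp")
    # cg0: comparison mean 0.415, reference mean 0.8025
    assert res.loc["cg0", "delta"] == pytest.approx(-0.3875)
    assert (res["q"] >= res["p"] - 1e-15).all()


def test_context_breakdown_tally(toy_beta, toy_sheet, toy_annotation):
    res = classify_probes(differential_methylation(toy_beta, toy_sheet, "ref", "cmp"))
    out = cpg_context_breakdown(res, toy_annotation)
    # brute-force tally
    ctx = toy_annotation.table["cpg_context"]
    for label in ("hypo", "hyper", "ns"):
        for context in ("Island", "Shore", "Shelf", "OpenSea"):
            expected = int(
                ((res["label"] == label) & (ctx.loc[res.index] == context)).sum()
            )
            assert out.loc[label, context] == expected


def test_context_breakdown_missing_probe_errors(toy_beta, toy_sheet, toy_annotation):
    res = classify_probes(differential_methylation(toy_beta, toy_sheet, "ref", "cmp"))
    res = pd.concat(
        [res, res.iloc[[0]].rename(index={"cg0": "cg_unknown"})]
    )
    with pytest.raises(KeyError, match="cg_unknown"):
        cpg_context_breakdown(res, toy_annotation)
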