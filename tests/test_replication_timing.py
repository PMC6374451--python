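import numpy as np
import pandas as pd
import pytest

from gcimp.io import ProbeAnnotationTable, ReplicationTimingTrack
from gcimp.replication_timing import (
    RTThresholds,
    annotate_and_categorize,
    annotate_probes_rt,
    categorize_rt,
    compute_rt_thresholds,
    rt_enrichment_test,
)


def make_annotation(chroms, positions):
    df = pd.DataFrame(
        {
            "chromosome": chroms,
            "position": positions,
            "cpg_context": "OpenSea",
            "promoter_features": "",
            "snp_within_5bp": False,
            "sex_chromosome": False,
        },
        index=pd.Index([f"cg{i}" for i in range(len(positions))], name="probe_id"),
    )
    return ProbeAnnotationTable(df)


def make_track(rows):
    return ReplicationTimingTrack(
        pd.DataFrame(rows, columns=["chromosome", "start", "end", "rt_value"])
    )


class TestAnnotation:
    def test_containment(self):
        track = make_track([("chr1", 0, 1000, -1.2)])
        ann = make_annotation(["chr1"], [500])
        out = annotate_probes_rt(ann, track)
        assert out.loc["cg0", "rt_value"] == -1.2

    def test_half_open_boundary(self):
        # 1-based position 1000 -> 0-based 999 in [0,1000); 1001 -> 1000 in [1000,2000)
        track = make_track([("chr1", 0, 1000, -1.0), ("chr1", 1000, 2000, 1.0)])
        ann = make_annotation(["chr1", "chr1"], [1000, 1001])
        out = annotate_probes_rt(ann, track)
        assert out["rt_value"].tolist() == [-1.0, 1.0]

    def test_gap_gives_missing(self):
        track = make_track([("chr1", 0, 1000, -1.0), ("chr1", 5000, 6000, 1.0)])
        ann = make_annotation(["chr1", "chr2"], [2000, 100])
        out = annotate_probes_rt(ann, track)
        assert out["rt_value"].isna().all()

    def test_matches_brute_force_linear_scan(self):
        rng = np.random.default_rng(7)
        intervals = [("chr1", s, s + 500, float(v))
                     for s, v in zip(range(0, 10000, 1000), rng.normal(size=10))]
        track = make_track(intervals)
        positions = rng.integers(1, 10000, size=20).tolist()
        ann = make_annotation(["chr1"] * 20, positions)
        out = annotate_probes_rt(ann, track)
        for probe, pos in zip(ann.probe_ids, positions):
            expected = np.nan
            for chrom, s, e, v in intervals:
                if s <= pos - 1 < e:
                    expected = v
            got = out.loc[probe, "rt_value"]
            assert (np.isnan(expected) and np.isnan(got)) or got == expected

    def test_two_tracks_are_averaged(self):
        t1 = make_track([("chr1", 0, 1000, -1.0)])
        t2 = make_track([("chr1", 0, 1000, -0.5)])
        ann = make_annotation(["chr1"], [10])
        out = annotate_probes_rt(ann, [t1, t2])
        assert out.loc["cg0", "rt_value"] == pytest.approx(-0.75)


class TestThresholds:
    def test_two_point_medians(self):
        thr = compute_rt_thresholds([-2, -1, 1, 2])
        assert (thr.late_cut, thr.early_cut) == (-1.5, 1.5)

    def test_matches_sort_oracle_and_excludes_zero(self):
        rng = np.random.default_rng(11)
        v = np.round(rng.normal(size=1001), 3)
        v[::50] = 0.0
        thr = compute_rt_thresholds(v)
        neg = np.sort(v[v < 0])
        pos = np.sort(v[v > 0])

        def mid(x):
            n = len(x)
            return x[n // 2] if n % 2 else (x[n // 2 - 1] + x[n // 2]) / 2

        assert thr.late_cut == pytest.approx(mid(neg), rel=1e-12)
        assert thr.early_cut == pytest.approx(mid(pos), rel=1e-12)

    def test_requires_both_signs(self):
        with pytest.raises(ValueError):
            compute_rt_thresholds([0.5, 1.0])


class TestCategorize:
    THR = RTThresholds(late_cut=-0.4599, early_cut=0.80074)

    @pytest.mark.parametrize(
        "value,expected",
        [
            (-0.4599, "late"),  # boundary inclusive on the late side
            (-0.46, "late"),
            (-0.4598, "intermediate"),
            (0.80074, "intermediate"),  # boundary inclusive on the intermediate side
            (0.80075, "early"),
            (np.nan, "unassigned"),
        ],
    )
    def test_printed_inequalities(self, value, expected):
        assert categorize_rt([value], self.THR)[0] == expected


class TestEnrichment:
    def make_rt_df(self, categories):
        return pd.DataFrame(
            {"rt_value": 0.0, "rt_category": categories},
            index=pd.Index([f"cg{i}" for i in range(len(categories))],
                           name="probe_id"),
        )

    def test_identical_proportions_give_null(self):
        cats = ["late"] * 10 + ["early"] * 10
        rt = self.make_rt_df(cats)
        demeth = [f"cg{i}" for i in range(5)] + [f"cg{i}" for i in range(10, 15)]
        res = rt_enrichment_test(demeth, rt, mode="complement")
        assert res.chi_square_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_2x2_closed_form(self):
        # demethylated: 80 late / 20 early; others: 50 late / 50 early
        cats = ["late"] * 130 + ["early"] * 70
        rt = self.make_rt_df(cats)
        demeth = [f"cg{i}" for i in range(80)] + [f"cg{i}" for i in range(130, 150)]
        res = rt_enrichment_test(demeth, rt, mode="complement")
        assert res.odds_ratio_late == 4.0  # exact arithmetic (80*50)/(20*50)
        n = 200
        a, b, c, d = 80, 20, 50, 50
        expected_chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res.chi_square_stat == pytest.approx(expected_chi2, rel=1e-12)

    def test_complement_columns_partition_probes(self):
        cats = ["late"] * 50 + ["intermediate"] * 30 + ["early"] * 20
        rt = self.make_rt_df(cats)
        demeth = [f"cg{i}" for i in range(40)]
        res = rt_enrichment_test(demeth, rt, mode="complement")
        assert res.table.to_numpy().sum() == 100

    def test_invariant_to_table_permutation(self):
        cats = ["late"] * 60 + ["intermediate"] * 80 + ["early"] * 60
        rt = self.make_rt_df(cats)
        demeth = [f"cg{i}" for i in range(50)]
        res = rt_enrichment_test(demeth, rt, mode="complement")
        from scipy.stats import chi2_contingency

        permuted = res.table.iloc[::-1, ::-1].to_numpy()
        chi2_perm = chi2_contingency(permuted, correction=False)[0]
        assert res.chi_square_stat == pytest.approx(chi2_perm, rel=1e-12)

    def test_unknown_demeth_probe_errors(self):
        rt = self.make_rt_df(["late", "early"])
        with pytest.raises(KeyError):
            rt_enrichment_test(["cg_missing"], rt)


def test_synthetic_track_thresholds_equal_level_medians(default_cohort):
    beta, annotation, track, *_ = default_cohort
    rt, thresholds = annotate_and_categorize(annotation, track)
    assert thresholds.late_cut == -1.0
    assert thresholds.early_cut == 1.0
    # with a two-level track the early-level probes sit exactly at the early
    # cut and are categorized intermediate by the inclusive bound
    assert set(rt["rt_category"]) <= {"late", "intermediate"}
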