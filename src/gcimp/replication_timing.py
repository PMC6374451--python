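"""Replication-timing annotation of probes and late-domain enrichment testing.

Probes are assigned the signed replication-timing (RT) value of the track
interval covering their position, categorized as late / intermediate / early
by median-based thresholds (late iff rt <= late_cut; intermediate iff
late_cut < rt <= early_cut; early iff rt > early_cut, where late_cut is the
median of the negative values and early_cut the median of the positive
values), and the demethylated probe set is tested for enrichment in late
domains with a Pearson chi-square test.

Two comparator conventions exist for the 3x2 table: ``mode="all"`` compares
the demethylated set against *all* annotated probes (the convention used in
published volcano-plot analyses, columns overlap), ``mode="complement"``
against the non-demethylated probes (columns disjoint, satisfying the
chi-square independence assumption). The late-membership odds ratio is always
computed on the complement 2x2 table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ProbeAnnotationTable, ReplicationTimingTrack

logger = logging.getLogger(__name__)

RT_CATEGORIES = ("late", "intermediate", "early")


@dataclass(frozen=True)
class RTThresholds:
    late_cut: float
    early_cut: float

    def __post_init__(self) -> None:
        if not self.late_cut < self.early_cut:
            raise ValueError(
                f"late_cut ({self.late_cut}) must be < early_cut ({self.early_cut})"
            )


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # RT category x {demethylated, comparator}
    chi_square_stat: float
    df: int
    p: float
    residuals: pd.DataFrame  # standardized (Pearson) residuals
    odds_ratio_late: float
    mode: str


def annotate_probes_rt(
    annotation: ProbeAnnotationTable,
    tracks: ReplicationTimingTrack | Sequence[ReplicationTimingTrack],
) -> pd.DataFrame:
    """Per-probe RT value; NaN for probes in track gaps.

    Several replicate tracks (e.g. two Repli-seq profiles of the same cell
    type) may be given; their values at each probe are averaged over the
    tracks that cover it.
    """
    if isinstance(tracks, ReplicationTimingTrack):
        tracks = [tracks]
    t = annotation.table
    chroms = t["chromosome"].to_numpy(dtype=object)
    pos = t["position"].to_numpy()
    stacked = np.vstack([tr.values_at(chroms, pos) for tr in tracks])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-NaN columns are legitimate gaps
        rt = np.nanmean(stacked, axis=0)
    track_chroms = set().union(*(set(tr._index) for tr in tracks))
    absent = set(map(str, pd.unique(chroms))) - track_chroms
    if absent:
        logger.warning("chromosomes absent from RT track: %s", sorted(absent))
    return pd.DataFrame({"rt_value": rt}, index=t.index.rename("probe_id"))


def compute_rt_thresholds(rt_values) -> RTThresholds:
    """Median of the strictly negative and strictly positive RT values.

    Zeros belong to neither sign and are excluded from both medians; even-
    length medians are midpoints of the central pair (numpy convention).
    """
    v = np.asarray(rt_values, dtype=float)
    v = v[~np.isnan(v)]
    neg = v[v < 0]
    pos = v[v > 0]
    if neg.size == 0 or pos.size == 0:
        raise ValueError("need at least one negative and one positive RT value")
    return RTThresholds(float(np.median(neg)), float(np.median(pos)))


def categorize_rt(rt_values, thresholds: RTThresholds) -> np.ndarray:
    """late / intermediate / early by inclusive-upper-bound thresholds;
    ``unassigned`` where the RT value is missing."""
    v = np.asarray(rt_values, dtype=float)
    out = np.where(
        np.isnan(v),
        "unassigned",
        np.where(
            v <= thresholds.late_cut,
            "late",
            np.where(v <= thresholds.early_cut, "intermediate", "early"),
        ),
    )
    return out


def annotate_and_categorize(
    annotation: ProbeAnnotationTable,
    tracks: ReplicationTimingTrack | Sequence[ReplicationTimingTrack],
    thresholds: RTThresholds | None = None,
) -> tuple[pd.DataFrame, RTThresholds]:
    """Convenience: annotate, derive thresholds from the annotated values
    (unless given), and categorize. Returns (rt table, thresholds)."""
    rt = annotate_probes_rt(annotation, tracks)
    if thresholds is None:
        thresholds = compute_rt_thresholds(rt["rt_value"])
    rt["rt_category"] = categorize_rt(rt["rt_value"], thresholds)
    return rt, thresholds


def rt_enrichment_test(
    demeth_probe_ids: Iterable[str],
    rt_annotations: pd.DataFrame,
    mode: str = "all",
) -> EnrichmentResult:
    """Chi-square test of RT-category distribution, demethylated vs comparator.

    ``rt_annotations`` must carry an ``rt_category`` column; unassigned probes
    are excluded. Zero-margin rows are dropped (df recomputed, warning
    logged). No continuity correction.
    """
    if mode not in ("all", "complement"):
        raise ValueError(f"mode must be 'all' or 'complement', got {mode!r}")
    ann = rt_annotations[rt_annotations["rt_category"] != "unassigned"]
    demeth = set(map(str, demeth_probe_ids))
    stray = demeth - set(map(str, ann.index))
    if stray:
        raise KeyError(f"demethylated probes without RT category: {sorted(stray)[:5]}")
    is_demeth = ann.index.astype(str).isin(demeth)
    cat = ann["rt_category"]

    demeth_counts = cat[is_demeth].value_counts()
    other_counts = cat[~is_demeth].value_counts()
    all_counts = cat.value_counts()
    comparator = all_counts if mode == "all" else other_counts
    comparator_name = "all_probes" if mode == "all" else "other_probes"
    table = pd.DataFrame(
        {
            "demethylated": demeth_counts.reindex(RT_CATEGORIES, fill_value=0),
            comparator_name: comparator.reindex(RT_CATEGORIES, fill_value=0),
        }
    ).astype(int)
    table.index.name = "rt_category"

    test_table = table[table.sum(axis=1) > 0]
    if test_table.shape[0] < table.shape[0]:
        logger.warning(
            "dropped zero-margin RT rows: %s",
            sorted(set(table.index) - set(test_table.index)),
        )
    if test_table.shape[0] < 2 or (test_table.sum(axis=0) == 0).any():
        # degenerate table (e.g. empty demethylated set): test undefined
        logger.warning("degenerate RT contingency table; chi-square undefined")
        chi2, p, dof = np.nan, np.nan, 0
        residuals = test_table.astype(float) * np.nan
    else:
        chi2, p, dof, expected = stats.chi2_contingency(
            test_table.to_numpy(), correction=False
        )
        resid = (test_table.to_numpy() - expected) / np.sqrt(expected)
        residuals = pd.DataFrame(
            resid, index=test_table.index, columns=test_table.columns
        )

    # odds ratio of late membership, always on the disjoint complement table
    a = int(demeth_counts.get("late", 0))
    b = int(demeth_counts.drop("late", errors="ignore").sum())
    c = int(other_counts.get("late", 0))
    d = int(other_counts.drop("late", errors="ignore").sum())
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(
        table=table,
        chi_square_stat=float(chi2),
        df=int(dof),
        p=float(p),
        residuals=residuals,
        odds_ratio_late=float(odds),
        mode=mode,
    )


def volcano_table(
    diffmeth_results: pd.DataFrame, rt_annotations: pd.DataFrame
) -> pd.DataFrame:
    """Plot-data table (Δβ, -log10 q, RT category per probe)."""
    q = diffmeth_results["q"]
    out = pd.DataFrame(
        {
            "delta": diffmeth_results["delta"],
            "minus_log10_q": -np.log10(q.clip(lower=np.nextafter(0, 1))),
            "rt_category": rt_annotations["rt_category"].reindex(
                diffmeth_results.index, fill_value="unassigned"
            ),
        },
        index=diffmeth_results.index,
    )
    return out
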