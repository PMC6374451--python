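"""Per-probe two-group differential methylation.

The comparison follows the field-standard recipe for array β-values: an
unpaired two-sided Welch t-test per probe, Benjamini-Hochberg correction
across probes, and classification by an effect-size gate on the group mean
difference Δβ (comparison minus reference, so demethylation in the progressed
group is negative).

Two classification profiles are used downstream: a *count* profile
(q < 0.05, |Δβ| ≥ 0.2) and a stricter replication-timing profile that calls
only hypomethylation at Δβ ≤ −0.4.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import BetaMatrix, ProbeAnnotationTable, SampleSheet, CPG_CONTEXTS

LABELS_METH = ("hypo", "hyper", "ns")


def welch_test(values_ref, values_cmp) -> tuple[float, float, float, float]:
    """Unpaired two-sided Welch t-test for one feature.

    Returns ``(delta, t_stat, df, p)`` with ``delta = mean(cmp) - mean(ref)``.
    Missing values (NaN) are dropped. With fewer than two non-missing values
    in either group, or zero variance in both, the feature is untestable and
    t/df/p come back NaN (delta is still reported when both means exist).
    """
    ref = np.asarray(values_ref, dtype=float)
    cmp_ = np.asarray(values_cmp, dtype=float)
    ref = ref[~np.isnan(ref)]
    cmp_ = cmp_[~np.isnan(cmp_)]
    delta = float(cmp_.mean() - ref.mean()) if len(ref) and len(cmp_) else np.nan
    if len(ref) < 2 or len(cmp_) < 2:
        return delta, np.nan, np.nan, np.nan
    if ref.var(ddof=1) == 0.0 and cmp_.var(ddof=1) == 0.0:
        return delta, np.nan, np.nan, np.nan
    res = stats.ttest_ind(cmp_, ref, equal_var=False)
    return delta, float(res.statistic), float(res.df), float(res.pvalue)


def welch_test_matrix(ref: np.ndarray, cmp_: np.ndarray):
    """Row-wise Welch test on two 2-D arrays (features x samples).

    Vectorized counterpart of :func:`welch_test`; NaNs are omitted per row.
    Returns arrays ``(delta, t, df, p, n_ref, n_cmp)``.
    """
    ref = np.asarray(ref, dtype=float)
    cmp_ = np.asarray(cmp_, dtype=float)
    n_ref = np.sum(~np.isnan(ref), axis=1)
    n_cmp = np.sum(~np.isnan(cmp_), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mean_ref = np.nanmean(np.where(np.isnan(ref), np.nan, ref), axis=1)
        mean_cmp = np.nanmean(cmp_, axis=1)
        delta = mean_cmp - mean_ref
        res = stats.ttest_ind(cmp_, ref, axis=1, equal_var=False, nan_policy="omit")
        t = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
        df = np.asarray(res.df, dtype=float)
    untestable = (n_ref < 2) | (n_cmp < 2) | ~np.isfinite(t)
    t = np.where(untestable, np.nan, t)
    p = np.where(untestable, np.nan, p)
    df = np.where(untestable, np.nan, df)
    return delta, t, df, p, n_ref, n_cmp


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the ``m`` non-missing entries,
    capped at 1 and mapped back to input order; NaN entries pass through.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        bad = pv[(pv < 0) | (pv > 1)][0]
        raise ValueError(f"p-value outside [0,1]: {bad}")
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    ranked = np.minimum(ranked, 1.0)
    out = np.empty(m)
    out[order] = ranked
    q[mask] = out
    return q


def differential_methylation(
    beta: BetaMatrix,
    sheet: SampleSheet,
    reference_group: str,
    comparison_group: str,
) -> pd.DataFrame:
    """Welch + BH over all probes for one two-group contrast.

    Returns a DataFrame indexed by probe with columns
    ``delta, t_stat, df, p, q, n_ref, n_cmp``. Untestable probes are kept
    with missing p/q, never dropped.
    """
    ref_samples = sheet.samples_in_group(reference_group)
    cmp_samples = sheet.samples_in_group(comparison_group)
    if len(ref_samples) < 2 or len(cmp_samples) < 2:
        raise ValueError(
            f"need >=2 samples per group, got {len(ref_samples)} reference / "
            f"{len(cmp_samples)} comparison"
        )
    ref = beta.values[ref_samples].to_numpy()
    cmp_ = beta.values[cmp_samples].to_numpy()
    delta, t, df, p, n_ref, n_cmp = welch_test_matrix(ref, cmp_)
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "delta": delta,
            "t_stat": t,
            "df": df,
            "p": p,
            "q": q,
            "n_ref": n_ref.astype(int),
            "n_cmp": n_cmp.astype(int),
        },
        index=beta.values.index.rename("probe_id"),
    )


def classify_probes(
    results: pd.DataFrame,
    q_max: float = 0.05,
    delta_min: float = 0.2,
    hypo_only: bool = False,
) -> pd.DataFrame:
    """Attach a ``label`` column: hypo / hyper / ns.

    hypo: q < q_max and delta <= -delta_min; hyper symmetric. The stricter
    replication-timing profile uses ``delta_min=0.4, hypo_only=True`` (only
    demethylation is called at that gate). Untestable probes are ``ns``.
    """
    q = results["q"].to_numpy()
    delta = results["delta"].to_numpy()
    sig = ~np.isnan(q) & (q < q_max)
    label = np.where(
        sig & (delta <= -delta_min),
        "hypo",
        np.where((not hypo_only) & sig & (delta >= delta_min), "hyper", "ns"),
    )
    out = results.copy()
    out["label"] = label
    return out


def cpg_context_breakdown(
    labeled: pd.DataFrame, annotation: ProbeAnnotationTable
) -> pd.DataFrame:
    """Contingency counts of classification label x CpG context.

    Returns a DataFrame indexed by label (hypo, hyper, ns) with one column
    per context plus per-label proportion columns (``prop_<context>``).
    """
    missing = labeled.index.difference(annotation.table.index)
    if len(missing):
        raise KeyError(f"probes missing from annotation: {list(missing[:5])}")
    context = annotation.table.loc[labeled.index, "cpg_context"]
    counts = (
        pd.crosstab(labeled["label"], context)
        .reindex(index=list(LABELS_METH), columns=list(CPG_CONTEXTS), fill_value=0)
        .astype(int)
    )
    counts.index.name = "label"
    totals = counts.sum(axis=1)
    props = counts.div(totals.where(totals > 0, 1), axis=0)
    props.columns = [f"prop_{c}" for c in props.columns]
    return pd.concat([counts, props], axis=1)
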