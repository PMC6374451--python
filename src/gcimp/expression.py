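"""Two-group differential expression on FPKM.

Per gene: Welch t-test on log2(FPKM + epsilon) (variance-stabilized scale;
a ``test_scale="raw"`` mode is provided), BH correction across genes, and a
fold-change gate on the raw scale — fold_change = (mean_cmp + eps) /
(mean_ref + eps) — labelling up if q < q_max and FC > fc_up, down if
q < q_max and FC < fc_down.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffmeth import bh_adjust, welch_test_matrix
from .io import ExpressionMatrix, SampleSheet


def de_test(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    reference_group: str,
    comparison_group: str,
    q_max: float = 0.05,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    epsilon: float = 0.1,
    test_scale: str = "log2",
    min_fpkm: float | None = None,
) -> pd.DataFrame:
    """Per-gene DE table with columns
    ``log2_fc, fold_change, t_stat, df, p, q, n_ref, n_cmp, label``.

    Genes that are all-missing (or filtered by ``min_fpkm``, off by default)
    are kept with missing p/q and label ``ns``.
    """
    if test_scale not in ("log2", "raw"):
        raise ValueError(f"test_scale must be 'log2' or 'raw', got {test_scale!r}")
    ref_samples = sheet.samples_in_group(reference_group)
    cmp_samples = sheet.samples_in_group(comparison_group)
    if len(ref_samples) < 2 or len(cmp_samples) < 2:
        raise ValueError("need >=2 samples per group")
    ref = expr.values[ref_samples].to_numpy()
    cmp_ = expr.values[cmp_samples].to_numpy()

    mean_ref = np.nanmean(np.where(np.isnan(ref), np.nan, ref), axis=1)
    mean_cmp = np.nanmean(cmp_, axis=1)
    fold_change = (mean_cmp + epsilon) / (mean_ref + epsilon)

    if test_scale == "log2":
        a, b = np.log2(ref + epsilon), np.log2(cmp_ + epsilon)
    else:
        a, b = ref, cmp_
    _, t, df, p, n_ref, n_cmp = welch_test_matrix(a, b)

    if min_fpkm is not None:
        expressed = (mean_ref >= min_fpkm) | (mean_cmp >= min_fpkm)
        p = np.where(expressed, p, np.nan)
        t = np.where(expressed, t, np.nan)
        df = np.where(expressed, df, np.nan)
    q = bh_adjust(p)

    sig = ~np.isnan(q) & (q < q_max)
    label = np.where(
        sig & (fold_change > fc_up),
        "up",
        np.where(sig & (fold_change < fc_down), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "log2_fc": np.log2(fold_change),
            "fold_change": fold_change,
            "t_stat": t,
            "df": df,
            "p": p,
            "q": q,
            "n_ref": n_ref.astype(int),
            "n_cmp": n_cmp.astype(int),
            "label": label,
        },
        index=expr.values.index.rename("gene_id"),
    )


def de_volcano_table(de_results: pd.DataFrame) -> pd.DataFrame:
    """Plot-data table (log2 FC, -log10 q, label per gene)."""
    q = de_results["q"]
    return pd.DataFrame(
        {
            "log2_fc": de_results["log2_fc"],
            "minus_log10_q": -np.log10(q.clip(lower=np.nextafter(0, 1))),
            "label": de_results["label"],
        },
        index=de_results.index,
    )
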