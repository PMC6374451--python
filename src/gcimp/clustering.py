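"""Probe filtering, variance-based probe selection, and sample clustering.

The clustering recipe is the standard one for 450K methylation subtyping:
drop sex-chromosome and SNP-proximal probes, keep the top-k most variable
probes by standard deviation, then agglomerative clustering of samples with
Euclidean distance and Ward linkage in the R ``hclust`` "ward.D2" convention
(Ward criterion on unsquared Euclidean distances, which is exactly what
``scipy.cluster.hierarchy.linkage(..., method="ward")`` computes from raw
observations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .io import BetaMatrix, ProbeAnnotationTable

logger = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    labels: pd.Series  # sample_id -> cluster index in 1..k
    linkage: np.ndarray  # scipy linkage matrix (merge list with heights)
    k: int
    selected_probes: list[str]

    def partition(self) -> dict[str, int]:
        return {str(s): int(c) for s, c in self.labels.items()}


def filter_probes(annotation: ProbeAnnotationTable) -> list[str]:
    """Probes eligible for clustering: autosomal and with no SNP within 5 bp
    of (or at) the targeted CpG."""
    t = annotation.table
    keep = ~t["sex_chromosome"] & ~t["snp_within_5bp"]
    if not keep.any():
        logger.warning("probe filter removed every probe")
    return [str(p) for p in t.index[keep]]


def select_top_variable(
    beta: BetaMatrix, k: int = 10000, probes: list[str] | None = None
) -> list[str]:
    """Top-``k`` probes by descending sample standard deviation (ddof=1).

    Missing values are excluded pairwise; probes with fewer than two
    non-missing values cannot be ranked and are dropped (logged). Ties are
    broken by probe id, lexicographically.
    """
    values = beta.values if probes is None else beta.values.loc[probes]
    n_ok = values.notna().sum(axis=1)
    droppable = n_ok < 2
    if droppable.any():
        logger.warning(
            "%d probes excluded from SD ranking (<2 non-missing values)",
            int(droppable.sum()),
        )
        values = values[~droppable]
    if k > values.shape[0]:
        raise ValueError(f"k={k} exceeds {values.shape[0]} rankable probes")
    sd = values.std(axis=1, ddof=1)
    ranking = (
        pd.DataFrame({"sd": sd})
        .reset_index(names="probe_id")
        .sort_values(["sd", "probe_id"], ascending=[False, True], kind="mergesort")
    )
    return [str(p) for p in ranking["probe_id"].head(k)]


def hierarchical_cluster(
    beta: BetaMatrix, probes: list[str], k: int
) -> ClusterAssignment:
    """Ward.D2 clustering of samples over the selected probes, cut into k groups."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > beta.n_samples:
        raise ValueError(f"k={k} exceeds {beta.n_samples} samples")
    sub = beta.values.loc[probes]
    has_missing = sub.isna().any(axis=1)
    if has_missing.any():
        logger.warning(
            "%d selected probes dropped for missing values", int(has_missing.sum())
        )
        sub = sub[~has_missing]
    X = sub.to_numpy().T  # samples x probes
    Z = hierarchy.linkage(X, method="ward")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return ClusterAssignment(
        labels=pd.Series(labels, index=sub.columns, name="cluster"),
        linkage=Z,
        k=k,
        selected_probes=[str(p) for p in sub.index],
    )


def linkage_table(assignment: ClusterAssignment) -> pd.DataFrame:
    """Merge list as a writable table (child ids, height, cluster size)."""
    Z = assignment.linkage
    return pd.DataFrame(
        {
            "child_a": Z[:, 0].astype(int),
            "child_b": Z[:, 1].astype(int),
            "height": Z[:, 2],
            "size": Z[:, 3].astype(int),
        }
    )
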