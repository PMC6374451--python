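"""Promoter methylation aggregation and methylation-expression integration.

A probe belongs to a gene's promoter when it carries one of the feature
annotations TSS1500, TSS200, 5'UTR or 1stExon for that gene. Per gene, the
promoter methylation status is the per-sample mean β over the top 25% of
promoter probes most different between the two groups (|mean_cmp - mean_ref|
ranking, count = ceil(0.25 n), minimum 1); group difference of that score is
tested with Welch + BH across genes.

The starburst classification joins promoter methylation with differential
expression: a gene is *up_with_demethylation* when expression q and promoter
q are both < 0.05, expression fold change > 2, and the promoter methylation
difference < -0.2 (symmetric definition for down_with_hypermethylation).

The per-probe alternative scan skips aggregation and lists, for each
upregulated gene, individual promoter probes that are significantly
demethylated on their own.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .diffmeth import bh_adjust, welch_test
from .io import BetaMatrix, ProbeAnnotationTable, SampleSheet

STARBURST_CATEGORIES = ("up_with_demethylation", "down_with_hypermethylation", "other")


def promoter_probe_sets(annotation: ProbeAnnotationTable) -> dict[str, list[str]]:
    """gene -> sorted promoter probe ids (genes without promoter probes absent)."""
    gene_probes: dict[str, set[str]] = {}
    for probe, pairs in annotation.promoter_map().items():
        for _feature, gene in pairs:
            gene_probes.setdefault(gene, set()).add(probe)
    return {g: sorted(ps) for g, ps in sorted(gene_probes.items())}


def top_fraction_count(n_probes: int, fraction: float = 0.25) -> int:
    """Number of probes kept by the top-fraction rule: ceil(fraction*n), >= 1."""
    return max(1, math.ceil(fraction * n_probes))


def select_top_probes(
    abs_diff: pd.Series, fraction: float = 0.25, signed: bool = False
) -> list[str]:
    """Probes ranked by between-group difference, ties broken by probe id.

    ``signed=False`` (default) ranks by absolute difference; ``signed=True``
    ranks by most-negative difference (demethylation-directed).
    """
    key = abs_diff.abs() if not signed else -abs_diff
    ranking = (
        pd.DataFrame({"key": key})
        .reset_index(names="probe_id")
        .sort_values(["key", "probe_id"], ascending=[False, True], kind="mergesort")
    )
    k = top_fraction_count(len(ranking), fraction)
    return [str(p) for p in ranking["probe_id"].head(k)]


def summarize_promoter(
    beta: BetaMatrix,
    sheet: SampleSheet,
    gene_probes: Mapping[str, Iterable[str]],
    reference_group: str,
    comparison_group: str,
    fraction: float = 0.25,
    signed_ranking: bool = False,
) -> pd.DataFrame:
    """Per-gene promoter summary.

    Columns: ``n_promoter_probes, selected_probes` (``;``-joined),
    ``promoter_delta`` (cmp score mean - ref score mean), ``promoter_p``,
    ``promoter_q``. A sample whose selected probes are all missing gets a
    missing score and drops out of that gene's test pairwise.
    """
    ref_samples = sheet.samples_in_group(reference_group)
    cmp_samples = sheet.samples_in_group(comparison_group)
    if len(ref_samples) < 2 or len(cmp_samples) < 2:
        raise ValueError("need >=2 samples per group")
    rows = []
    for gene in sorted(gene_probes):
        probes = sorted(set(map(str, gene_probes[gene])))
        sub = beta.values.loc[probes]
        diff = sub[cmp_samples].mean(axis=1) - sub[ref_samples].mean(axis=1)
        selected = select_top_probes(diff, fraction, signed=signed_ranking)
        scores = beta.values.loc[selected].mean(axis=0)  # pandas mean skips NaN
        delta, t, df, p = welch_test(scores[ref_samples], scores[cmp_samples])
        rows.append(
            {
                "gene": gene,
                "n_promoter_probes": len(probes),
                "selected_probes": ";".join(selected),
                "promoter_delta": delta,
                "promoter_t": t,
                "promoter_df": df,
                "promoter_p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("gene")
    out["promoter_q"] = bh_adjust(out["promoter_p"])
    return out


def starburst_classify(
    promoters: pd.DataFrame,
    expression: pd.DataFrame,
    q_max: float = 0.05,
    delta_min: float = 0.2,
    fc_min: float = 2.0,
) -> pd.DataFrame:
    """Joint classification over genes having both a promoter summary and an
    expression result (intersection).

    Returns a DataFrame indexed by gene with the inputs' key columns, a
    ``category`` column, and signed plot axes (``plot_x`` = promoter Δβ,
    ``plot_y`` = expression log2 FC).
    """
    genes = promoters.index.intersection(expression.index).sort_values()
    pm = promoters.loc[genes]
    ex = expression.loc[genes]
    both_sig = (
        ~pm["promoter_q"].isna()
        & ~ex["q"].isna()
        & (pm["promoter_q"] < q_max)
        & (ex["q"] < q_max)
    )
    up = both_sig & (ex["fold_change"] > fc_min) & (pm["promoter_delta"] < -delta_min)
    down = both_sig & (ex["fold_change"] < 1 / fc_min) & (
        pm["promoter_delta"] > delta_min
    )
    category = np.where(up, "up_with_demethylation",
                        np.where(down, "down_with_hypermethylation", "other"))
    return pd.DataFrame(
        {
            "promoter_delta": pm["promoter_delta"],
            "promoter_q": pm["promoter_q"],
            "fold_change": ex["fold_change"],
            "log2_fc": ex["log2_fc"],
            "expression_q": ex["q"],
            "category": category,
            "plot_x": pm["promoter_delta"],
            "plot_y": ex["log2_fc"],
        },
        index=genes.rename("gene"),
    )


def per_probe_promoter_scan(
    upregulated_genes: Iterable[str],
    diffmeth_results: pd.DataFrame,
    gene_probes: Mapping[str, Iterable[str]],
    q_max: float = 0.05,
    delta_min: float = 0.2,
) -> dict[str, list[str]]:
    """For each upregulated gene, promoter probes individually demethylated
    (q < q_max and Δβ < -delta_min). Genes with no passing probe are absent."""
    flagged: dict[str, list[str]] = {}
    for gene in sorted(set(map(str, upregulated_genes))):
        probes = sorted(set(map(str, gene_probes.get(gene, ()))))
        if not probes:
            continue
        sub = diffmeth_results.loc[diffmeth_results.index.intersection(probes)]
        passing = sub[(sub["q"] < q_max) & (sub["delta"] < -delta_min)]
        if len(passing):
            flagged[gene] = sorted(map(str, passing.index))
    return flagged
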