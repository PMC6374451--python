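"""End-to-end orchestration: simulate -> cluster -> diffmeth -> rt-enrich ->
de -> integrate -> fusions, with a deterministic summary report.

Every stage writes its result table under the output directory; the report
only restates numbers recomputable from those tables. Identical config +
seed give byte-identical reports (no timestamps inside the report; wall
times go to the log).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import clustering, diffmeth, expression, fusions, promoter, replication_timing
from .io import write_table
from .simulate import (
    DEMETH_GROUP,
    REFERENCE_GROUP,
    SimulationConfig,
    generate_cohort,
    generate_fusion_candidates,
    write_cohort,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds carry the published defaults of each stage."""

    output_dir: str
    simulation: SimulationConfig
    k_clusters: int = 2
    top_n_probes: int = 10_000
    reference_group: str = REFERENCE_GROUP
    comparison_group: str = DEMETH_GROUP
    q_max: float = 0.05
    delta_count: float = 0.2
    delta_rt: float = 0.4
    fc_up: float = 2.0
    fc_down: float = 0.5
    epsilon: float = 0.1
    promoter_fraction: float = 0.25
    fusion_min_match: int = 12
    fusion_min_reads: int = 4
    fusion_min_intra_distance: int = 100_000
    rt_mode: str = "all"

    def validate(self) -> None:
        for name in (
            "q_max", "delta_count", "delta_rt", "fc_up", "epsilon",
            "promoter_fraction", "fusion_min_match", "fusion_min_intra_distance",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.simulation.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = SimulationConfig(**raw.pop("simulation"))
        return cls(simulation=sim, **raw)

    def canonical_yaml(self) -> str:
        d = asdict(self)
        d.pop("output_dir")  # hash covers the analysis, not where it lands
        d["simulation"]["context_demeth_weight"] = dict(
            d["simulation"]["context_demeth_weight"]
        )
        return yaml.safe_dump(d, sort_keys=True)


def _stage(name: str):
    logger.info("stage=%s start", name)
    return time.perf_counter()


def _stage_done(name: str, t0: float, **counts) -> None:
    extra = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s done wall=%.2fs %s", name, time.perf_counter() - t0, extra)


def run_all(config: RunConfig) -> dict:
    """Run the whole pipeline on a simulated cohort; returns the report dict."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    t0 = _stage("simulate")
    beta, annotation, track, expr, sheet, truth = generate_cohort(config.simulation)
    candidates, fusion_truth = generate_fusion_candidates(config.simulation)
    truth.fusion_truth = fusion_truth
    manifest.update(write_cohort(outdir / "inputs", beta, annotation, track, expr,
                                 sheet, truth))
    _stage_done("simulate", t0, probes=beta.n_probes, samples=beta.n_samples)

    t0 = _stage("cluster")
    eligible = clustering.filter_probes(annotation)
    top_n = min(config.top_n_probes, len(eligible))
    top = clustering.select_top_variable(beta, k=top_n, probes=eligible)
    assignment = clustering.hierarchical_cluster(beta, top, k=config.k_clusters)
    cluster_df = assignment.labels.rename("cluster").to_frame()
    cluster_df.index.name = "sample_id"
    write_table(cluster_df.reset_index(), outdir / "cluster_assignment.tsv")
    write_table(clustering.linkage_table(assignment), outdir / "cluster_linkage.tsv")
    manifest["cluster_assignment"] = str(outdir / "cluster_assignment.tsv")
    manifest["cluster_linkage"] = str(outdir / "cluster_linkage.tsv")
    _stage_done("cluster", t0, k=config.k_clusters, probes_used=len(top))

    t0 = _stage("diffmeth")
    dm = diffmeth.differential_methylation(
        beta, sheet, config.reference_group, config.comparison_group
    )
    dm_count = diffmeth.classify_probes(dm, config.q_max, config.delta_count)
    dm_rt = diffmeth.classify_probes(dm, config.q_max, config.delta_rt, hypo_only=True)
    write_table(dm_count.reset_index(), outdir / "diffmeth_probes.tsv")
    manifest["diffmeth_probes"] = str(outdir / "diffmeth_probes.tsv")
    breakdown = diffmeth.cpg_context_breakdown(dm_count, annotation)
    write_table(breakdown.reset_index(), outdir / "diffmeth_context_breakdown.tsv")
    manifest["diffmeth_context_breakdown"] = str(
        outdir / "diffmeth_context_breakdown.tsv"
    )
    n_hypo = int((dm_count["label"] == "hypo").sum())
    n_hyper = int((dm_count["label"] == "hyper").sum())
    _stage_done("diffmeth", t0, hypo=n_hypo, hyper=n_hyper)

    t0 = _stage("rt-enrich")
    rt_ann, thresholds = replication_timing.annotate_and_categorize(annotation, track)
    write_table(rt_ann.reset_index(), outdir / "rt_annotation.tsv")
    manifest["rt_annotation"] = str(outdir / "rt_annotation.tsv")
    demeth_ids = dm_rt.index[dm_rt["label"] == "hypo"]
    enrich_all = replication_timing.rt_enrichment_test(demeth_ids, rt_ann, mode="all")
    enrich_comp = replication_timing.rt_enrichment_test(
        demeth_ids, rt_ann, mode="complement"
    )
    write_table(
        enrich_comp.table.reset_index(), outdir / "rt_contingency_complement.tsv"
    )
    manifest["rt_contingency_complement"] = str(
        outdir / "rt_contingency_complement.tsv"
    )
    volcano = replication_timing.volcano_table(dm, rt_ann)
    write_table(volcano.reset_index(), outdir / "rt_volcano_data.tsv")
    manifest["rt_volcano_data"] = str(outdir / "rt_volcano_data.tsv")
    _stage_done("rt-enrich", t0, demeth=len(demeth_ids))

    t0 = _stage("de")
    de = expression.de_test(
        expr, sheet, config.reference_group, config.comparison_group,
        q_max=config.q_max, fc_up=config.fc_up, fc_down=config.fc_down,
        epsilon=config.epsilon,
    )
    write_table(de.reset_index(), outdir / "de_genes.tsv")
    manifest["de_genes"] = str(outdir / "de_genes.tsv")
    n_up = int((de["label"] == "up").sum())
    n_down = int((de["label"] == "down").sum())
    _stage_done("de", t0, up=n_up, down=n_down)

    t0 = _stage("integrate")
    gene_probes = promoter.promoter_probe_sets(annotation)
    summaries = promoter.summarize_promoter(
        beta, sheet, gene_probes, config.reference_group, config.comparison_group,
        fraction=config.promoter_fraction,
    )
    write_table(summaries.reset_index(), outdir / "promoter_summary.tsv")
    manifest["promoter_summary"] = str(outdir / "promoter_summary.tsv")
    starburst = promoter.starburst_classify(
        summaries, de, q_max=config.q_max, delta_min=config.delta_count,
        fc_min=config.fc_up,
    )
    write_table(starburst.reset_index(), outdir / "starburst.tsv")
    manifest["starburst"] = str(outdir / "starburst.tsv")
    up_genes = de.index[de["label"] == "up"]
    scan = promoter.per_probe_promoter_scan(
        up_genes, dm_count, gene_probes, q_max=config.q_max,
        delta_min=config.delta_count,
    )
    scan_df = pd.DataFrame(
        {"gene": list(scan), "demethylated_probes": [";".join(v) for v in scan.values()]}
    )
    write_table(scan_df, outdir / "per_probe_promoter_scan.tsv")
    manifest["per_probe_promoter_scan"] = str(outdir / "per_probe_promoter_scan.tsv")
    starburst_up = sorted(
        starburst.index[starburst["category"] == "up_with_demethylation"]
    )
    _stage_done("integrate", t0, starburst_up=len(starburst_up))

    t0 = _stage("fusions")
    calls = fusions.filter_fusions(
        candidates,
        min_match=config.fusion_min_match,
        min_reads_exclusive=config.fusion_min_reads,
        min_intra_distance=config.fusion_min_intra_distance,
    )
    fusions.write_fusion_candidates(candidates, outdir / "fusion_candidates.tsv")
    calls_df = fusions.calls_to_table(calls)
    write_table(calls_df, outdir / "fusion_calls.tsv")
    manifest["fusion_candidates"] = str(outdir / "fusion_candidates.tsv")
    manifest["fusion_calls"] = str(outdir / "fusion_calls.tsv")
    n_pass = int(calls_df["pass"].sum())
    _stage_done("fusions", t0, n_pass=n_pass)

    report = {
        "software_version": __version__,
        "config_hash": hashlib.sha256(
            config.canonical_yaml().encode()
        ).hexdigest(),
        "seed": config.simulation.rng_seed,
        "cluster_sizes": {
            str(c): int(n) for c, n in assignment.labels.value_counts().sort_index().items()
        },
        "n_probes_tested": int(dm["p"].notna().sum()),
        "hypo_probes": n_hypo,
        "hyper_probes": n_hyper,
        "hypo_probes_rt_profile": int((dm_rt["label"] == "hypo").sum()),
        "rt_thresholds": {
            "late_cut": thresholds.late_cut,
            "early_cut": thresholds.early_cut,
        },
        "rt_chi_square": {
            "all": {"stat": enrich_all.chi_square_stat, "df": enrich_all.df,
                    "p": enrich_all.p},
            "complement": {"stat": enrich_comp.chi_square_stat, "df": enrich_comp.df,
                           "p": enrich_comp.p},
            "odds_ratio_late": enrich_comp.odds_ratio_late,
        },
        "up_genes": n_up,
        "down_genes": n_down,
        "starburst_up_with_demethylation": starburst_up,
        "per_probe_scan_genes": sorted(scan),
        "fusion_calls_pass": n_pass,
        "fusion_calls_fail": int((~calls_df["pass"]).sum()),
        "manifest": {k: str(Path(v).relative_to(outdir)) for k, v in manifest.items()},
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
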