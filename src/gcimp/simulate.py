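"""Synthetic cohort generator with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes for a methylation-array cohort of IDH-mutant gliomas:

* a hypermethylated reference group (G-CIMP-like: CpG-island probes around
  β = 0.8, open-sea probes around 0.7), and
* a partially demethylated comparison group (G-CIMP-low-like) whose planted
  demethylation is concentrated in late-replicating domains and outside CpG
  islands — the signature of passive demethylation under accelerated cell
  division;
* one synthetic chromosome tiled with alternating early/late replication-
  timing domains (piecewise-constant signed track; a smooth sinusoidal
  profile is available to exercise the intermediate category);
* promoter-coupled expression: a small set of planted genes receives both
  promoter demethylation and a log-normal expression up-shift;
* fusion candidates with per-class decoys, each violating exactly one
  filter rule.

β noise is drawn from a Beta distribution re-parameterized by (mean,
concentration): the bounded, skewed noise that array β-values actually show.
All randomness flows from ``rng_seed``; the same config is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .fusions import FusionCandidate, FusionPartner, JunctionRead
from .io import (
    BetaMatrix,
    ExpressionMatrix,
    ProbeAnnotationTable,
    ReplicationTimingTrack,
    SampleSheet,
    write_beta_matrix,
    write_expression_matrix,
    write_probe_annotation,
    write_rt_track,
    write_sample_sheet,
)

REFERENCE_GROUP = "gcimp_high"
DEMETH_GROUP = "gcimp_demeth"

#: mean reference-group β by CpG context (islands hypermethylated in G-CIMP)
CONTEXT_BASE_BETA = {"Island": 0.80, "Shore": 0.76, "Shelf": 0.73, "OpenSea": 0.70}

#: normal-brain-like profile used by the contamination mixing option
CONTEXT_NORMAL_BETA = {"Island": 0.15, "Shore": 0.40, "Shelf": 0.60, "OpenSea": 0.75}

_DECOY_CLASSES = ("too_few_reads", "short_match", "read_through")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Sample sizes default to 20 reference / 9 demethylated tumors — the
    reference/progressed contrast of the motivating study at reduced scale.
    """

    rng_seed: int
    n_probes: int = 10_000
    n_genes: int = 1_000
    n_samples_reference: int = 20
    n_samples_demeth: int = 9
    fraction_island_probes: float = 0.30
    fraction_shore_probes: float = 0.15
    fraction_shelf_probes: float = 0.10
    chromosome: str = "chrS"
    n_rt_domains: int = 40
    rt_domain_length: int = 100_000
    rt_early_level: float = 1.0
    rt_late_level: float = -1.0
    rt_profile: str = "blocks"  # or "sine"
    planted_demeth_delta: float = 0.45
    late_demeth_prob: float = 0.30
    early_demeth_prob: float = 0.02
    context_demeth_weight: Mapping[str, float] = field(
        default_factory=lambda: {
            "Island": 0.15,
            "Shore": 0.50,
            "Shelf": 0.80,
            "OpenSea": 1.00,
        }
    )
    n_planted_promoter_genes: int = 3
    planted_expression_log2fc: float = 2.0
    expression_base_log2_mean: float = 3.0
    expression_base_log2_sd: float = 1.5
    expression_noise_log2_sd: float = 0.5
    beta_noise_concentration: float = 60.0
    probe_mean_jitter: float = 0.05
    max_promoter_probes_per_gene: int = 6
    island_promoter_weight: float = 4.0
    contamination_fraction: float = 0.0
    n_true_fusions: int = 3
    n_decoys_per_class: int = 1

    def validate(self) -> None:
        probs = {
            "fraction_island_probes": self.fraction_island_probes,
            "fraction_shore_probes": self.fraction_shore_probes,
            "fraction_shelf_probes": self.fraction_shelf_probes,
            "late_demeth_prob": self.late_demeth_prob,
            "early_demeth_prob": self.early_demeth_prob,
            "contamination_fraction": self.contamination_fraction,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        frac_sum = (
            self.fraction_island_probes
            + self.fraction_shore_probes
            + self.fraction_shelf_probes
        )
        if frac_sum > 1.0:
            raise ValueError("context fractions sum above 1")
        if not 0.0 <= self.planted_demeth_delta < 1.0:
            raise ValueError("planted_demeth_delta must be in [0,1)")
        for name in ("n_probes", "n_genes", "n_rt_domains", "rt_domain_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_samples_reference < 2 or self.n_samples_demeth < 2:
            raise ValueError("need >=2 samples per group")
        if self.beta_noise_concentration <= 0:
            raise ValueError("beta_noise_concentration must be > 0")
        if self.rt_profile not in ("blocks", "sine"):
            raise ValueError("rt_profile must be 'blocks' or 'sine'")
        if self.n_planted_promoter_genes > self.n_genes:
            raise ValueError("more planted genes than genes")
        if self.rng_seed is None:
            raise ValueError("rng_seed is mandatory")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["context_demeth_weight"] = dict(d["context_demeth_weight"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class SyntheticTruth:
    """Ground truth recorded at generation time."""

    group_labels: pd.Series  # sample -> group
    demeth_probes: frozenset[str]  # probes with a real planted β shift
    probe_rt_category: pd.Series  # 'late' / 'early' at generation time
    planted_genes: tuple[str, ...]
    fusion_truth: pd.DataFrame | None = None  # candidate_id, is_true, decoy_class
    n_beta_clipped: int = 0


def _make_rt_track(cfg: SimulationConfig) -> ReplicationTimingTrack:
    n, L = cfg.n_rt_domains, cfg.rt_domain_length
    if cfg.rt_profile == "blocks":
        starts = np.arange(n, dtype=np.int64) * L
        values = np.where(np.arange(n) % 2 == 0, cfg.rt_early_level, cfg.rt_late_level)
        df = pd.DataFrame(
            {
                "chromosome": cfg.chromosome,
                "start": starts,
                "end": starts + L,
                "rt_value": values.astype(float),
            }
        )
    else:  # sine: 10 bins per domain, one full period per early+late pair
        bins_per_domain = 10
        width = max(1, L // bins_per_domain)
        total = n * L
        starts = np.arange(0, total, width, dtype=np.int64)
        ends = np.minimum(starts + width, total)
        mid = (starts + ends) / 2.0
        amp = max(abs(cfg.rt_early_level), abs(cfg.rt_late_level))
        values = amp * np.sin(2 * np.pi * mid / (2 * L) + np.pi / 2)
        df = pd.DataFrame(
            {
                "chromosome": cfg.chromosome,
                "start": starts,
                "end": ends,
                "rt_value": np.round(values, 6),
            }
        )
    return ReplicationTimingTrack(df)


def _beta_draw(rng, mean: np.ndarray, concentration: float, n_cols: int) -> np.ndarray:
    a = mean * concentration
    b = (1.0 - mean) * concentration
    return rng.beta(a[:, None], b[:, None], size=(mean.size, n_cols))


def generate_cohort(
    config: SimulationConfig,
) -> tuple[
    BetaMatrix,
    ProbeAnnotationTable,
    ReplicationTimingTrack,
    ExpressionMatrix,
    SampleSheet,
    SyntheticTruth,
]:
    """Generate one cohort (β matrix, probe annotation, RT track, expression
    matrix, sample sheet) together with its ground truth."""
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.rng_seed)

    track = _make_rt_track(cfg)
    chrom_len = cfg.n_rt_domains * cfg.rt_domain_length

    # --- probes -------------------------------------------------------------
    positions = np.sort(
        rng.choice(np.arange(1, chrom_len + 1), size=cfg.n_probes, replace=False)
    )
    probe_ids = np.array([f"cg{i:08d}" for i in range(cfg.n_probes)])
    p_open = 1.0 - (
        cfg.fraction_island_probes
        + cfg.fraction_shore_probes
        + cfg.fraction_shelf_probes
    )
    contexts = rng.choice(
        np.array(["Island", "Shore", "Shelf", "OpenSea"]),
        size=cfg.n_probes,
        p=[
            cfg.fraction_island_probes,
            cfg.fraction_shore_probes,
            cfg.fraction_shelf_probes,
            p_open,
        ],
    )
    rt_at_probe = track.values_at([cfg.chromosome] * cfg.n_probes, positions)
    rt_cat = np.where(rt_at_probe < 0, "late", "early")

    # --- promoter feature assignment (island-biased) ------------------------
    gene_ids = [f"GENE{i:04d}" for i in range(cfg.n_genes)]
    weight = np.where(contexts == "Island", cfg.island_promoter_weight, 1.0)
    weight = weight / weight.sum()
    features = np.array(["TSS1500", "TSS200", "5'UTR", "1stExon"])
    probe_feature_pairs: dict[int, list[str]] = {}
    gene_probe_idx: dict[str, np.ndarray] = {}
    for gene in gene_ids:
        k = int(rng.integers(1, cfg.max_promoter_probes_per_gene + 1))
        idx = rng.choice(cfg.n_probes, size=k, replace=False, p=weight)
        feats = rng.choice(features, size=k)
        gene_probe_idx[gene] = idx
        for i, f in zip(idx, feats):
            probe_feature_pairs.setdefault(int(i), []).append(f"{f}:{gene}")
    promoter_col = [
        ";".join(probe_feature_pairs.get(i, [])) for i in range(cfg.n_probes)
    ]

    # --- planted demethylation ----------------------------------------------
    ctx_w = np.array([cfg.context_demeth_weight[c] for c in contexts])
    p_plant = (
        np.where(rt_at_probe < 0, cfg.late_demeth_prob, cfg.early_demeth_prob) * ctx_w
    )
    planted = rng.random(cfg.n_probes) < p_plant

    planted_genes = tuple(
        sorted(
            str(g)
            for g in rng.choice(gene_ids, size=cfg.n_planted_promoter_genes, replace=False)
        )
    )
    for gene in planted_genes:
        planted[gene_probe_idx[gene]] = True

    # --- β values -----------------------------------------------------------
    base = np.array([CONTEXT_BASE_BETA[c] for c in contexts])
    base = base + rng.uniform(-cfg.probe_mean_jitter, cfg.probe_mean_jitter, cfg.n_probes)
    base = np.clip(base, 0.02, 0.98)
    cmp_mean = base - cfg.planted_demeth_delta * planted
    if cfg.contamination_fraction > 0:
        normal = np.array([CONTEXT_NORMAL_BETA[c] for c in contexts])
        cmp_mean = (
            1 - cfg.contamination_fraction
        ) * cmp_mean + cfg.contamination_fraction * normal
    cmp_mean = np.clip(cmp_mean, 0.02, 0.98)

    ref_vals = _beta_draw(rng, base, cfg.beta_noise_concentration, cfg.n_samples_reference)
    cmp_vals = _beta_draw(rng, cmp_mean, cfg.beta_noise_concentration, cfg.n_samples_demeth)
    values = np.concatenate([ref_vals, cmp_vals], axis=1)
    eps = 1e-6
    n_clipped = int(np.sum((values < eps) | (values > 1 - eps)))
    values = np.clip(values, eps, 1 - eps)

    ref_names = [f"R{i + 1:03d}" for i in range(cfg.n_samples_reference)]
    cmp_names = [f"D{i + 1:03d}" for i in range(cfg.n_samples_demeth)]
    sample_ids = ref_names + cmp_names
    beta = BetaMatrix(
        pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids)
    )

    annotation = ProbeAnnotationTable(
        pd.DataFrame(
            {
                "chromosome": cfg.chromosome,
                "position": positions,
                "cpg_context": contexts,
                "promoter_features": promoter_col,
                "snp_within_5bp": False,
                "sex_chromosome": False,
            },
            index=pd.Index(probe_ids, name="probe_id"),
        )
    )

    # --- expression ---------------------------------------------------------
    base_log2 = rng.normal(
        cfg.expression_base_log2_mean, cfg.expression_base_log2_sd, cfg.n_genes
    )
    shift = np.zeros(cfg.n_genes)
    planted_mask = np.isin(np.array(gene_ids), np.array(planted_genes))
    shift[planted_mask] = cfg.planted_expression_log2fc
    x_ref = base_log2[:, None] + rng.normal(
        0, cfg.expression_noise_log2_sd, (cfg.n_genes, cfg.n_samples_reference)
    )
    x_cmp = (base_log2 + shift)[:, None] + rng.normal(
        0, cfg.expression_noise_log2_sd, (cfg.n_genes, cfg.n_samples_demeth)
    )
    fpkm = np.power(2.0, np.concatenate([x_ref, x_cmp], axis=1))
    expr = ExpressionMatrix(
        pd.DataFrame(fpkm, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    )

    sheet = SampleSheet(
        pd.DataFrame(
            {
                "group_label": [REFERENCE_GROUP] * len(ref_names)
                + [DEMETH_GROUP] * len(cmp_names),
                "pair_id": "",
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    demeth_probes = (
        frozenset(probe_ids[planted]) if cfg.planted_demeth_delta > 0 else frozenset()
    )
    truth = SyntheticTruth(
        group_labels=sheet.table["group_label"].copy(),
        demeth_probes=demeth_probes,
        probe_rt_category=pd.Series(rt_cat, index=probe_ids, name="rt_category"),
        planted_genes=planted_genes,
        n_beta_clipped=n_clipped,
    )
    return beta, annotation, track, expr, sheet, truth


def generate_fusion_candidates(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[FusionCandidate], pd.DataFrame]:
    """Fusion candidates whose truth table exercises every filter rule.

    True fusions satisfy every rule (interchromosomal or >= 100 kb apart,
    >= 5 reads each matching >= 12 bases on both sides). Each decoy violates
    exactly one named rule: ``too_few_reads`` has exactly 4 good reads,
    ``short_match`` has enough reads but sub-threshold matches on one side,
    ``read_through`` is an intrachromosomal pair closer than 100 kb.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 1)
    candidates: list[FusionCandidate] = []
    truth_rows = []

    def good_reads(n: int) -> list[JunctionRead]:
        return [
            JunctionRead(int(rng.integers(12, 40)), int(rng.integers(12, 40)))
            for _ in range(n)
        ]

    for i in range(config.n_true_fusions):
        cid = f"TRUE{i + 1:02d}"
        if i % 2 == 0:  # interchromosomal
            p5 = FusionPartner(f"GENEA{i}", "chr7", int(rng.integers(1, 5_000_000)), "2")
            p3 = FusionPartner(f"GENEB{i}", "chr1", int(rng.integers(1, 5_000_000)), "2")
        else:  # intrachromosomal, comfortably beyond the read-through distance
            pos5 = int(rng.integers(1, 2_000_000))
            p5 = FusionPartner(f"GENEA{i}", "chr7", pos5, "2")
            p3 = FusionPartner(
                f"GENEB{i}", "chr7", pos5 + int(rng.integers(150_000, 5_000_000)), "2"
            )
        candidates.append(
            FusionCandidate(cid, p5, p3, good_reads(int(rng.integers(5, 12))))
        )
        truth_rows.append((cid, True, ""))

    for cls in _DECOY_CLASSES:
        for j in range(config.n_decoys_per_class):
            cid = f"DECOY_{cls.upper()}{j + 1:02d}"
            pos5 = int(rng.integers(1, 2_000_000))
            if cls == "read_through":
                p5 = FusionPartner(f"RT5_{j}", "chr3", pos5, "1")
                p3 = FusionPartner(
                    f"RT3_{j}", "chr3", pos5 + int(rng.integers(5_000, 100_000)), "1"
                )
                reads = good_reads(int(rng.integers(5, 10)))
            elif cls == "too_few_reads":
                p5 = FusionPartner(f"TF5_{j}", "chr3", pos5, "1")
                p3 = FusionPartner(f"TF3_{j}", "chr9", pos5 + 500_000, "1")
                reads = good_reads(4)  # forced by the '>4 reads' rule
            else:  # short_match
                p5 = FusionPartner(f"SM5_{j}", "chr3", pos5, "1")
                p3 = FusionPartner(f"SM3_{j}", "chr11", pos5 + 500_000, "1")
                reads = [
                    JunctionRead(int(rng.integers(12, 40)), int(rng.integers(4, 12)))
                    for _ in range(int(rng.integers(6, 10)))
                ]
            candidates.append(FusionCandidate(cid, p5, p3, reads))
            truth_rows.append((cid, False, cls))

    truth = pd.DataFrame(truth_rows, columns=["candidate_id", "is_true", "decoy_class"])
    return candidates, truth


def write_cohort(
    outdir: str | Path,
    beta: BetaMatrix,
    annotation: ProbeAnnotationTable,
    track: ReplicationTimingTrack,
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    truth: SyntheticTruth,
) -> dict[str, str]:
    """Write the six artifacts to a directory; returns a name -> path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta_matrix": outdir / "beta_matrix.tsv",
        "probe_annotation": outdir / "probe_annotation.tsv",
        "rt_track": outdir / "rt_track.bedgraph",
        "expression_matrix": outdir / "expression_matrix.tsv",
        "sample_sheet": outdir / "sample_sheet.tsv",
        "truth_probes": outdir / "truth_demethylated_probes.tsv",
        "truth_genes": outdir / "truth_planted_genes.tsv",
    }
    write_beta_matrix(beta, paths["beta_matrix"])
    write_probe_annotation(annotation, paths["probe_annotation"])
    write_rt_track(track, paths["rt_track"])
    write_expression_matrix(expr, paths["expression_matrix"])
    write_sample_sheet(sheet, paths["sample_sheet"])
    pd.DataFrame({"probe_id": sorted(truth.demeth_probes)}).to_csv(
        paths["truth_probes"], sep="\t", index=False
    )
    pd.DataFrame({"gene": list(truth.planted_genes)}).to_csv(
        paths["truth_genes"], sep="\t", index=False
    )
    return {k: str(v) for k, v in paths.items()}
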