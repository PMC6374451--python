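# Methods

`gcimp` implements the integrative methylation analysis used to characterize
DNA demethylation during malignant progression of IDH-mutant lower-grade
gliomas, as a reusable, tested pipeline. The biological setting: IDH-mutant
gliomas carry the glioma CpG-island methylator phenotype (G-CIMP), a
genome-wide hypermethylation state. On malignant progression a subset of
tumors partially loses this methylation ("G-CIMP-low"), and the loss is
concentrated in late-replicating, non-regulatory chromatin — the signature of
*passive* demethylation: DNMT1-mediated maintenance methylation failing to
keep up with accelerated cell division. The pipeline quantifies that
signature and searches for the exceptional genes whose promoter demethylation
does drive expression.

## Analysis model

**Differential methylation.** Per probe, the methylation level is the
β-value, the methylated-signal fraction in [0, 1]. Two groups (reference =
G-CIMP-high-like; comparison = demethylated) are compared with an unpaired
two-sided Welch t-test; p-values are adjusted across probes with the
Benjamini-Hochberg (BH) step-up. Δβ is always comparison minus reference, so
demethylation in the progressed group is negative. Two classification
profiles are provided: the *count* profile (q < 0.05, |Δβ| ≥ 0.2, both
directions) used for hypo/hyper tallies and the CpG-context breakdown, and a
stricter *replication-timing* profile (q < 0.05, Δβ ≤ −0.4, demethylation
only) that feeds the enrichment test.

**Clustering.** Probes on chrX/chrY or with a SNP within 5 bp of (or at) the
target CpG are excluded; the top 10,000 probes by sample standard deviation
(ddof = 1, pairwise missing exclusion, ties broken by probe id) are clustered
over samples with Euclidean distance and Ward linkage in the R `hclust`
"ward.D2" convention. `scipy.cluster.hierarchy.linkage(X, "ward")` on raw
observations computes exactly this criterion; the tests verify its merge
heights against an independent centroid-formula implementation. k is
user-supplied; there is no automatic model selection.

**Replication timing.** Probes take the signed replication-timing (RT) value
of the bedGraph interval covering their position (probe coordinates are
1-based, intervals 0-based half-open; a probe at position p lies in
[start, end) iff start ≤ p−1 < end). Category thresholds are the median of
the strictly negative values (late cut) and of the strictly positive values
(early cut); zeros belong to neither median. Boundaries are inclusive
upward: late iff rt ≤ late_cut, intermediate iff late_cut < rt ≤ early_cut,
early otherwise. Enrichment of a demethylated probe set in late domains is a
Pearson chi-square without continuity correction on the RT-category × set
table. Two comparator conventions are reported: `all` (demethylated set vs
all probes — the convention of published volcano-plot analyses, whose
columns overlap) and `complement` (vs the non-demethylated probes, disjoint
columns satisfying the independence assumption). The late-membership odds
ratio is always computed on the disjoint 2×2 (late vs not-late). When
several replicate RT tracks are supplied their values at each probe are
averaged over the tracks covering it before thresholding.

**Expression.** Per gene, Welch on log2(FPKM + ε), ε = 0.1 (a raw-scale test
mode exists), BH across genes; the fold change reported and gated is
raw-scale, (mean_cmp + ε)/(mean_ref + ε); up if q < 0.05 and FC > 2, down if
q < 0.05 and FC < 0.5. Log-scale testing stabilizes variance while the
raw-scale FC keeps the ">2 / <0.5" semantics of the thresholds.

**Promoter integration.** A probe is promoter-associated for a gene when it
carries TSS1500, TSS200, 5'UTR or 1stExon annotation for that gene (a probe
may serve several genes). Per gene, promoter probes are ranked by the
absolute between-group mean difference (a signed, demethylation-directed
ranking is available) and the top ceil(0.25·n) (≥ 1) are kept; the
per-sample promoter score is the mean β over those probes; scores are Welch-
tested between groups with BH across genes. Starburst classification:
*up_with_demethylation* iff expression q < 0.05, FC > 2, promoter q < 0.05
and promoter Δβ < −0.2 (symmetric for down/hyper). The per-probe scan
bypasses aggregation and lists, per upregulated gene, individual promoter
probes with q < 0.05 and Δβ < −0.2; at equal thresholds it is at least as
sensitive as the aggregated route.

**Fusion filtering.** A junction read supports a candidate when it matches
≥ 12 bases on *both* sides of the junction; a call requires strictly more
than 4 supporting reads; intrachromosomal candidates closer than 100,000 bp
are rejected as read-through artifacts (the distance rule does not apply
across chromosomes). Boundary semantics follow the printed wording: "at
least 12" is inclusive, "more than four" is exclusive. By default only
reads passing the match rule count toward the read threshold (the stricter
of the two possible readings; configurable). Failed-rule attribution is
deterministic: `read_through` when applicable and violated; for a read
deficit, `min_reads` when the candidate simply has ≤ 4 reads, `min_match`
when it has enough reads but match filtering drops it under the threshold.

## Synthetic cohorts

The generator (`gcimp.simulate`) produces, from one seed, every input the
pipeline consumes plus ground truth. Default study conditions:

| parameter | default | meaning |
|---|---|---|
| n_samples_reference / n_samples_demeth | 20 / 9 | reference vs progressed group, the real contrast at reduced scale |
| n_probes / n_genes | 10,000 / 1,000 | desk-scale array and transcriptome |
| chromosome | one synthetic chromosome, 40 × 100 kb RT domains | alternating early (+1.0) / late (−1.0) blocks; `sine` option yields a continuum with a real intermediate class |
| context fractions | Island 0.30, Shore 0.15, Shelf 0.10, OpenSea 0.45 | island probes are additionally 4× enriched in promoter features |
| reference mean β | Island 0.80 … OpenSea 0.70 (± 0.05 per-probe jitter) | hypermethylated G-CIMP-like baseline |
| planted_demeth_delta | 0.45 | planted β loss; exceeds the 0.4 gate of the RT profile so the enrichment path is exercised |
| late_demeth_prob / early_demeth_prob | 0.30 / 0.02 | per-probe planting probability by RT sign — the passive-demethylation signature |
| context_demeth_weight | Island 0.15, Shore 0.5, Shelf 0.8, OpenSea 1.0 | island CpGs resist demethylation, reproducing the open-sea bias of real demethylated probes |
| beta_noise_concentration | 60 | per-sample β ~ Beta(μν, (1−μ)ν); sd ≈ 0.06 at μ = 0.7, a realistic within-group spread for variable probes |
| n_planted_promoter_genes | 3 | genes given both promoter demethylation and expression up-shift — the scale of signal the starburst step is meant to find |
| planted_expression_log2fc | 2.0 | FC 4 for planted genes; expression is log-normal (base log2 mean 3, sd 1.5; per-sample noise sd 0.5) |
| contamination_fraction | 0.0 | optional mixing of the comparison group toward a normal-brain-like profile (unmethylated islands, methylated open sea); no published value exists to calibrate it |
| fusions | 3 true + 1 decoy per class | decoys each violate exactly one filter rule |

Truth records group labels, the planted probe set (defined empty when the
planted Δβ is 0 — an unshifted probe is not demethylated), each probe's RT
category at generation, the planted genes, and the fusion truth table.

What the generator does **not** emulate: probe-type (Infinium I/II) chemistry
differences, spatial correlation of β along the genome, cross-probe
correlation within samples, tumor-purity gradients (beyond the single mixing
parameter), copy-number effects on intensity, batch structure, and
heavy-tailed outlier samples. Passing tests therefore demonstrate
correctness of the statistical machinery and recoverability of the planted
structure, not performance on the full messiness of real arrays.

## Numerical and design choices

- Missing values are "NA" on disk, NaN in memory, excluded pairwise
  everywhere; nothing is imputed. Untestable features keep missing p/q and
  label `ns` rather than being dropped.
- The BH step-up is implemented directly (the missing-passthrough contract
  is part of the module surface) and is checked against
  `statsmodels.stats.multitest` property-wise in the tests.
- Ranking tie-breaks (SD selection, promoter top-25%) are lexicographic on
  probe id, making all selections order-independent and reproducible.
- Matrix writers emit shortest-repr floats so write→read round trips are
  bit-exact; derived result tables use 6 significant digits for diffability.
- On a two-level synthetic RT track the early-domain probes sit exactly at
  the early cut and are categorized intermediate by the inclusive bound; the
  enrichment table then has an empty `early` row, which is dropped with the
  degrees of freedom recomputed (warning logged). Zero column margins (an
  empty demethylated set) make the chi-square undefined: reported as NaN.
- All randomness flows from a single config seed; replicate studies derive
  child seeds arithmetically (kept below 2^31).

## Known limitations

- **Extreme-tail calibration of the Welch test.** β noise is bounded and
  skewed; with 9 comparison samples the normal-theory Welch p-value is
  inflated roughly 2–3× at the p ≈ 5×10⁻⁶ tail (measured by direct Monte
  Carlo under the generator's own noise model). Consequently, on a
  completely null cohort of 10,000 probes the probability that BH at
  q < 0.05 makes at least one (false) discovery is ~0.2–0.3 rather than the
  nominal ≤ 0.05, and the empirical false-discovery proportion over null
  replicates exceeds the BH guarantee. The corresponding suite test asserts
  the guarantee as stated and documents the failure. The spurious null
  discoveries have |Δβ| ≈ 0.07–0.08 and never survive the |Δβ| ≥ 0.2
  effect-size gate, so classified hypo/hyper counts on null data remain 0.
  Variance-moderated (empirical-Bayes) testing would repair the tail but is
  deliberately out of scope; the plain Welch test is the method this
  pipeline exists to reproduce.
- The published RT category cuts (−0.4599 / 0.80074) derive from a specific
  neural-progenitor Repli-seq profile (GEO GSE63428) evaluated at 450K probe
  positions; reproducing them requires those external downloads. The suite
  contains the corresponding check, runnable by placing the track and probe
  coordinates under `data/reference/`; without them it reports the missing
  inputs as a failure rather than silently skipping.
- The `all` comparator mode of the enrichment test uses overlapping columns
  (the demethylated set is contained in "all probes"), which violates the
  chi-square independence assumption; it is retained for fidelity to common
  practice, and the `complement` mode is always computed alongside.
- Medians for the RT thresholds are computed over probe-position values, not
  over all genomic bins of the track; with non-uniform probe placement the
  two differ.
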