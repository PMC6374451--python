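"""Fusion-transcript junction filtering.

Candidates come from an upstream split-read caller as a table of junction
reads. A read supports a fusion when it matches at least ``min_match`` bases
on *both* sides of the junction (conjunction). A candidate is called when

* strictly more than ``min_reads_exclusive`` reads support it ("more than
  four reads" means >= 5), and
* when both partners lie on the same chromosome, their breakpoints are at
  least ``min_intra_distance`` bp apart (read-through suppression; the rule
  does not apply to interchromosomal candidates).

By default only reads passing the per-read match rule are counted (the
stricter reading); ``count_matching_only=False`` counts all spanning reads
and instead requires at least one matching read.

Failed-rule attribution is unambiguous: ``read_through`` when the distance
rule applies and fails; for a read-count deficit, ``min_reads`` when the
candidate simply has too few reads, ``min_match`` when it has enough reads
but match filtering drops it below the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .io import write_table


@dataclass(frozen=True)
class JunctionRead:
    matched_bases_5: int
    matched_bases_3: int

    def __post_init__(self) -> None:
        if self.matched_bases_5 < 0 or self.matched_bases_3 < 0:
            raise ValueError("matched base counts must be >= 0")


@dataclass(frozen=True)
class FusionPartner:
    gene: str
    chromosome: str
    position: int  # breakpoint, 1-based
    exon: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"breakpoint position must be >= 1: {self.position}")


@dataclass
class FusionCandidate:
    candidate_id: str
    partner5: FusionPartner
    partner3: FusionPartner
    reads: list[JunctionRead] = field(default_factory=list)

    @property
    def intrachromosomal(self) -> bool:
        return self.partner5.chromosome == self.partner3.chromosome

    @property
    def distance(self) -> int | None:
        if not self.intrachromosomal:
            return None
        return abs(self.partner5.position - self.partner3.position)


@dataclass
class FusionCall:
    candidate_id: str
    passed: bool
    n_supporting_reads: int
    failed_rules: tuple[str, ...]


def filter_fusions(
    candidates: list[FusionCandidate],
    min_match: int = 12,
    min_reads_exclusive: int = 4,
    min_intra_distance: int = 100_000,
    count_matching_only: bool = True,
) -> list[FusionCall]:
    calls = []
    for cand in candidates:
        matching = [
            r
            for r in cand.reads
            if r.matched_bases_5 >= min_match and r.matched_bases_3 >= min_match
        ]
        n_support = len(matching)
        failed: list[str] = []
        if count_matching_only:
            if n_support <= min_reads_exclusive:
                failed.append(
                    "min_reads" if len(cand.reads) <= min_reads_exclusive else "min_match"
                )
        else:
            if len(cand.reads) <= min_reads_exclusive:
                failed.append("min_reads")
            elif n_support == 0:
                failed.append("min_match")
        dist = cand.distance
        if dist is not None and dist < min_intra_distance:
            failed.append("read_through")
        calls.append(
            FusionCall(
                candidate_id=cand.candidate_id,
                passed=not failed,
                n_supporting_reads=n_support,
                failed_rules=tuple(failed),
            )
        )
    return calls


# -- tabular interchange -----------------------------------------------------

_CANDIDATE_COLUMNS = [
    "candidate_id",
    "gene5",
    "chrom5",
    "pos5",
    "exon5",
    "gene3",
    "chrom3",
    "pos3",
    "exon3",
    "matched_bases_5",
    "matched_bases_3",
]


def candidates_to_table(candidates: list[FusionCandidate]) -> pd.DataFrame:
    """One row per junction read."""
    rows = []
    for c in candidates:
        for r in c.reads:
            rows.append(
                (
                    c.candidate_id,
                    c.partner5.gene, c.partner5.chromosome, c.partner5.position,
                    c.partner5.exon,
                    c.partner3.gene, c.partner3.chromosome, c.partner3.position,
                    c.partner3.exon,
                    r.matched_bases_5, r.matched_bases_3,
                )
            )
        if not c.reads:  # zero-read candidate: keep one row with missing read fields
            rows.append(
                (
                    c.candidate_id,
                    c.partner5.gene, c.partner5.chromosome, c.partner5.position,
                    c.partner5.exon,
                    c.partner3.gene, c.partner3.chromosome, c.partner3.position,
                    c.partner3.exon,
                    -1, -1,
                )
            )
    return pd.DataFrame(rows, columns=_CANDIDATE_COLUMNS)


def candidates_from_table(df: pd.DataFrame) -> list[FusionCandidate]:
    out = []
    for cid, sub in df.groupby("candidate_id", sort=True):
        first = sub.iloc[0]
        reads = [
            JunctionRead(int(r.matched_bases_5), int(r.matched_bases_3))
            for r in sub.itertuples()
            if int(r.matched_bases_5) >= 0
        ]
        out.append(
            FusionCandidate(
                candidate_id=str(cid),
                partner5=FusionPartner(
                    str(first["gene5"]), str(first["chrom5"]),
                    int(first["pos5"]), str(first["exon5"]),
                ),
                partner3=FusionPartner(
                    str(first["gene3"]), str(first["chrom3"]),
                    int(first["pos3"]), str(first["exon3"]),
                ),
                reads=reads,
            )
        )
    return out


def read_fusion_candidates(path: str | Path) -> list[FusionCandidate]:
    df = pd.read_csv(path, sep="\t", dtype={"exon5": str, "exon3": str},
                     keep_default_na=False)
    return candidates_from_table(df)


def write_fusion_candidates(candidates: list[FusionCandidate], path: str | Path) -> None:
    write_table(candidates_to_table(candidates), path)


def calls_to_table(calls: list[FusionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "candidate_id": [c.candidate_id for c in calls],
            "pass": [c.passed for c in calls],
            "n_supporting_reads": [c.n_supporting_reads for c in calls],
            "failed_rules": [";".join(c.failed_rules) for c in calls],
        }
    )
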