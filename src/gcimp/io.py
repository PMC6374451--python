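"""Readers, writers and validated containers for the pipeline's external formats.

Everything tabular travels as TSV with a header row; the replication-timing
track is standard 4-column bedGraph (0-based, half-open). Probe positions are
1-based (array-manifest convention). A probe at 1-based position ``p`` falls in
a track interval ``[start, end)`` iff ``start <= p - 1 < end``; that conversion
is defined here once and used everywhere.

Missing values are spelled ``NA`` on disk and carried as ``NaN`` in memory.
They are excluded pairwise in downstream statistics, never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING_TOKEN = "NA"

#: CpG-island contexts after normalization. The manifest's N_Shore/S_Shore and
#: N_Shelf/S_Shelf are collapsed to Shore/Shelf; a blank context means OpenSea.
CPG_CONTEXTS = ("Island", "Shore", "Shelf", "OpenSea")

#: Feature groups that place a probe in a gene's promoter.
PROMOTER_FEATURES = ("TSS1500", "TSS200", "5'UTR", "1stExon")

_CONTEXT_ALIASES = {
    "island": "Island",
    "n_shore": "Shore",
    "s_shore": "Shore",
    "shore": "Shore",
    "n_shelf": "Shelf",
    "s_shelf": "Shelf",
    "shelf": "Shelf",
    "opensea": "OpenSea",
    "open sea": "OpenSea",
    "open_sea": "OpenSea",
    "": "OpenSea",
}


class FormatError(ValueError):
    """A file violated the format contract (bad value, duplicate id, ...)."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dups[:5]}")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation β-values.

    β is the methylated-signal fraction at a CpG, in [0, 1]; NaN marks a
    missing (e.g. detection-failed) measurement.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_unique(self.values.index, "probe ids")
        _check_unique(self.values.columns, "sample ids")
        bad = (self.values < 0) | (self.values > 1)
        if bad.any().any():
            probe = bad.any(axis=1).idxmax()
            sample = bad.loc[probe].idxmax()
            raise FormatError(
                f"beta value out of [0,1] at probe {probe!r}, sample {sample!r}: "
                f"{self.values.loc[probe, sample]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of FPKM values (non-negative; NaN = missing)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        bad = self.values < 0
        if bad.any().any():
            gene = bad.any(axis=1).idxmax()
            sample = bad.loc[gene].idxmax()
            raise FormatError(
                f"negative FPKM at gene {gene!r}, sample {sample!r}: "
                f"{self.values.loc[gene, sample]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ProbeAnnotationTable:
    """Per-probe genomic annotation.

    Columns: ``probe_id`` (index), ``chromosome``, ``position`` (1-based CpG
    coordinate), ``cpg_context`` (one of :data:`CPG_CONTEXTS`),
    ``promoter_features`` (``FEATURE:GENE`` pairs joined by ``;``, possibly
    empty — a probe may serve several genes), ``snp_within_5bp`` and
    ``sex_chromosome`` boolean flags.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        _check_unique(t.index, "probe ids")
        required = {
            "chromosome",
            "position",
            "cpg_context",
            "promoter_features",
            "snp_within_5bp",
            "sex_chromosome",
        }
        missing = required - set(t.columns)
        if missing:
            raise FormatError(f"probe annotation missing columns: {sorted(missing)}")
        if (t["position"] < 1).any():
            bad = t.index[t["position"] < 1][:5].tolist()
            raise FormatError(f"probe position < 1 for {bad}")
        unknown = set(t["cpg_context"]) - set(CPG_CONTEXTS)
        if unknown:
            raise FormatError(f"unknown CpG context values: {sorted(unknown)}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def promoter_map(self) -> dict[str, list[tuple[str, str]]]:
        """Parse ``promoter_features`` into probe -> [(feature, gene), ...]."""
        out: dict[str, list[tuple[str, str]]] = {}
        for probe, spec in self.table["promoter_features"].items():
            if not spec:
                continue
            pairs = []
            for item in str(spec).split(";"):
                item = item.strip()
                if not item:
                    continue
                feature, _, gene = item.partition(":")
                if feature not in PROMOTER_FEATURES or not gene:
                    raise FormatError(
                        f"bad promoter feature {item!r} on probe {probe!r}"
                    )
                pairs.append((feature, gene))
            if pairs:
                out[str(probe)] = pairs
        return out


@dataclass
class ReplicationTimingTrack:
    """Genomic intervals with signed replication-timing values.

    Positive values mark early-replicating, negative late-replicating
    chromatin. Intervals are 0-based half-open, sorted and non-overlapping
    within each chromosome.
    """

    intervals: pd.DataFrame  # columns: chromosome, start, end, rt_value
    _index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        init=False, repr=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        t = self.intervals
        required = {"chromosome", "start", "end", "rt_value"}
        if set(t.columns) != required:
            t = t[["chromosome", "start", "end", "rt_value"]]
        bad = t["start"] >= t["end"]
        if bad.any():
            row = t[bad].iloc[0]
            raise FormatError(
                f"interval start >= end: {row['chromosome']}:"
                f"{row['start']}-{row['end']}"
            )
        t = t.sort_values(["chromosome", "start"], kind="mergesort").reset_index(
            drop=True
        )
        for chrom, sub in t.groupby("chromosome", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            overlap = starts[1:] < ends[:-1]
            if overlap.any():
                i = int(np.flatnonzero(overlap)[0])
                raise FormatError(
                    f"overlapping intervals on {chrom}: "
                    f"[{starts[i]},{ends[i]}) and [{starts[i + 1]},{ends[i + 1]})"
                )
            self._index[str(chrom)] = (
                starts,
                ends,
                sub["rt_value"].to_numpy(float),
            )
        self.intervals = t

    def values_at(self, chromosomes: Sequence[str], positions: Sequence[int]) -> np.ndarray:
        """RT value covering each 1-based position; NaN where no interval does."""
        chroms = np.asarray(chromosomes, dtype=object)
        pos0 = np.asarray(positions, dtype=np.int64) - 1  # to 0-based
        out = np.full(len(pos0), np.nan)
        for chrom in pd.unique(chroms):
            if chrom not in self._index:
                continue
            starts, ends, vals = self._index[str(chrom)]
            mask = chroms == chrom
            idx = np.searchsorted(starts, pos0[mask], side="right") - 1
            ok = (idx >= 0) & (pos0[mask] < ends[np.clip(idx, 0, len(ends) - 1)])
            res = np.full(mask.sum(), np.nan)
            res[ok] = vals[idx[ok]]
            out[mask] = res
        return out


@dataclass
class SampleSheet:
    """Sample -> group assignment; optional pair_id links initial/recurrent pairs."""

    table: pd.DataFrame  # index sample_id; columns group_label, pair_id

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample ids")
        if "group_label" not in self.table.columns:
            raise FormatError("sample sheet missing 'group_label' column")
        if "pair_id" not in self.table.columns:
            self.table = self.table.assign(pair_id="")

    def samples_in_group(self, group: str) -> list[str]:
        mask = self.table["group_label"] == group
        return list(self.table.index[mask])

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        na_values=[MISSING_TOKEN],
        keep_default_na=False,
        **kwargs,
    )


def read_beta_matrix(path: str | Path) -> BetaMatrix:
    """Read a probes x samples β-value TSV (first column = probe ids)."""
    df = _read_tsv(path, index_col=0)
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric beta value in {path}: {exc}") from exc
    return BetaMatrix(df)


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples FPKM TSV (first column = gene ids)."""
    df = _read_tsv(path, index_col=0)
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric FPKM value in {path}: {exc}") from exc
    return ExpressionMatrix(df)


def normalize_cpg_context(raw: str) -> str:
    key = str(raw).strip().lower()
    if key in ("nan", "na"):
        key = ""
    if key not in _CONTEXT_ALIASES:
        raise FormatError(f"unknown CpG context {raw!r}")
    return _CONTEXT_ALIASES[key]


def _parse_bool(column: pd.Series) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False}
    out = column.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        bad = column[out.isna()].iloc[0]
        raise FormatError(f"cannot parse boolean flag {bad!r}")
    return out.astype(bool)


def read_probe_annotation(path: str | Path) -> ProbeAnnotationTable:
    df = _read_tsv(path, index_col=0, dtype=str)
    df["position"] = pd.to_numeric(df["position"]).astype(np.int64)
    df["cpg_context"] = df["cpg_context"].fillna("").map(normalize_cpg_context)
    df["promoter_features"] = df["promoter_features"].fillna("")
    df["snp_within_5bp"] = _parse_bool(df["snp_within_5bp"].fillna("false"))
    df["sex_chromosome"] = _parse_bool(df["sex_chromosome"].fillna("false"))
    return ProbeAnnotationTable(df)


def read_rt_track(path: str | Path) -> ReplicationTimingTrack:
    """Read a 4-column bedGraph replication-timing track."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chromosome", "start", "end", "rt_value"],
        dtype={"chromosome": str},
    )
    if df[["start", "end", "rt_value"]].isna().any().any():
        raise FormatError(f"malformed bedGraph line in {path}")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return ReplicationTimingTrack(df)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = _read_tsv(path, index_col=0, dtype=str)
    df["group_label"] = df["group_label"].fillna("")
    if "pair_id" in df.columns:
        df["pair_id"] = df["pair_id"].fillna("")
    return SampleSheet(df)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_beta_matrix(matrix: BetaMatrix, path: str | Path) -> None:
    # shortest-repr floats: deterministic, diffable, and bit-exact on re-read
    matrix.values.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, index_label="probe_id")


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, index_label="gene_id")


def write_probe_annotation(annotation: ProbeAnnotationTable, path: str | Path) -> None:
    cols = [
        "chromosome",
        "position",
        "cpg_context",
        "promoter_features",
        "snp_within_5bp",
        "sex_chromosome",
    ]
    annotation.table[cols].to_csv(path, sep="\t", index_label="probe_id")


def write_rt_track(track: ReplicationTimingTrack, path: str | Path) -> None:
    track.intervals.to_csv(path, sep="\t", header=False, index=False)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    self_cols = ["group_label", "pair_id"]
    sheet.table[self_cols].to_csv(path, sep="\t", index_label="sample_id")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a derived result table with fixed 6-significant-digit floats."""
    df.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, index=index, float_format="%.6g")


def format_sig(x: float, digits: int = 6) -> str:
    """Format one float to a fixed number of significant digits."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return MISSING_TOKEN
    return f"{x:.{digits}g}"
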