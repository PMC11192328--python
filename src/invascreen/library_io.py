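"""Readers, writers and container types for sgRNA libraries and count matrices.

A pooled CRISPRi screen is described by two flat files: a *library table*
mapping each sgRNA to its targeted gene (non-targeting controls carry a
sentinel gene id, ``NTC`` by default) and a *count matrix* of sequencing
read counts per sgRNA and sample.  Samples are either the pre-invasion
``T0`` population or the harvested ``endpoint`` population of one screen
replicate.  An optional exact-match counter assigns raw FASTQ reads to
library protospacers.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

DEFAULT_NTC_SENTINEL = "NTC"
CONDITIONS = ("T0", "endpoint")

_SAMPLE_RE = re.compile(r"^(T0|endpoint)_r(\d+)$")


class LibraryError(ValueError):
    """Raised when an sgRNA library violates its invariants."""


class CountMatrixError(ValueError):
    """Raised when a count matrix violates its invariants."""


@dataclass(frozen=True)
class LibraryTable:
    """Validated sgRNA library: sgrna_id, gene_id, protospacer, is_ntc.

    ``is_ntc`` is true exactly when ``gene_id`` equals the NTC sentinel.
    Every targeting gene must carry at least two sgRNAs so that gene-level
    scoring has a sample to rank.
    """

    records: pd.DataFrame
    ntc_sentinel: str = DEFAULT_NTC_SENTINEL

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", _validate_library(self.records, self.ntc_sentinel))

    @property
    def sgrna_ids(self) -> pd.Index:
        return pd.Index(self.records["sgrna_id"])

    @property
    def genes(self) -> list[str]:
        mask = ~self.records["is_ntc"]
        return sorted(self.records.loc[mask, "gene_id"].unique())

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_ntc(self) -> int:
        return int(self.records["is_ntc"].sum())

    @property
    def ntc_ids(self) -> pd.Index:
        return pd.Index(self.records.loc[self.records["is_ntc"], "sgrna_id"])

    @property
    def protospacer_length(self) -> int:
        return len(self.records["protospacer"].iloc[0]) if len(self.records) else 0

    def gene_map(self) -> pd.Series:
        """sgrna_id -> gene_id (NTC rows keep the sentinel)."""
        return self.records.set_index("sgrna_id")["gene_id"]

    def __len__(self) -> int:
        return len(self.records)


def _validate_library(df: pd.DataFrame, sentinel: str) -> pd.DataFrame:
    required = ["sgrna_id", "gene_id", "protospacer"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LibraryError(f"library table missing columns: {missing}")
    df = df.copy()
    df["sgrna_id"] = df["sgrna_id"].astype(str)
    df["gene_id"] = df["gene_id"].astype(str)
    df["protospacer"] = df["protospacer"].astype(str).str.upper()

    dup = df.loc[df["sgrna_id"].duplicated(), "sgrna_id"].unique()
    if len(dup):
        raise LibraryError(f"duplicate sgrna_id values: {sorted(dup)[:10]}")

    bad = ~df["protospacer"].str.fullmatch("[ACGT]+")
    if bad.any():
        row = df.index[bad][0]
        raise LibraryError(
            f"non-ACGT protospacer at row {row}: "
            f"{df.loc[row, 'sgrna_id']} = {df.loc[row, 'protospacer']!r}"
        )
    lengths = df["protospacer"].str.len().unique()
    if len(lengths) > 1:
        raise LibraryError(f"protospacer lengths not uniform: {sorted(lengths)}")

    if "is_ntc" in df.columns:
        df["is_ntc"] = df["is_ntc"].astype(bool)
        mismatch = df["is_ntc"] != (df["gene_id"] == sentinel)
        if mismatch.any():
            raise LibraryError(
                "is_ntc flag inconsistent with gene_id sentinel for "
                f"{df.loc[mismatch, 'sgrna_id'].tolist()[:10]}"
            )
    else:
        df["is_ntc"] = df["gene_id"] == sentinel

    sizes = df.loc[~df["is_ntc"]].groupby("gene_id").size()
    small = sizes[sizes < 2]
    if len(small):
        raise LibraryError(
            f"genes with fewer than 2 sgRNAs (cannot be scored): {small.index.tolist()[:10]}"
        )
    df = df.reset_index(drop=True)
    logger.info(
        "library: %d sgRNAs, %d genes, %d non-targeting controls",
        len(df), sizes.shape[0], int(df["is_ntc"].sum()),
    )
    return df


def read_library(path, ntc_sentinel: str = DEFAULT_NTC_SENTINEL) -> LibraryTable:
    """Read a tab-separated sgRNA library with header sgrna_id, gene_id, protospacer."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return LibraryTable(df, ntc_sentinel=ntc_sentinel)


def write_library(library: LibraryTable, path) -> None:
    library.records[["sgrna_id", "gene_id", "protospacer"]].to_csv(path, sep="\t", index=False)


def sample_name(condition: str, replicate: int) -> str:
    if condition not in CONDITIONS:
        raise CountMatrixError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    return f"{condition}_r{int(replicate)}"


def parse_sample_name(name: str) -> tuple[str, int]:
    m = _SAMPLE_RE.match(name)
    if m is None:
        raise CountMatrixError(
            f"sample column {name!r} does not follow the '<condition>_r<replicate>' convention"
        )
    return m.group(1), int(m.group(2))


@dataclass(frozen=True)
class CountMatrix:
    """sgRNA x sample read counts plus per-sample condition/replicate metadata.

    Sample columns follow the ``{condition}_r{replicate}`` naming convention,
    e.g. ``T0_r1`` / ``endpoint_r1``.  Zero-sum sample columns are flagged
    unusable rather than rejected, so a failed sample does not block reading.
    """

    counts: pd.DataFrame
    unusable_samples: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        counts, unusable = _validate_counts(self.counts)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "unusable_samples", unusable)

    @property
    def samples(self) -> pd.DataFrame:
        rows = []
        for name in self.counts.columns:
            condition, replicate = parse_sample_name(name)
            rows.append({"sample_id": name, "condition": condition, "replicate": replicate})
        return pd.DataFrame(rows).set_index("sample_id")

    @property
    def replicates(self) -> list[int]:
        return sorted({parse_sample_name(c)[1] for c in self.counts.columns})

    def select_replicate(self, replicate: int) -> "CountMatrix":
        """The T0 + endpoint column pair of one screen replicate."""
        cols = [c for c in self.counts.columns if parse_sample_name(c)[1] == replicate]
        conditions = {parse_sample_name(c)[0] for c in cols}
        missing = set(CONDITIONS) - conditions
        if missing:
            raise CountMatrixError(f"replicate {replicate} lacks sample(s): {sorted(missing)}")
        return CountMatrix(self.counts[cols])

    def column(self, condition: str, replicate: int) -> pd.Series:
        return self.counts[sample_name(condition, replicate)]


def _validate_counts(counts: pd.DataFrame) -> tuple[pd.DataFrame, tuple[str, ...]]:
    counts = counts.copy()
    counts.index = counts.index.astype(str)
    counts.index.name = "sgrna_id"
    for name in counts.columns:
        parse_sample_name(name)
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()].unique().tolist()
        raise CountMatrixError(f"duplicate sgrna_id rows: {dup[:10]}")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise CountMatrixError("counts must be numeric")
    if (values < 0).any():
        raise CountMatrixError("negative counts are not allowed")
    if not np.allclose(values, np.round(values)):
        raise CountMatrixError("counts must be integers")
    counts = counts.astype(np.int64)
    zero = counts.sum(axis=0) == 0
    unusable = tuple(counts.columns[zero])
    for name in unusable:
        logger.warning("sample %s has zero total counts; flagged unusable", name)
    return counts, unusable


def read_counts(path, library: LibraryTable | None = None) -> CountMatrix:
    """Read a count-matrix TSV (first column sgrna_id, one column per sample).

    When a library is given, rows absent from the library are a hard error
    (the orphans are listed) and missing library sgRNAs are an error too,
    since phenotype computation assumes the two agree.
    """
    df = pd.read_csv(path, sep="\t", index_col="sgrna_id")
    cm = CountMatrix(df)
    if library is not None:
        orphans = cm.counts.index.difference(library.sgrna_ids)
        if len(orphans):
            raise CountMatrixError(f"sgrna_id rows absent from library: {orphans.tolist()[:10]}")
        absent = library.sgrna_ids.difference(cm.counts.index)
        if len(absent):
            raise CountMatrixError(f"library sgRNAs missing from counts: {absent.tolist()[:10]}")
    return cm


def write_counts(cm: CountMatrix, path) -> None:
    cm.counts.to_csv(path, sep="\t", index=True)


def count_reads(
    fastq_path,
    library: LibraryTable,
    match_offset: int = 0,
    match_length: int | None = None,
) -> tuple[pd.Series, int]:
    """Assign reads to sgRNAs by exact substring match at a fixed 0-based offset.

    Returns one count column (indexed like the library) and the number of
    unassigned reads; assigned + unassigned equals the number of input reads.
    Gzip input is detected by the ``.gz`` suffix.
    """
    if len(library) == 0:
        raise LibraryError("cannot count reads against an empty library")
    if match_length is None:
        match_length = library.protospacer_length
    if match_offset < 0 or match_length <= 0:
        raise ValueError("match_offset must be >= 0 and match_length > 0")
    lookup = dict(zip(library.records["protospacer"], library.records["sgrna_id"]))
    counts = dict.fromkeys(library.sgrna_ids, 0)
    unassigned = 0
    opener = gzip.open if str(fastq_path).endswith(".gz") else open
    with opener(fastq_path, "rt") as handle:
        for _title, seq, _qual in FastqGeneralIterator(handle):
            key = seq[match_offset : match_offset + match_length].upper()
            sgrna = lookup.get(key)
            if sgrna is None:
                unassigned += 1
            else:
                counts[sgrna] += 1
    return pd.Series(counts, name="count"), unassigned
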