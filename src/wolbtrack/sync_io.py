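"""Readers and writers for the PoPoolation2 sync format and the package's TSV tables.

The sync format is the de-facto interchange format for Pool-Seq allele
counts: one line per site with ``contig, 1-based position, reference base``
followed by one ``A:T:C:G:N:del`` count string per sequenced pool. Counts
are strandless and coordinates are 1-based inclusive.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column order of a sync count string.
SYNC_ALLELES = ("A", "T", "C", "G", "N", "del")

#: Index of each base in the count vector.
ALLELE_INDEX = {a: i for i, a in enumerate(SYNC_ALLELES)}


class SyncParseError(ValueError):
    """Raised when a sync line cannot be parsed; message names the line."""


@dataclass
class SyncRecord:
    """Per-site nucleotide counts for one or more pools.

    Parameters
    ----------
    contig : str
        Reference sequence name.
    position : int
        1-based position on the contig.
    reference : str
        Reference base at the site.
    counts : ndarray of shape (n_replicates, 6)
        Non-negative integer counts in ``A, T, C, G, N, del`` order,
        one row per pool in file order.
    """

    contig: str
    position: int
    reference: str
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim == 1:
            self.counts = self.counts.reshape(1, -1)
        if self.counts.shape[1] != 6:
            raise ValueError("counts must have six columns (A,T,C,G,N,del)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[0]

    def coverage(self, replicate: int) -> int:
        """Total read count (all six categories) for one pool."""
        return int(self.counts[replicate].sum())

    def allele_count(self, replicate: int, allele: str) -> int:
        return int(self.counts[replicate, ALLELE_INDEX[allele]])


def _open_maybe_gzip(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_count_string(token: str) -> list[int]:
    parts = token.split(":")
    if len(parts) != 6:
        raise ValueError(f"expected six ':'-separated counts, got {token!r}")
    return [int(p) for p in parts]


def read_sync(path: str | Path) -> list[SyncRecord]:
    """Read a sync file (plain or gzip) into a list of :class:`SyncRecord`.

    Replicate (pool) order is preserved. Malformed count strings raise
    :class:`SyncParseError` naming the offending line number. An empty
    file yields an empty list with a logged warning.
    """
    records: list[SyncRecord] = []
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise SyncParseError(
                    f"{path}:{lineno}: expected >=4 tab-separated columns, got {len(fields)}"
                )
            contig, pos_s, ref = fields[0], fields[1], fields[2]
            try:
                position = int(pos_s)
                counts = [_parse_count_string(tok) for tok in fields[3:]]
            except ValueError as exc:
                raise SyncParseError(f"{path}:{lineno}: {exc}") from exc
            records.append(SyncRecord(contig, position, ref, np.array(counts)))
    if not records:
        logger.warning("sync file %s contained no records", path)
    return records


def write_sync(records: Iterable[SyncRecord], path: str | Path) -> None:
    """Write records in sync format (gzip if the path ends in .gz)."""
    with _open_maybe_gzip(path, "wt") as fh:
        for rec in records:
            tokens = [":".join(str(c) for c in row) for row in rec.counts]
            fh.write("\t".join([rec.contig, str(rec.position), rec.reference, *tokens]) + "\n")


def index_records(records: Sequence[SyncRecord]) -> dict[tuple[str, int], SyncRecord]:
    """Index sync records by (contig, 1-based position)."""
    return {(r.contig, r.position): r for r in records}


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

CLADE_TABLE_COLUMNS = ["contig", "position", "allele", "clade"]
COVERAGE_COLUMNS = [
    "sample_id",
    "mean_depth_nuclear",
    "mean_depth_wolbachia",
    "mean_depth_mtdna",
    "wolbachia_breadth",
]


class SchemaError(ValueError):
    """Raised when a TSV header does not match the documented schema."""


def _check_header(df: pd.DataFrame, required: Sequence[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}; found {list(df.columns)}")


def read_clade_table(path: str | Path) -> pd.DataFrame:
    """Read a diagnostic-SNP table (columns contig/position/allele/clade)."""
    df = pd.read_csv(path, sep="\t")
    _check_header(df, CLADE_TABLE_COLUMNS, path)
    return df[CLADE_TABLE_COLUMNS].astype({"position": int})


def write_clade_table(df: pd.DataFrame, path: str | Path) -> None:
    df[CLADE_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_coverage_table(path: str | Path) -> pd.DataFrame:
    """Read per-sample coverage summaries (depths and Wolbachia breadth)."""
    df = pd.read_csv(path, sep="\t")
    _check_header(df, COVERAGE_COLUMNS, path)
    return df


def read_fasta_alignment(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA haplotype panel as {name: sequence}."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_label_map(path: str | Path) -> dict[str, str]:
    """Read a haplotype-to-clade label mapping TSV (columns name/clade)."""
    df = pd.read_csv(path, sep="\t")
    _check_header(df, ["name", "clade"], path)
    return dict(zip(df["name"].astype(str), df["clade"].astype(str)))


def replicate_names(n: int, prefix: str = "r") -> list[str]:
    """Default pool labels r1..rn used when a sync file names none."""
    return [f"{prefix}{i + 1}" for i in range(n)]
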