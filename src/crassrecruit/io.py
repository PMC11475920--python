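"""Readers and writers for the plain-text formats the pipeline touches.

The pipeline consumes reference genomes (FASTA), virome reads (FASTQ),
read-vs-genome alignments in the standard 12-column tabular dialect
(``qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore``, optionally extended with a 13th ``qlen`` column), and
per-virome metadata tables (TSV with header).  All coordinates are 1-based
inclusive; an alignment row with ``sstart > send`` is a minus-strand hit
and is preserved as written.

The 12-column dialect does not carry the query length, which the
query-coverage filter needs.  ``read_tabular_alignments`` therefore resolves
a ``qlen`` for every row from one of three sources: a 13th column, a
FASTA/FASTQ file of the reads, or a constant.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO


class FastaError(ValueError):
    """Malformed or invalid FASTA input."""


class AlignmentFormatError(ValueError):
    """Malformed tabular alignment input."""


class MetadataError(ValueError):
    """Invalid virome metadata table."""


#: Canonical column order of the tabular alignment dialect.
ALN_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

_ALN_DTYPES = {
    "qseqid": str, "sseqid": str, "pident": float, "length": int,
    "mismatch": int, "gapopen": int, "qstart": int, "qend": int,
    "sstart": int, "send": int, "evalue": float, "bitscore": float,
}

#: Required columns of a virome metadata table.
METADATA_COLUMNS = ["virome_name", "pool", "country", "dataset_bp", "sample_kind"]

_VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class GenomeRecord:
    """A reference genome: identifier, uppercase sequence over {A,C,G,T,N}."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path) -> list[GenomeRecord]:
    """Parse a FASTA file into :class:`GenomeRecord` objects.

    The record id is the first whitespace-delimited token of the header;
    sequences are upper-cased.  Raises :class:`FastaError` (with the
    offending line number) on empty files, duplicate ids, or characters
    outside {A,C,G,T,N}.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    cur_id: str | None = None
    parts: list[str] = []

    def _flush() -> None:
        if cur_id is None:
            return
        records.append(GenomeRecord(cur_id, "".join(parts)))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].strip()
                if not header:
                    raise FastaError(f"{path}: line {lineno}: empty FASTA header")
                cur_id = header.split()[0]
                if cur_id in seen:
                    raise FastaError(
                        f"{path}: line {lineno}: duplicate sequence id {cur_id!r}"
                    )
                seen.add(cur_id)
                parts = []
            else:
                if cur_id is None:
                    raise FastaError(
                        f"{path}: line {lineno}: sequence data before first header"
                    )
                seq = line.upper()
                bad = set(seq) - _VALID_BASES
                if bad:
                    raise FastaError(
                        f"{path}: line {lineno}: invalid character(s) "
                        f"{''.join(sorted(bad))!r} (only A/C/G/T/N allowed)"
                    )
                parts.append(seq)
    _flush()
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def write_fasta(genomes, path, width: int = 80) -> None:
    """Write genomes (mapping id -> sequence, or GenomeRecord iterable) as FASTA."""
    if isinstance(genomes, Mapping):
        items = genomes.items()
    else:
        items = ((g.id, g.sequence) for g in genomes)
    with open(path, "w") as fh:
        for gid, seq in items:
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: Iterable[tuple[str, str]], path, quality_char: str = "I") -> None:
    """Write (read_id, sequence) pairs as FASTQ with a flat dummy quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_sequence_lengths(path) -> dict[str, int]:
    """Map read id -> length from a FASTA or FASTQ file (format sniffed)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), fmt)}


# ---------------------------------------------------------------------------
# Tabular alignments

def read_tabular_alignments(path, qlen_source: str | None = None) -> pd.DataFrame:
    """Read a 12/13-column tabular alignment file into a DataFrame.

    Parameters
    ----------
    path:
        Tab-separated alignment file, no header; 12 columns, or 13 with a
        trailing query length.
    qlen_source:
        How to resolve the query length of every row: ``"column13"``,
        ``"fastq:<path>"`` / ``"fasta:<path>"`` (lengths looked up from the
        reads file), or ``"constant:<N>"``.  ``None`` uses column 13 when
        present and errors otherwise.

    Returns a DataFrame with :data:`ALN_COLUMNS` plus ``qlen``.  Minus-strand
    rows (``sstart > send``) are preserved as-is.
    """
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (12, 13):
                raise AlignmentFormatError(
                    f"{path}: row {lineno}: expected 12 or 13 tab-separated "
                    f"columns, got {len(parts)}"
                )
            rows.append(parts)

    has13 = any(len(r) == 13 for r in rows)
    cols = ALN_COLUMNS + (["qlen"] if has13 else [])
    df = pd.DataFrame(
        [r + [None] * (len(cols) - len(r)) for r in rows], columns=cols
    )
    if df.empty:
        df = pd.DataFrame(columns=ALN_COLUMNS + ["qlen"])
    for col, dtype in _ALN_DTYPES.items():
        df[col] = df[col].astype(dtype) if len(df) else df.get(col, pd.Series(dtype=dtype))

    df = _resolve_qlen(df, qlen_source, path)
    _validate_alignments(df, path)
    return df


def _resolve_qlen(df: pd.DataFrame, qlen_source: str | None, path) -> pd.DataFrame:
    df = df.copy()
    if qlen_source is None or qlen_source == "column13":
        if "qlen" not in df.columns or df["qlen"].isna().any():
            missing = (
                df.loc[df["qlen"].isna(), "qseqid"].iloc[0]
                if "qlen" in df.columns and len(df)
                else (df["qseqid"].iloc[0] if len(df) else "<none>")
            )
            if qlen_source == "column13" or len(df):
                raise AlignmentFormatError(
                    f"{path}: query length unresolved for query {missing!r}; "
                    "no 13th column and no qlen_source given"
                )
            df["qlen"] = pd.Series(dtype=int)
    elif qlen_source.startswith("constant:"):
        n = int(qlen_source.split(":", 1)[1])
        if n <= 0:
            raise AlignmentFormatError(f"constant qlen must be positive, got {n}")
        df["qlen"] = n
    elif qlen_source.startswith(("fastq:", "fasta:")):
        lengths = read_sequence_lengths(qlen_source.split(":", 1)[1])
        qlen = df["qseqid"].map(lengths)
        if qlen.isna().any():
            missing = df.loc[qlen.isna(), "qseqid"].iloc[0]
            raise AlignmentFormatError(
                f"{path}: query {missing!r} not found in reads file; "
                "cannot resolve query length"
            )
        df["qlen"] = qlen
    else:
        raise ValueError(f"unknown qlen_source {qlen_source!r}")
    if len(df):
        df["qlen"] = df["qlen"].astype(int)
    return df


def _validate_alignments(df: pd.DataFrame, path) -> None:
    if df.empty:
        return
    bad = df[(df["qstart"] < 1) | (df["qstart"] > df["qend"])]
    if len(bad):
        raise AlignmentFormatError(
            f"{path}: query {bad['qseqid'].iloc[0]!r}: requires 1 <= qstart <= qend"
        )
    bad = df[(df["pident"] < 0) | (df["pident"] > 100)]
    if len(bad):
        raise AlignmentFormatError(
            f"{path}: query {bad['qseqid'].iloc[0]!r}: pident outside [0, 100]"
        )
    bad = df[df["evalue"] < 0]
    if len(bad):
        raise AlignmentFormatError(
            f"{path}: query {bad['qseqid'].iloc[0]!r}: negative e-value"
        )
    if "qlen" in df.columns:
        bad = df[df["qend"] > df["qlen"]]
        if len(bad):
            raise AlignmentFormatError(
                f"{path}: query {bad['qseqid'].iloc[0]!r}: qend exceeds qlen"
            )


def write_alignments(df: pd.DataFrame, path, include_qlen: bool = True) -> None:
    """Write alignments in the 12/13-column dialect (no header)."""
    cols = ALN_COLUMNS + (["qlen"] if include_qlen and "qlen" in df.columns else [])
    out = df[cols].copy()
    out["pident"] = out["pident"].map(lambda v: f"{v:.2f}")
    out["evalue"] = out["evalue"].map(lambda v: f"{v:.3g}")
    out["bitscore"] = out["bitscore"].map(lambda v: f"{v:g}")
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Metadata and generic tables

def read_metadata(path) -> pd.DataFrame:
    """Read a virome metadata TSV, validating the required columns.

    Required columns: ``virome_name pool country dataset_bp sample_kind``.
    ``country`` may be empty; ``dataset_bp`` must be a positive integer.
    Unknown columns are preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            raise MetadataError(f"{path}: missing required metadata column {col!r}")
    if not len(df):
        raise MetadataError(f"{path}: empty metadata table")
    try:
        df["dataset_bp"] = df["dataset_bp"].str.replace(" ", "", regex=False).astype("int64")
    except ValueError as exc:
        raise MetadataError(f"{path}: non-integer dataset_bp: {exc}") from exc
    bad = df[df["dataset_bp"] <= 0]
    if len(bad):
        raise MetadataError(
            f"{path}: virome {bad['virome_name'].iloc[0]!r}: dataset_bp must be > 0"
        )
    empty_pool = df[df["pool"].str.len() == 0]
    if len(empty_pool):
        raise MetadataError(
            f"{path}: virome {empty_pool['virome_name'].iloc[0]!r}: empty pool name"
        )
    return df


def write_table(df: pd.DataFrame, path, header_comments: Iterable[str] = ()) -> None:
    """Write a DataFrame as TSV with header, preceded by '#' comment lines."""
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    """Read a TSV with header, skipping '#' comment lines (inverse of write_table)."""
    return pd.read_csv(path, sep="\t", comment="#")
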