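"""Format readers and writers shared across the pipeline.

All tabular artefacts are TSV with a header row, UTF-8, no quoting, matching
the layout of the per-library count files and mapping tables such screens
deposit.  FASTQ reading is gzip-transparent and raises errors that carry the
file name and the offset of the offending record.
"""

from __future__ import annotations

import gzip
import hashlib
import io as _io
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator


class FastqFormatError(ValueError):
    """A malformed FASTQ record, reported with its file and record offset."""


def open_text(path: str | Path, mode: str = "rt"):
    """Open ``path`` for text I/O, transparently handling ``.gz`` suffixes."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield ``(read_id, sequence, quality)`` tuples from a FASTQ file.

    Wraps Biopython's four-line FASTQ iterator; a malformed record aborts
    with a :class:`FastqFormatError` naming the file and the 0-based offset
    of the record at which parsing failed.
    """
    n = 0
    with open_text(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                yield title.split(None, 1)[0], seq.upper(), qual
                n += 1
        except ValueError as exc:
            raise FastqFormatError(
                f"{path}: malformed FASTQ record at record offset {n}: {exc}"
            ) from exc


def write_fastq(path: str | Path, records: Iterator[tuple[str, str, str]] | list) -> int:
    """Write ``(read_id, sequence, quality)`` records; returns the count."""
    n = 0
    with open_text(path, "wt") as handle:
        for rid, seq, qual in records:
            handle.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a TSV table with a header row.  CRLF line endings are accepted."""
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed TSV: {exc}") from exc


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


REQUIRED_SHEET_COLUMNS = ["sample", "condition", "replicate"]
OPTIONAL_SHEET_COLUMNS = ["fastq_path", "library", "end_label"]


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the sample sheet mapping samples to conditions and FASTQ paths.

    Required columns: sample, condition, replicate.  Optional: fastq_path,
    library, end_label.  Duplicate sample names are rejected.
    """
    sheet = read_tsv(path, dtype=str)
    missing = [c for c in REQUIRED_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"{path}: sample sheet missing column(s): {', '.join(missing)}")
    dup = sheet["sample"][sheet["sample"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate sample name(s): {', '.join(dup)}")
    return sheet


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA reference into a name → uppercase-sequence dict."""
    from Bio import SeqIO

    with open_text(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(path: str | Path, sequences: dict[str, str], width: int = 80) -> None:
    with open_text(path, "wt") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
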