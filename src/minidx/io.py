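"""FASTA/FASTQ and report I/O (gzip-transparent)."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterator, Sequence

from Bio import SeqIO

__all__ = [
    "read_fasta",
    "read_fastx",
    "write_fasta",
    "write_fastq",
]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _sniff_format(path: Path) -> str:
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    return "fasta"


def read_fastx(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA or FASTQ (by extension) as (id, sequence) pairs."""
    path = Path(path)
    fmt = _sniff_format(path)
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, fmt)]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(
    records: Sequence[tuple[str, str]], path: str | Path, width: int = 70
) -> None:
    with _open_text(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write records with uniform placeholder qualities."""
    with _open_text(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
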