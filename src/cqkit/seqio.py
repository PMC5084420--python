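"""Light FASTA/FASTQ I/O helpers.

Reading goes through Biopython's SeqIO so the usual dialects (multi-line
FASTA, gzipped FASTQ) are handled; writing is done directly because the
simulator guarantees a fixed layout (60-column FASTA, phred+33 FASTQ with a
constant quality line) and byte-identical output matters for reproducibility.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

FASTA_WRAP = 60


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(path: str | Path) -> str:
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[:-3]
    suffix = Path(name).suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    return "fasta"


def read_sequences(path: str | Path, fmt: str | None = None) -> Iterator[tuple[str, str]]:
    """Yield ``(id, sequence)`` pairs from a FASTA/FASTQ file, possibly gzipped."""
    fmt = fmt or _sniff_format(path)
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, fmt):
            yield record.id, str(record.seq).upper()


def read_fasta_dict(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    Duplicate ids are rejected: downstream per-contig tallies would silently
    merge them.
    """
    out: dict[str, str] = {}
    for name, seq in read_sequences(path, "fasta"):
        if name in out:
            raise ValueError(f"duplicate sequence id {name!r} in {path}")
        out[name] = seq
    return out


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), FASTA_WRAP):
                fh.write(seq[i : i + FASTA_WRAP] + "\n")


def write_fastq(path: str | Path, records: Iterable[tuple[str, str]], quality_char: str = "I") -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")
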