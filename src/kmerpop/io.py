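"""File formats: FASTA/FASTQ sequence I/O and count-table TSV.

Sequence parsing goes through Bio.SeqIO; gzip-compressed inputs are
recognized by a ``.gz`` suffix.  Count tables serialize to two-column
TSV ``kmer<TAB>count`` with a ``#k=<k> canonical=<0|1>`` header.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .counting import KmerCountTable

__all__ = [
    "iter_sequences",
    "write_fasta",
    "write_fastq",
    "write_count_table",
    "read_count_table",
]

_FASTA_SUFFIXES = {".fa", ".fasta", ".fna"}
_FASTQ_SUFFIXES = {".fq", ".fastq"}


def _sequence_format(path: Path) -> str:
    suffixes = [s.lower() for s in path.suffixes]
    if suffixes and suffixes[-1] == ".gz":
        suffixes = suffixes[:-1]
    if suffixes and suffixes[-1] in _FASTQ_SUFFIXES:
        return "fastq"
    if suffixes and suffixes[-1] in _FASTA_SUFFIXES:
        return "fasta"
    # sniff: FASTA records start with '>', FASTQ with '@'
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        first = fh.read(1)
    return "fastq" if first == "@" else "fasta"


def iter_sequences(path) -> Iterator[str]:
    """Yield upper-case sequence strings from a FASTA/FASTQ file."""
    path = Path(path)
    fmt = _sequence_format(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for record in SeqIO.parse(fh, fmt):
            yield str(record.seq).upper()


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    """Write (id, sequence) pairs to a FASTA file."""
    path = Path(path)
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    try:
        with open(path, "w") as fh:
            SeqIO.write(seqs, fh, "fasta")
    except OSError as exc:
        raise OSError(f"failed to write FASTA to {path}: {exc}") from exc


def write_fastq(records: Iterable[tuple[str, str, str]], path) -> None:
    """Write (id, sequence, quality-string) triples to a FASTQ file."""
    path = Path(path)
    try:
        with open(path, "w") as fh:
            for name, seq, qual in records:
                if len(seq) != len(qual):
                    raise ValueError(
                        f"sequence/quality length mismatch for record {name!r}"
                    )
                fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
    except OSError as exc:
        raise OSError(f"failed to write FASTQ to {path}: {exc}") from exc


def write_count_table(table: KmerCountTable, path) -> None:
    path = Path(path)
    try:
        with open(path, "w") as fh:
            fh.write(f"#k={table.k} canonical={int(table.canonical)}\n")
            for kmer, count in table.items():
                fh.write(f"{kmer}\t{count}\n")
    except OSError as exc:
        raise OSError(f"failed to write count table to {path}: {exc}") from exc


def read_count_table(path) -> KmerCountTable:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#k="):
            raise ValueError(f"{path}: missing '#k=<k> canonical=<0|1>' header")
        fields = dict(part.split("=", 1) for part in header[1:].split())
        k = int(fields["k"])
        canonical = bool(int(fields.get("canonical", "1")))
        counts: dict[str, int] = {}
        for line in fh:
            line = line.strip()
            if not line:
                continue
            kmer, count = line.split("\t")
            counts[kmer] = int(count)
    return KmerCountTable.from_dict(counts, k=k, canonical=canonical)
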