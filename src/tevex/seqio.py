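"""Thin FASTA/FASTQ wrappers around Bio.SeqIO.

All sequences are handled as plain upper-case strings; records are
(name, sequence) or (name, sequence, quality) tuples.
"""

from __future__ import annotations

import os
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    recs = (SeqRecord(Seq(seq), id=name, description="") for name, seq in records)
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str, str]]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq).upper(), qual))
    return out


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | os.PathLike) -> None:
    """Write (name, sequence, quality) tuples as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
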