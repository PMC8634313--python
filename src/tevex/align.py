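"""Minimal exact-seed, ungapped read aligner.

Used so the synthetic test data can be taken through the chimera
pipeline without an external alignment binary: reads are matched by
exact 20-mer seeds (both strands) and extended without gaps while bases
match. The seed length mirrors the shortest exact substring a
sensitive short-read aligner requires, and the 28-bp minimum reported
segment mirrors the shortest local alignment the chimera caller
trusts. This aligner is only intended for error-free or near
error-free reads; real data should be aligned externally and imported
via :func:`tevex.chimera.parse_alignments`.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .chimera import ReadAlignment
from .seqio import reverse_complement

DEFAULT_SEED_LENGTH = 20


class SeedIndex:
    """Exact k-mer index over a set of subject sequences."""

    def __init__(self, subjects: Mapping[str, str], subject_kind: str, k: int = DEFAULT_SEED_LENGTH):
        self.k = k
        self.subject_kind = subject_kind
        self.subjects = dict(subjects)
        self._index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.subjects.items():
            for p in range(len(seq) - k + 1):
                self._index.setdefault(seq[p : p + k], []).append((name, p))

    def align_read(self, read_id: str, read: str, min_length: int = 1) -> list[ReadAlignment]:
        """All maximal ungapped exact alignments of the read, both strands."""
        out: list[ReadAlignment] = []
        for strand in ("+", "-"):
            query = read if strand == "+" else reverse_complement(read)
            seen: dict[tuple[str, int], tuple[int, int]] = {}  # (subject, diag) -> query interval
            for i in range(len(query) - self.k + 1):
                matches = self._index.get(query[i : i + self.k])
                if not matches:
                    continue
                for name, p in matches:
                    diag = p - i
                    prev = seen.get((name, diag))
                    if prev is not None and prev[0] <= i < prev[1]:
                        continue  # seed already inside an extension on this diagonal
                    q0, q1 = self._extend(query, self.subjects[name], i, p)
                    seen[(name, diag)] = (q0, q1)
                    if q1 - q0 < min_length:
                        continue
                    s0, s1 = q0 + diag, q1 + diag
                    if strand == "+":
                        read_interval = (q0, q1)
                    else:
                        read_interval = (len(read) - q1, len(read) - q0)
                    out.append(
                        ReadAlignment(
                            read_id=read_id,
                            subject_kind=self.subject_kind,
                            subject_name=name,
                            read_interval=read_interval,
                            subject_interval=(s0, s1),
                            subject_strand=strand,
                            percent_identity=100.0,
                            bitscore=float(q1 - q0),
                        )
                    )
        return out

    def _extend(self, query: str, subject: str, qi: int, sp: int) -> tuple[int, int]:
        q0, s0 = qi, sp
        while q0 > 0 and s0 > 0 and query[q0 - 1] == subject[s0 - 1]:
            q0 -= 1
            s0 -= 1
        q1, s1 = qi + self.k, sp + self.k
        while q1 < len(query) and s1 < len(subject) and query[q1] == subject[s1]:
            q1 += 1
            s1 += 1
        return q0, q1


def align_reads(
    reads: Iterable[tuple[str, str] | tuple[str, str, str]],
    indexes: Sequence[SeedIndex],
    min_length: int = 1,
) -> list[ReadAlignment]:
    """Align reads against one or more seed indexes.

    ``reads`` are (read_id, sequence[, quality]) tuples; qualities are
    ignored. Returns every maximal alignment of at least ``min_length``
    bp; downstream consumers select best hits.
    """
    out: list[ReadAlignment] = []
    for rec in reads:
        read_id, seq = rec[0], rec[1]
        for index in indexes:
            out.extend(index.align_read(read_id, seq, min_length=min_length))
    return out
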