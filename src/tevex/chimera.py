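"""Detection of TE-virus chimeric reads from per-read local alignments.

A chimeric read spans a junction between a TE copy integrated in a
viral genome and the flanking viral sequence: one portion of the read
aligns to a TE consensus only, the other to the viral genome only.
Junctions are classified by which TE extremity they touch (5', 3', or
internal to the consensus), tabulated per family/time point/replicate,
binned into genome windows to reveal insertion hotspots, and quantified
as junction-level RPKM.

Alignments are consumed either from 12-column tabular files (BLAST
``-outfmt 6``-style, 1-based inclusive coordinates, converted on
parsing) or from the built-in exact-seed aligner in
:mod:`tevex.align`, which exists so that synthetic data can be analysed
without an external aligner.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_MIN_SEGMENT = 28  # shortest alignment the chimera caller trusts, bp
DEFAULT_OVERLAP_TOL = 10  # max bp of read shared by (or uncovered between) the two segments
DEFAULT_TIP_TOL = 5  # max bp from a consensus extremity to call a tip junction
DEFAULT_HOTSPOT_WINDOW = 50  # bp
OTHERS_THRESHOLD = 10  # families with fewer chimeras overall are lumped


@dataclass(frozen=True)
class ReadAlignment:
    """One local alignment of a read against a TE consensus or the virus.

    ``read_interval`` and ``subject_interval`` are 0-based half-open;
    ``subject_interval`` always has start < end, with minus-strand hits
    flagged by ``subject_strand``.
    """

    read_id: str
    subject_kind: str  # 'te' or 'virus'
    subject_name: str
    read_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    subject_strand: str  # '+' or '-'
    percent_identity: float = 100.0
    mismatches: int = 0
    gap_opens: int = 0
    evalue: float = 0.0
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        q0, q1 = self.read_interval
        s0, s1 = self.subject_interval
        if not q0 < q1:
            raise ValueError(f"read interval must be non-empty: {self.read_interval}")
        if not s0 < s1:
            raise ValueError(f"subject interval must be normalized start<end: {self.subject_interval}")
        if self.subject_kind not in ("te", "virus"):
            raise ValueError(f"subject_kind must be 'te' or 'virus': {self.subject_kind}")

    @property
    def aligned_length(self) -> int:
        return self.read_interval[1] - self.read_interval[0]


@dataclass
class ChimericRead:
    """A read split between a TE-only and a virus-only portion."""

    read_id: str
    family_name: str
    te_read_interval: tuple[int, int]
    virus_read_interval: tuple[int, int]
    te_consensus_interval: tuple[int, int]
    te_strand: str  # TE alignment strand relative to the read
    virus_strand: str  # virus alignment strand relative to the read
    virus_junction_coord: int  # 0-based position right of the junction on the TE-free genome
    orientation: str  # TE strand relative to the virus
    te_side: str = "internal"  # five_prime | three_prime | internal
    te_offset: int = 0  # bp from the junction to the nearest consensus extremity
    time_point: float | None = None
    replicate: str | None = None

    @property
    def is_tip(self) -> bool:
        return self.te_side in ("five_prime", "three_prime")


@dataclass
class HotspotHistogram:
    window_size: int
    counts: pd.DataFrame  # rows: window index; columns: time point

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


# ---------------------------------------------------------------------------
# tabular alignment I/O

_BLAST6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore"
).split()


def parse_alignments(
    path: str | os.PathLike,
    dialect: str = "blast6",
    virus_names: Iterable[str] = (),
    subject_kind: str | None = None,
) -> list[ReadAlignment]:
    """Parse a 12-column tabular alignment file.

    Subject kind is ``virus`` for subjects listed in ``virus_names``
    and ``te`` otherwise, unless a uniform ``subject_kind`` is forced.
    1-based inclusive coordinates become 0-based half-open; subject
    hits with reversed coordinates are normalized to start < end with
    strand '-'. Malformed lines raise with their line numbers.
    """
    if dialect != "blast6":
        raise ValueError(f"unknown alignment dialect: {dialect!r}")
    virus_names = set(virus_names)
    out: list[ReadAlignment] = []
    bad: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                bad.append(lineno)
                continue
            try:
                (qseqid, sseqid, pident, length, mismatch, gapopen,
                 qstart, qend, sstart, send, evalue, bitscore) = fields
                qstart, qend, sstart, send = int(qstart), int(qend), int(sstart), int(send)
                if sstart <= send:
                    sint, strand = (sstart - 1, send), "+"
                else:
                    sint, strand = (send - 1, sstart), "-"
                kind = subject_kind or ("virus" if sseqid in virus_names else "te")
                out.append(
                    ReadAlignment(
                        read_id=qseqid,
                        subject_kind=kind,
                        subject_name=sseqid,
                        read_interval=(qstart - 1, qend),
                        subject_interval=sint,
                        subject_strand=strand,
                        percent_identity=float(pident),
                        mismatches=int(mismatch),
                        gap_opens=int(gapopen),
                        evalue=float(evalue),
                        bitscore=float(bitscore),
                    )
                )
            except (ValueError, IndexError):
                bad.append(lineno)
    if bad:
        raise ValueError(f"{path}: malformed 12-column lines at {bad}")
    return out


def write_alignments(alignments: Iterable[ReadAlignment], path: str | os.PathLike) -> None:
    """Write alignments back to the 12-column tabular format."""
    with open(path, "w") as fh:
        for a in alignments:
            q0, q1 = a.read_interval
            s0, s1 = a.subject_interval
            if a.subject_strand == "+":
                sstart, send = s0 + 1, s1
            else:
                sstart, send = s1, s0 + 1
            fh.write(
                "\t".join(
                    [
                        a.read_id,
                        a.subject_name,
                        f"{a.percent_identity:.2f}",
                        str(a.aligned_length),
                        str(a.mismatches),
                        str(a.gap_opens),
                        str(q0 + 1),
                        str(q1),
                        str(sstart),
                        str(send),
                        f"{a.evalue:.2g}",
                        f"{a.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# chimera detection


def _pair_geometry_ok(
    te: ReadAlignment, virus: ReadAlignment, overlap_tol: int
) -> bool:
    t0, t1 = te.read_interval
    v0, v1 = virus.read_interval
    # neither segment may contain the other: each must cover read bases
    # the other does not
    if (t0 >= v0 and t1 <= v1) or (v0 >= t0 and v1 <= t1):
        return False
    overlap = min(t1, v1) - max(t0, v0)
    # positive = shared read bases (junction micro-homology); negative =
    # uncovered gap between the segments
    return -overlap_tol <= overlap <= overlap_tol


def _junction_coord(te: ReadAlignment, virus: ReadAlignment) -> int:
    """Viral coordinate adjacent to the TE-facing end of the virus segment.

    Reported as the 0-based reference position immediately right of the
    junction, on the TE-free viral reference. The junction position on
    the read is taken from the TE segment boundary, not the virus one:
    at a tip junction the TE alignment is hard-bounded by the consensus
    extremity, whereas the virus alignment can extend a few bases into
    the TE through junction micro-homology. That read position is then
    mapped onto the viral reference along the virus alignment diagonal
    (extrapolating across any small uncovered gap).
    """
    virus_first = virus.read_interval[0] < te.read_interval[0]
    j = te.read_interval[0] if virus_first else te.read_interval[1]
    v0, _ = virus.read_interval
    s0, s1 = virus.subject_interval
    if virus.subject_strand == "+":
        return s0 + (j - v0)
    return s1 - (j - v0)


def classify_junction_side(
    chimera: ChimericRead, te_length: int, tip_tol: int = DEFAULT_TIP_TOL
) -> tuple[str, int]:
    """Classify which TE consensus extremity abuts the junction.

    The junction-proximal end of the TE segment is located on the
    consensus (orientation-normalized). Within ``tip_tol`` bp of
    consensus position 0 it is a 5' junction; within ``tip_tol`` of the
    consensus end a 3' junction; otherwise internal. ``te_offset`` is
    the exact distance to the nearest extremity.
    """
    if te_length <= 0:
        raise ValueError("te_length must be positive")
    te_first = chimera.te_read_interval[0] < chimera.virus_read_interval[0]
    c0, c1 = chimera.te_consensus_interval
    # junction-proximal read end of the TE segment: 3' end if the TE
    # comes first on the read, else 5' end; map to consensus coords
    if te_first:
        proximal = c1 if chimera.te_strand == "+" else c0
    else:
        proximal = c0 if chimera.te_strand == "+" else c1
    offset5 = proximal
    offset3 = te_length - proximal
    if offset5 <= tip_tol and offset5 <= offset3:
        return "five_prime", offset5
    if offset3 <= tip_tol:
        return "three_prime", offset3
    return "internal", min(offset5, offset3)


def detect_chimeras(
    alignments: Iterable[ReadAlignment],
    te_lengths: Mapping[str, int],
    min_segment: int = DEFAULT_MIN_SEGMENT,
    overlap_tol: int = DEFAULT_OVERLAP_TOL,
    tip_tol: int = DEFAULT_TIP_TOL,
) -> list[ChimericRead]:
    """Identify reads split between a TE consensus and the viral genome.

    A read is chimeric iff it carries a TE alignment and a virus
    alignment, each at least ``min_segment`` bp long on the read, whose
    read intervals neither contain one another nor overlap/gap by more
    than ``overlap_tol`` bp. One call is made per read: the pair with
    the largest combined aligned length wins, ties broken by the lowest
    virus junction coordinate.
    """
    by_read: dict[str, tuple[list[ReadAlignment], list[ReadAlignment]]] = {}
    for a in alignments:
        te_list, virus_list = by_read.setdefault(a.read_id, ([], []))
        if a.aligned_length < min_segment:
            continue
        (te_list if a.subject_kind == "te" else virus_list).append(a)

    chimeras: list[ChimericRead] = []
    for read_id in sorted(by_read):
        te_list, virus_list = by_read[read_id]
        best: tuple[int, int, ReadAlignment, ReadAlignment] | None = None
        for te in te_list:
            for virus in virus_list:
                if not _pair_geometry_ok(te, virus, overlap_tol):
                    continue
                score = te.aligned_length + virus.aligned_length
                coord = _junction_coord(te, virus)
                key = (-score, coord)
                if best is None or key < (-best[0], best[1]):
                    best = (score, coord, te, virus)
        if best is None:
            continue
        _, coord, te, virus = best
        orientation = "+" if te.subject_strand == virus.subject_strand else "-"
        chim = ChimericRead(
            read_id=read_id,
            family_name=te.subject_name,
            te_read_interval=te.read_interval,
            virus_read_interval=virus.read_interval,
            te_consensus_interval=te.subject_interval,
            te_strand=te.subject_strand,
            virus_strand=virus.subject_strand,
            virus_junction_coord=coord,
            orientation=orientation,
        )
        chim.te_side, chim.te_offset = classify_junction_side(
            chim, te_lengths[te.subject_name], tip_tol
        )
        chimeras.append(chim)
    return chimeras


# ---------------------------------------------------------------------------
# tabulation


def tabulate_chimeras(
    chimeras: Sequence[ChimericRead],
    others_threshold: int = OTHERS_THRESHOLD,
    tips_only: bool = True,
) -> pd.DataFrame:
    """Count chimeras by family x time point x replicate x junction side.

    Families supported by fewer than ``others_threshold`` chimeric
    reads over all data sets jointly are lumped into an ``Others`` row.
    By default only tip (5'/3') chimeras are tabulated, matching how
    junction counts are normally reported; internal chimeras are
    excluded before lumping.
    """
    rows = [
        {
            "family": c.family_name,
            "time_point": c.time_point,
            "replicate": c.replicate,
            "side": c.te_side,
        }
        for c in chimeras
        if not tips_only or c.is_tip
    ]
    if not rows:
        return pd.DataFrame(columns=["family", "time_point", "replicate", "side", "n"])
    df = pd.DataFrame(rows)
    totals = df.groupby("family").size()
    lumped = totals[totals < others_threshold].index
    df.loc[df["family"].isin(lumped), "family"] = "Others"
    counts = (
        df.groupby(["family", "time_point", "replicate", "side"], dropna=False)
        .size()
        .rename("n")
        .reset_index()
    )
    return counts


def chimera_table_pivot(counts: pd.DataFrame) -> pd.DataFrame:
    """Pivot tidy chimera counts into a family x (time, side) table."""
    if counts.empty:
        return pd.DataFrame()
    return counts.pivot_table(
        index=["replicate", "family"],
        columns=["time_point", "side"],
        values="n",
        aggfunc="sum",
        fill_value=0,
    )


def bin_hotspots(
    chimeras: Sequence[ChimericRead],
    genome_length: int,
    window: int = DEFAULT_HOTSPOT_WINDOW,
) -> HotspotHistogram:
    """Bin junction coordinates into fixed windows along the genome.

    Window *k* covers the half-open interval [k*window, (k+1)*window).
    Counts are split by time point; coordinates outside the genome
    raise.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    n_windows = (genome_length + window - 1) // window
    tps = sorted({c.time_point for c in chimeras}, key=lambda x: (x is None, x))
    counts = pd.DataFrame(0, index=range(n_windows), columns=tps or [None])
    for c in chimeras:
        if not 0 <= c.virus_junction_coord < genome_length:
            raise ValueError(
                f"junction coordinate {c.virus_junction_coord} outside genome of "
                f"length {genome_length}"
            )
        counts.loc[c.virus_junction_coord // window, c.time_point] += 1
    return HotspotHistogram(window_size=window, counts=counts)


def junction_rpkm(
    count: float | np.ndarray, length_bp: float, total_mapped: float | np.ndarray
) -> float | np.ndarray:
    """Reads per kilobase of junction feature per million mapped reads."""
    length_bp = np.asarray(length_bp, dtype=float)
    total = np.asarray(total_mapped, dtype=float)
    if (length_bp <= 0).any():
        raise ValueError("feature length must be positive")
    if (total <= 0).any():
        raise ValueError("total mapped reads must be positive")
    out = np.asarray(count, dtype=float) / (length_bp / 1e3) / (total / 1e6)
    return float(out) if out.ndim == 0 else out


def average_junction_rpkm(
    counts_by_replicate: Sequence[float],
    length_bp: float,
    totals_by_replicate: Sequence[float],
) -> float:
    """Mean junction RPKM over replicates (each with its own library size)."""
    vals = [
        junction_rpkm(c, length_bp, t)
        for c, t in zip(counts_by_replicate, totals_by_replicate, strict=True)
    ]
    return float(np.mean(vals))


def chimeras_to_frame(chimeras: Sequence[ChimericRead]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [c.read_id for c in chimeras],
            "family": [c.family_name for c in chimeras],
            "virus_junction_coord": [c.virus_junction_coord for c in chimeras],
            "te_side": [c.te_side for c in chimeras],
            "te_offset": [c.te_offset for c in chimeras],
            "orientation": [c.orientation for c in chimeras],
            "time_point": [c.time_point for c in chimeras],
            "replicate": [c.replicate for c in chimeras],
        }
    )
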