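"""Target-site-duplication (TSD) validation of TE insertions.

Canonical ("cut-and-paste" or retro-) transposition duplicates a short
stretch of the target sequence on both flanks of the new insertion.
On the TE-free viral reference this leaves a signature: the viral
coordinate seen by chimeric reads at the TE 5' extremity and the one
seen at the 3' extremity differ by exactly the TSD length (e.g. 4 bp
and a TTAA/ATAA motif for piggyBac, 3 bp for Harbinger, 0 for a blunt
event). This module pairs 5' and 3' chimeras into insertion calls,
extracts the duplicated motif from the reference, and counts distinct
insertions and motif frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .chimera import ChimericRead

DEFAULT_MAX_DELTA = 5  # max bp between paired 5' and 3' junction coordinates


@dataclass
class InsertionCall:
    """A TSD-validated insertion supported by paired 5' and 3' chimeras."""

    family_name: str
    viral_coord_5p: int
    viral_coord_3p: int
    orientation: str
    n_reads_5p: int
    n_reads_3p: int
    tsd_motif: str = ""
    time_point: float | None = None

    @property
    def tsd_length(self) -> int:
        return abs(self.viral_coord_5p - self.viral_coord_3p)

    @property
    def n_reads(self) -> int:
        return self.n_reads_5p + self.n_reads_3p

    @property
    def coordinate_pair(self) -> tuple[int, int]:
        return (self.viral_coord_5p, self.viral_coord_3p)


def pair_junctions(
    chimeras: Iterable[ChimericRead], max_delta: int = DEFAULT_MAX_DELTA
) -> list[InsertionCall]:
    """Pair 5' and 3' tip chimeras into insertion calls.

    Candidates must share the TE family and a concordant orientation
    (the TE strand implied by the 5' chimera equals that implied by the
    3' one), and their viral junction coordinates must agree to within
    ``max_delta`` bp (inclusive). Internal-side chimeras never pair.
    Chimeras are first collapsed to junction groups (unique coordinate
    per side); groups are then paired greedily one-to-one by descending
    read support, ties broken by coordinate, so each read supports at
    most one insertion. Pairing is done within time points when
    chimeras carry one.
    """
    # (family, orientation, time_point) -> side -> {coord: n_reads}
    groups: dict[tuple, dict[str, dict[int, int]]] = {}
    for c in chimeras:
        if c.te_side not in ("five_prime", "three_prime"):
            continue
        key = (c.family_name, c.orientation, c.time_point)
        sides = groups.setdefault(key, {"five_prime": {}, "three_prime": {}})
        coords = sides[c.te_side]
        coords[c.virus_junction_coord] = coords.get(c.virus_junction_coord, 0) + 1

    calls: list[InsertionCall] = []
    for (family, orientation, tp), sides in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][1], _tp_key(kv[0][2]))
    ):
        five, three = sides["five_prime"], sides["three_prime"]
        candidates = [
            (n5 + n3, c5, c3, n5, n3)
            for c5, n5 in five.items()
            for c3, n3 in three.items()
            if abs(c5 - c3) <= max_delta
        ]
        candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
        used5: set[int] = set()
        used3: set[int] = set()
        for _, c5, c3, n5, n3 in candidates:
            if c5 in used5 or c3 in used3:
                continue
            used5.add(c5)
            used3.add(c3)
            calls.append(
                InsertionCall(
                    family_name=family,
                    viral_coord_5p=c5,
                    viral_coord_3p=c3,
                    orientation=orientation,
                    n_reads_5p=n5,
                    n_reads_3p=n3,
                    time_point=tp,
                )
            )
    return calls


def _tp_key(tp: float | None) -> tuple[int, float]:
    return (1, 0.0) if tp is None else (0, float(tp))


def extract_tsd_motif(call: InsertionCall, viral_reference: str) -> str:
    """Duplicated motif between the paired junction coordinates.

    The motif is the reference substring between the 5' and 3'
    junction coordinates (empty when they coincide, i.e. a blunt
    insertion).
    """
    lo = min(call.viral_coord_5p, call.viral_coord_3p)
    hi = max(call.viral_coord_5p, call.viral_coord_3p)
    if lo < 0 or hi > len(viral_reference):
        raise ValueError(f"junction coordinates [{lo}, {hi}] outside the reference")
    return viral_reference[lo:hi]


def annotate_motifs(calls: Sequence[InsertionCall], viral_reference: str) -> list[InsertionCall]:
    """Fill ``tsd_motif`` on each call from the viral reference, in place."""
    for call in calls:
        call.tsd_motif = extract_tsd_motif(call, viral_reference)
    return list(calls)


@dataclass
class InsertionSummary:
    n_distinct: int  # unique (family, coordinate pair, orientation) overall
    per_group: pd.Series  # distinct insertions per (family, time point)
    motif_counts: pd.Series  # motif -> number of calls
    total_supporting_reads: int


def count_distinct_insertions(
    calls: Sequence[InsertionCall], merge_tol: int = 0
) -> InsertionSummary:
    """Count unique insertions and tally TSD motifs.

    Two calls describe the same insertion when family and orientation
    match and both the 5' and the 3' coordinates each agree to within
    ``merge_tol`` bp (default 0: exact coordinate pairs). Distinctness
    is counted overall and per (family, time point).
    """
    reps: dict[tuple[str, str], list[tuple[int, int]]] = {}

    def _canonical(call: InsertionCall) -> tuple[str, str, int, int]:
        key = (call.family_name, call.orientation)
        for r5, r3 in reps.setdefault(key, []):
            if abs(call.viral_coord_5p - r5) <= merge_tol and abs(call.viral_coord_3p - r3) <= merge_tol:
                return (*key, r5, r3)
        reps[key].append((call.viral_coord_5p, call.viral_coord_3p))
        return (*key, call.viral_coord_5p, call.viral_coord_3p)

    canon = [_canonical(c) for c in sorted(calls, key=lambda c: (-c.n_reads, c.coordinate_pair))]
    order = sorted(range(len(calls)), key=lambda i: (-calls[i].n_reads, calls[i].coordinate_pair))
    canon_by_call = dict(zip(order, canon))

    distinct_overall = len(set(canon_by_call.values()))
    rows = [
        {
            "family": calls[i].family_name,
            "time_point": calls[i].time_point,
            "insertion": canon_by_call[i],
        }
        for i in range(len(calls))
    ]
    if rows:
        df = pd.DataFrame(rows)
        per_group = df.groupby(["family", "time_point"], dropna=False)["insertion"].nunique()
        motifs = pd.Series([c.tsd_motif for c in calls]).value_counts()
    else:
        per_group = pd.Series(dtype=int)
        motifs = pd.Series(dtype=int)
    return InsertionSummary(
        n_distinct=distinct_overall,
        per_group=per_group,
        motif_counts=motifs,
        total_supporting_reads=sum(c.n_reads for c in calls),
    )


def calls_to_frame(calls: Sequence[InsertionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "family": [c.family_name for c in calls],
            "viral_coord_5p": [c.viral_coord_5p for c in calls],
            "viral_coord_3p": [c.viral_coord_3p for c in calls],
            "orientation": [c.orientation for c in calls],
            "tsd_motif": [c.tsd_motif for c in calls],
            "tsd_length": [c.tsd_length for c in calls],
            "n_reads_5p": [c.n_reads_5p for c in calls],
            "n_reads_3p": [c.n_reads_3p for c in calls],
            "time_point": [c.time_point for c in calls],
        }
    )
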