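"""TE copy aggregation, filtering and genomic landscape summaries.

Repeat-annotation tools report transposable-element (TE) matches as
fragments: a single genomic TE copy interrupted by deletions or nested
insertions appears as several hits to the same consensus. This module
re-assembles fragments into copies, applies the copy-level and
library-level retention filters used for expression analysis, and
computes landscape summaries (superfamily copy numbers, divergence
histogram as an age proxy, masked genome fraction, distance to genes).

Coordinates are 0-based half-open internally; RepeatMasker-style tables
(1-based inclusive) are converted at parse time.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: TE library categories discarded from the expression library: short
#: non-autonomous or non-TE repeats for which family-level expression
#: is not interpretable.
EXCLUDED_CATEGORIES = frozenset({"SINE", "tRNA", "rRNA", "Unknown"})

#: Copy filter: retained copies must be longer than this many bp ...
MIN_COPY_LENGTH = 80
#: ... and share more than this percent identity with their consensus.
MIN_COPY_IDENTITY = 80.0

#: Library filter: consensus length must exceed this ...
MIN_LIBRARY_LENGTH = 300
#: ... and the best protein hit must cover at least this fraction of a
#: TE protein.
MIN_PROTEIN_COVERAGE = 0.5

#: Default maximum gap (bp) between same-family, same-strand fragments
#: merged into one copy.
DEFAULT_MAX_GAP = 150


@dataclass(frozen=True)
class RepeatHit:
    """One repeat-annotation fragment (RepeatMasker-style hit)."""

    contig: str
    start: int  # 0-based
    end: int  # half-open
    strand: str  # '+' or '-'
    family_name: str
    divergence: float  # percent mismatch to consensus, in [0, 100]

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"hit has start >= end: {self}")
        if not 0.0 <= self.divergence <= 100.0:
            raise ValueError(f"divergence outside [0, 100]: {self.divergence}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TEFamily:
    """A TE consensus sequence; the unit of family-level expression."""

    name: str
    te_class: str  # 'I' (retrotransposon) or 'II' (DNA transposon)
    superfamily: str
    consensus: str

    def __post_init__(self) -> None:
        if len(self.consensus) == 0:
            raise ValueError("consensus must be non-empty")

    @property
    def length(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class TECopy:
    """An aggregated genomic TE copy (one or more merged fragments)."""

    family_name: str
    contig: str
    start: int
    end: int
    strand: str
    mean_divergence: float  # length-weighted mean of fragment divergences
    n_fragments: int = 1

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError("copy must span at least 1 bp")
        if self.n_fragments < 1:
            raise ValueError("n_fragments must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def identity(self) -> float:
        """Percent identity to consensus (100 - divergence)."""
        return 100.0 - self.mean_divergence


@dataclass(frozen=True)
class LibraryCandidate:
    """A candidate consensus for the expression TE library."""

    name: str
    length: int
    best_protein_coverage: float  # fraction of a TE protein covered, [0, 1]
    category: str  # superfamily label, or SINE/tRNA/rRNA/Unknown

    def __post_init__(self) -> None:
        if not 0.0 <= self.best_protein_coverage <= 1.0:
            raise ValueError("coverage must be in [0, 1]")


# ---------------------------------------------------------------------------
# parsing


def read_repeatmasker_out(path: str | os.PathLike) -> list[RepeatHit]:
    """Parse a RepeatMasker ``.out``-style whitespace table into hits.

    The standard layout is three header lines followed by rows of::

        score div del ins contig qbegin qend (left) strand repeat
        class/family rbegin rend (left) id

    Query coordinates are 1-based inclusive and converted to 0-based
    half-open; strand ``C`` (complement) becomes ``-``.
    """
    hits: list[RepeatHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or not fields[0].replace(".", "", 1).isdigit():
                continue  # header or blank line
            try:
                div = float(fields[1])
                contig = fields[4]
                qbegin, qend = int(fields[5]), int(fields[6])
                strand = "-" if fields[8] in ("C", "-") else "+"
                family = fields[9]
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}") from exc
            hits.append(
                RepeatHit(
                    contig=contig,
                    start=qbegin - 1,
                    end=qend,
                    strand=strand,
                    family_name=family,
                    divergence=div,
                )
            )
    return hits


def read_gff_genes(path: str | os.PathLike, feature: str = "gene") -> pd.DataFrame:
    """Read gene intervals from a GFF3 file.

    Returns a DataFrame with columns ``contig``, ``start``, ``end``
    (0-based half-open), keeping only rows whose type column matches
    ``feature``.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["contig", "source", "type", "start", "end", "score", "strand", "phase", "attributes"],
        dtype={"contig": str},
    )
    genes = df[df["type"] == feature].copy()
    genes["start"] = genes["start"].astype(int) - 1  # GFF is 1-based inclusive
    genes["end"] = genes["end"].astype(int)
    return genes[["contig", "start", "end"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# aggregation and filtering


def aggregate_hits(hits: Iterable[RepeatHit], max_gap: int = DEFAULT_MAX_GAP) -> list[TECopy]:
    """Merge same-family, same-strand fragments into TE copies.

    Hits sharing (contig, family, strand) are chained whenever the gap
    between consecutive fragments is at most ``max_gap`` bp; overlapping
    or nested fragments are merged by interval union. The copy's
    divergence is the length-weighted mean over its fragments.
    """
    copies: list[TECopy] = []
    ordered = sorted(hits, key=lambda h: (h.contig, h.family_name, h.strand, h.start, h.end))
    cur: list[RepeatHit] = []

    def _flush() -> None:
        if not cur:
            return
        start = cur[0].start
        end = max(h.end for h in cur)
        weights = np.array([h.length for h in cur], dtype=float)
        divs = np.array([h.divergence for h in cur])
        copies.append(
            TECopy(
                family_name=cur[0].family_name,
                contig=cur[0].contig,
                start=start,
                end=end,
                strand=cur[0].strand,
                mean_divergence=float(np.average(divs, weights=weights)),
                n_fragments=len(cur),
            )
        )

    for hit in ordered:
        if cur and (
            hit.contig != cur[0].contig
            or hit.family_name != cur[0].family_name
            or hit.strand != cur[0].strand
            or hit.start - max(h.end for h in cur) > max_gap
        ):
            _flush()
            cur = []
        cur.append(hit)
    _flush()
    copies.sort(key=lambda c: (c.contig, c.start, c.end, c.family_name))
    return copies


def filter_copies(copies: Iterable[TECopy]) -> list[TECopy]:
    """Keep copies longer than 80 bp with more than 80% identity.

    Both bounds are strict: an 80-bp copy or one at exactly 80%
    identity (20% divergence) is removed. Input order is preserved.
    """
    return [
        c
        for c in copies
        if c.length > MIN_COPY_LENGTH and c.identity > MIN_COPY_IDENTITY
    ]


def filter_library(candidates: Iterable[LibraryCandidate]) -> list[LibraryCandidate]:
    """Apply the library retention rule to candidate consensus sequences.

    A candidate is kept iff it is longer than 300 bp, its best protein
    hit covers at least half of a TE protein, and its category is not
    one of the excluded non-TE/short-repeat classes.
    """
    return [
        c
        for c in candidates
        if c.length > MIN_LIBRARY_LENGTH
        and c.best_protein_coverage >= MIN_PROTEIN_COVERAGE
        and c.category not in EXCLUDED_CATEGORIES
    ]


# ---------------------------------------------------------------------------
# landscape summaries


def _merged_interval_bp(intervals: Sequence[tuple[int, int]]) -> int:
    """Total bp covered by a set of intervals after merging overlaps."""
    total = 0
    cur_start = cur_end = None
    for start, end in sorted(intervals):
        if cur_end is None or start > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_end is not None:
        total += cur_end - cur_start
    return total


@dataclass
class LandscapeSummary:
    superfamily_counts: pd.Series  # copies per superfamily
    class_fractions: pd.Series  # fraction of copies per TE class
    divergence_histogram: pd.Series  # counts per 1% divergence bin
    masked_bp: int  # overlap-merged bp covered by copies
    genome_fraction: float  # masked_bp / genome size
    n_copies: int = field(default=0)


def landscape_summary(
    copies: Sequence[TECopy],
    families: Mapping[str, TEFamily] | Iterable[TEFamily],
    genome_size: int,
) -> LandscapeSummary:
    """Summarise a set of TE copies against the genome.

    ``families`` supplies the class/superfamily label for each family
    name. The divergence histogram uses 1% bins [i, i+1); copies at
    exactly 100% divergence fall in the final bin.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if not isinstance(families, Mapping):
        families = {f.name: f for f in families}

    superfams = pd.Series(
        [families[c.family_name].superfamily for c in copies], dtype=object
    )
    classes = pd.Series([families[c.family_name].te_class for c in copies], dtype=object)
    divs = np.array([c.mean_divergence for c in copies], dtype=float)

    hist_counts, _ = np.histogram(divs, bins=np.arange(0, 102))
    hist = pd.Series(hist_counts, index=np.arange(0, 101), name="copies")

    by_contig: dict[str, list[tuple[int, int]]] = {}
    for c in copies:
        by_contig.setdefault(c.contig, []).append((c.start, c.end))
    masked = sum(_merged_interval_bp(iv) for iv in by_contig.values())

    n = len(copies)
    return LandscapeSummary(
        superfamily_counts=superfams.value_counts().sort_index(),
        class_fractions=(classes.value_counts() / n).sort_index() if n else pd.Series(dtype=float),
        divergence_histogram=hist,
        masked_bp=masked,
        genome_fraction=masked / genome_size,
        n_copies=n,
    )


def distance_to_nearest_gene(
    copies: Sequence[TECopy], genes: pd.DataFrame
) -> tuple[pd.Series, pd.Series]:
    """Distance (bp) from each copy to the nearest gene, strand-ignored.

    A copy overlapping any gene gets distance 0; otherwise the minimum
    gap to the closest gene boundary on the same contig. Copies on
    contigs with no annotated gene get NaN.

    Returns ``(per_copy, per_family_mean)``; ``per_copy`` is indexed
    like ``copies`` and ``per_family_mean`` by family name.
    """
    if genes is None or len(genes) == 0:
        raise ValueError("gene set is empty: distances are undefined")

    gene_arrays = {
        contig: (grp["start"].to_numpy(), grp["end"].to_numpy())
        for contig, grp in genes.groupby("contig")
    }
    dists = np.full(len(copies), np.nan)
    for i, c in enumerate(copies):
        arrs = gene_arrays.get(c.contig)
        if arrs is None:
            continue
        gstart, gend = arrs
        overlap = (gstart < c.end) & (gend > c.start)
        if overlap.any():
            dists[i] = 0
        else:
            # copy entirely left (gap = gstart - end) or right (start - gend)
            gaps = np.where(gstart >= c.end, gstart - c.end, c.start - gend)
            dists[i] = gaps.min()
    per_copy = pd.Series(dists, name="distance_bp")
    fams = pd.Series([c.family_name for c in copies], name="family")
    per_family = per_copy.groupby(fams).mean()
    return per_copy, per_family


def copies_to_frame(copies: Sequence[TECopy]) -> pd.DataFrame:
    """Tabulate copies for TSV export."""
    return pd.DataFrame(
        {
            "family": [c.family_name for c in copies],
            "contig": [c.contig for c in copies],
            "start": [c.start for c in copies],
            "end": [c.end for c in copies],
            "strand": [c.strand for c in copies],
            "mean_divergence": [c.mean_divergence for c in copies],
            "n_fragments": [c.n_fragments for c in copies],
        }
    )


def family_factors(
    copies: Sequence[TECopy], genes: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-family covariates used in expression correlations.

    Copy number, mean divergence (an age proxy: older families have
    drifted further from consensus) and, when gene intervals are
    given, mean distance to the nearest gene.
    """
    df = copies_to_frame(copies)
    out = df.groupby("family").agg(
        copy_number=("family", "size"), mean_divergence=("mean_divergence", "mean")
    )
    if genes is not None and len(genes):
        _, per_family = distance_to_nearest_gene(copies, genes)
        out["mean_gene_distance"] = per_family
    return out
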