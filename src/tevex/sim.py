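"""Synthetic data generation with ground truth for every pipeline stage.

Emulates the study system end to end: a large (~100 kb) double-stranded
DNA viral genome akin to a baculovirus, a library of TE consensus
sequences with terminal inverted repeats, host-TE insertions planted
into viral genomes with duplicated target sites (TSDs: the short viral
motif copied to both flanks during canonical transposition, e.g. TTAA
for piggyBac, a 3-mer for Harbinger), single-end reads spanning the
TE-virus junctions, and negative-binomial count tables with planted
fold changes for the differential-expression stage.

All generators are bit-reproducible under a fixed seed, and every read
carries a provenance label so that downstream detection can be scored
against truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import TEFamily
from .seqio import reverse_complement

logger = logging.getLogger(__name__)

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the simulator.

    ``read_length`` defaults to 101 bp (the cell-line libraries; the
    midgut libraries were 51 bp). ``depth`` is the mean read coverage
    per transcript position.
    """

    seed: int = 0
    viral_length: int = 100_000
    gc: float = 0.41  # AcMNPV-like GC content
    read_length: int = 101
    depth: float = 30.0
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.viral_length < 1000:
            raise ValueError("viral_length must be >= 1000")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be in [0, 1]")
        if self.read_length < 1:
            raise ValueError("read_length must be positive")
        if not 0.0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


@dataclass(frozen=True)
class PlantedInsertion:
    """A TE insertion planted at a known position on the viral genome.

    ``viral_coord`` is the 0-based position on the TE-free reference
    where the TSD motif starts; ``tsd_motif`` may be empty (blunt
    insertion, no duplication).
    """

    family_name: str
    viral_coord: int
    tsd_motif: str = ""
    orientation: str = "+"

    def __post_init__(self) -> None:
        if self.viral_coord < 0:
            raise ValueError("viral_coord must be >= 0")
        if self.orientation not in ("+", "-"):
            raise ValueError("orientation must be '+' or '-'")


@dataclass(frozen=True)
class ReadProvenance:
    read_id: str
    origin: str  # virus | te | junction_5p | junction_3p | host_gene
    insertion_ref: PlantedInsertion | None = None

    def __post_init__(self) -> None:
        if self.origin.startswith("junction") and self.insertion_ref is None:
            raise ValueError("junction reads must reference their insertion")


@dataclass(frozen=True)
class CountSimTruth:
    """Ground truth for one entity in a simulated count table.

    NB parameterisation: variance = mu + dispersion * mu**2.
    """

    entity: str
    true_log2fc: float
    true_mean: float
    dispersion: float = 0.05

    def __post_init__(self) -> None:
        if self.true_mean <= 0:
            raise ValueError("true_mean must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


# ---------------------------------------------------------------------------
# sequence generation


def generate_viral_genome(config: SimConfig, rng: np.random.Generator | None = None) -> str:
    """Random viral genome of ``viral_length`` bp at the given GC content.

    The genome is treated as linear: reads never span the circular
    origin, matching linear-coordinate downstream analyses.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return random_sequence(config.viral_length, config.gc, rng)


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]
    return "".join(rng.choice(_BASES, size=length, p=p))


#: Default superfamily templates: (superfamily, class, TSD motif). The
#: TSD motifs follow the canonical integration-site preferences of
#: each superfamily (piggyBac duplicates TTAA; Harbinger a 3-mer).
DEFAULT_SUPERFAMILIES: tuple[tuple[str, str, str], ...] = (
    ("PiggyBac", "II", "TTAA"),
    ("PiggyBac", "II", "ATAA"),
    ("PIF-Harbinger", "II", "TTA"),
    ("L2", "I", ""),
    ("Gypsy", "I", ""),
    ("R1", "I", ""),
)


def generate_te_library(
    n_families: int,
    rng: np.random.Generator,
    length_range: tuple[int, int] = (600, 1600),
    gc: float = 0.40,
    tir_length: int = 13,
    superfamilies: Sequence[tuple[str, str, str]] = DEFAULT_SUPERFAMILIES,
) -> tuple[list[TEFamily], dict[str, str]]:
    """Random TE consensus library with terminal inverted repeats.

    Families cycle through ``superfamilies``; class II consensus get a
    TIR (the reverse complement of the 5' terminus at the 3' end),
    mimicking DNA-transposon structure. Returns the families and a
    ``{family_name: preferred TSD motif}`` map.
    """
    families: list[TEFamily] = []
    tsd_of: dict[str, str] = {}
    for i in range(n_families):
        superfam, te_class, tsd = superfamilies[i % len(superfamilies)]
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        body = random_sequence(length, gc, rng)
        if te_class == "II" and length > 2 * tir_length:
            tir = body[:tir_length]
            body = body[: length - tir_length] + reverse_complement(tir)
        name = f"{superfam}_{i + 1}"
        families.append(TEFamily(name=name, te_class=te_class, superfamily=superfam, consensus=body))
        tsd_of[name] = tsd
    return families, tsd_of


def choose_insertion_sites(
    reference: str,
    motif: str,
    n: int,
    rng: np.random.Generator,
    min_separation: int = 500,
    margin: int = 300,
    exclude: Iterable[int] = (),
) -> list[int]:
    """Sample ``n`` motif occurrences on the reference as insertion sites.

    Sites are at least ``min_separation`` bp apart and at least
    ``margin`` bp from the reference ends so junction-spanning reads
    fit. An empty motif samples arbitrary coordinates. ``exclude``
    lists coordinates already taken (the separation constraint is
    enforced against them too).
    """
    if motif:
        candidates = []
        pos = reference.find(motif, margin)
        while pos != -1 and pos <= len(reference) - margin - len(motif):
            candidates.append(pos)
            pos = reference.find(motif, pos + 1)
        candidates = np.array(candidates, dtype=int)
    else:
        candidates = np.arange(margin, len(reference) - margin, dtype=int)

    taken = list(exclude)
    chosen: list[int] = []
    order = rng.permutation(len(candidates))
    for idx in order:
        c = int(candidates[idx])
        if all(abs(c - t) >= min_separation for t in taken):
            chosen.append(c)
            taken.append(c)
            if len(chosen) == n:
                return sorted(chosen)
    raise ValueError(
        f"could not place {n} sites for motif {motif!r} with separation {min_separation}"
    )


def plant_insertion(
    reference: str, te: TEFamily, ins: PlantedInsertion
) -> tuple[str, int, int]:
    """Insert a TE into the reference, duplicating the TSD motif.

    The motif at ``[viral_coord, viral_coord + k)`` ends up on both
    flanks of the inserted (oriented) TE. Returns ``(modified_sequence,
    left_junction, right_junction)`` where both junction coordinates
    are on the TE-free reference: ``left = viral_coord + k`` and
    ``right = viral_coord`` (they differ by exactly the motif length).
    """
    k = len(ins.tsd_motif)
    c = ins.viral_coord
    if c + k > len(reference):
        raise ValueError("insertion coordinate outside reference")
    if reference[c : c + k] != ins.tsd_motif:
        raise ValueError(
            f"TSD motif {ins.tsd_motif!r} absent at coordinate {c} "
            f"(found {reference[c:c + k]!r})"
        )
    te_seq = te.consensus if ins.orientation == "+" else reverse_complement(te.consensus)
    modified = reference[: c + k] + te_seq + reference[c:]
    return modified, c + k, c


def junction_templates(
    reference: str,
    te: TEFamily,
    ins: PlantedInsertion,
    flank: int = 200,
) -> list[tuple[str, str, str, PlantedInsertion]]:
    """Transcript templates centred on each junction of a planted insertion.

    Returns two ``(name, sequence, origin, insertion)`` tuples, one per
    junction. The origin labels which TE extremity abuts the junction:
    for a '+' insertion the left junction meets the TE 5' end
    (``junction_5p``) and the right junction its 3' end; for a '-'
    insertion the labels swap.
    """
    modified, left_j, right_j = plant_insertion(reference, te, ins)
    k = len(ins.tsd_motif)
    te_len = te.length
    # positions of the two junctions on the modified sequence
    left_mod = ins.viral_coord + k
    right_mod = left_mod + te_len
    left_origin = "junction_5p" if ins.orientation == "+" else "junction_3p"
    right_origin = "junction_3p" if ins.orientation == "+" else "junction_5p"
    out = []
    for mod_pos, origin in ((left_mod, left_origin), (right_mod, right_origin)):
        lo = max(0, mod_pos - flank)
        hi = min(len(modified), mod_pos + flank)
        name = f"{ins.family_name}@{ins.viral_coord}:{origin}"
        out.append((name, modified[lo:hi], origin, ins))
    return out


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(
    templates: Sequence[tuple[str, str, str, PlantedInsertion | None]],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str, str]], list[ReadProvenance]]:
    """Uniform-start single-end reads from transcript templates.

    Each template ``(name, sequence, origin, insertion_or_None)``
    yields a Poisson number of reads with mean
    ``depth * (L - read_length + 1) / read_length`` (so mean per-base
    coverage is ~``depth``), start positions uniform, and independent
    per-base substitutions at ``error_rate``. Qualities are constant
    'I' (Phred 40). Templates shorter than the read length are skipped
    with a warning.

    Returns FASTQ-style ``(read_id, sequence, quality)`` tuples and a
    parallel provenance list.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rl = config.read_length
    qual = "I" * rl
    reads: list[tuple[str, str, str]] = []
    prov: list[ReadProvenance] = []
    for name, seq, origin, ins in templates:
        L = len(seq)
        if L < rl:
            logger.warning("template %s shorter than read length (%d < %d); skipped", name, L, rl)
            continue
        n_starts = L - rl + 1
        n_reads = int(rng.poisson(config.depth * n_starts / rl))
        starts = rng.integers(0, n_starts, size=n_reads)
        for j, s in enumerate(starts):
            read = seq[s : s + rl]
            if config.error_rate > 0:
                read = _mutate(read, config.error_rate, rng)
            rid = f"{name}/{j}"
            reads.append((rid, read, qual))
            prov.append(ReadProvenance(read_id=rid, origin=origin, insertion_ref=ins))
    return reads, prov


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < error_rate
    if hit.any():
        idx = np.flatnonzero(hit)
        for i in idx:
            choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
            arr[i] = bytes([choices[rng.integers(0, 3)]])
    return arr.tobytes().decode()


def provenance_frame(prov: Sequence[ReadProvenance]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [p.read_id for p in prov],
            "origin": [p.origin for p in prov],
            "family": [p.insertion_ref.family_name if p.insertion_ref else "" for p in prov],
            "viral_coord": [
                p.insertion_ref.viral_coord if p.insertion_ref else -1 for p in prov
            ],
        }
    )


# ---------------------------------------------------------------------------
# count-table simulation


def simulate_count_table(
    truth: Sequence[CountSimTruth],
    n_replicates_per_condition: int,
    library_sizes: Sequence[float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial counts with planted per-condition fold changes.

    Columns are ``mock_1..mock_n`` then ``infected_1..infected_n``;
    the mean for entity *e* in replicate *r* is
    ``true_mean_e * sizefactor_r * 2**(true_log2fc_e * condition_r)``
    with condition 0 for mock and 1 for infected. ``library_sizes``
    are relative size factors (default all 1). Dispersion 0 reduces to
    Poisson; otherwise counts are gamma-Poisson with
    variance = mu + dispersion * mu**2.

    Returns ``(counts, samples)``: counts indexed by entity, and a
    sample table with ``condition`` per column.
    """
    n = n_replicates_per_condition
    if n < 2:
        raise ValueError("need at least 2 replicates per condition")
    if library_sizes is None:
        library_sizes = [1.0] * (2 * n)
    library_sizes = np.asarray(library_sizes, dtype=float)
    if len(library_sizes) != 2 * n:
        raise ValueError("library_sizes must have one entry per replicate")
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")

    rng = np.random.default_rng(seed)
    cols = [f"mock_{i + 1}" for i in range(n)] + [f"infected_{i + 1}" for i in range(n)]
    condition = np.array([0] * n + [1] * n)

    means = np.array([t.true_mean for t in truth])[:, None]
    lfc = np.array([t.true_log2fc for t in truth])[:, None]
    disp = np.array([t.dispersion for t in truth])[:, None]
    mu = means * library_sizes[None, :] * np.power(2.0, lfc * condition[None, :])

    counts = np.empty_like(mu, dtype=np.int64)
    poisson_rows = (disp[:, 0] == 0)
    if poisson_rows.any():
        counts[poisson_rows] = rng.poisson(mu[poisson_rows])
    nb_rows = ~poisson_rows
    if nb_rows.any():
        shape = 1.0 / disp[nb_rows]
        lam = rng.gamma(shape=shape, scale=mu[nb_rows] * disp[nb_rows])
        counts[nb_rows] = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=[t.entity for t in truth], columns=cols)
    samples = pd.DataFrame(
        {"condition": np.where(condition == 0, "mock", "infected")}, index=cols
    )
    return counts_df, samples


def truth_frame(truth: Sequence[CountSimTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "entity": [t.entity for t in truth],
            "true_log2fc": [t.true_log2fc for t in truth],
            "true_mean": [t.true_mean for t in truth],
            "dispersion": [t.dispersion for t in truth],
        }
    )
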