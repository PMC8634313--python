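"""End-to-end convenience workflows over the module-level operations.

These compose the simulator, aligner, chimera caller and TSD pairing
into the two standard runs: simulating an infection data set with
planted virus-borne TE insertions, and taking its reads through
detection back to insertion calls scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import align, chimera, tsd
from .annotation import TEFamily
from .sim import (
    PlantedInsertion,
    ReadProvenance,
    SimConfig,
    choose_insertion_sites,
    generate_te_library,
    generate_viral_genome,
    junction_templates,
    simulate_reads,
)


@dataclass
class InfectionDataset:
    """A simulated infection: genome, TE library, insertions, reads, truth."""

    config: SimConfig
    genome: str
    families: list[TEFamily]
    tsd_of: dict[str, str]
    insertions: list[PlantedInsertion]
    reads: list[tuple[str, str, str]]
    provenance: list[ReadProvenance]

    @property
    def te_lengths(self) -> dict[str, int]:
        return {f.name: f.length for f in self.families}

    def planted_truth(self) -> pd.DataFrame:
        """Expected insertion calls: family, orientation, 5'/3' coordinates, motif.

        For a '+' insertion the TE 5' extremity abuts the left junction
        (coordinate ``viral_coord + k`` on the TE-free reference) and
        the 3' extremity the right one (``viral_coord``); for a '-'
        insertion the sides swap.
        """
        rows = []
        for ins in self.insertions:
            k = len(ins.tsd_motif)
            left, right = ins.viral_coord + k, ins.viral_coord
            c5, c3 = (left, right) if ins.orientation == "+" else (right, left)
            rows.append(
                {
                    "family": ins.family_name,
                    "orientation": ins.orientation,
                    "viral_coord_5p": c5,
                    "viral_coord_3p": c3,
                    "tsd_motif": ins.tsd_motif,
                }
            )
        return pd.DataFrame(rows)


def simulate_infection_dataset(
    config: SimConfig,
    n_families: int = 6,
    n_insertions: int = 20,
    flank: int = 200,
) -> InfectionDataset:
    """Simulate a viral genome with planted TE insertions and junction reads.

    Families cycle through the default superfamily templates (two
    piggyBac-like with TTAA/ATAA TSDs, one Harbinger-like with a TTA
    TSD, and blunt-inserting retroelements), insertions are placed at
    motif occurrences on the genome with random orientation, and reads
    are drawn from transcript templates spanning each junction at the
    configured depth and error rate. Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    genome = generate_viral_genome(config, rng)
    families, tsd_of = generate_te_library(n_families, rng)
    fam_by_name = {f.name: f for f in families}

    insertions: list[PlantedInsertion] = []
    taken: list[int] = []
    for i in range(n_insertions):
        fam = families[i % len(families)]
        motif = tsd_of[fam.name]
        coord = choose_insertion_sites(genome, motif, 1, rng, exclude=taken)[0]
        taken.append(coord)
        orientation = "+" if rng.random() < 0.5 else "-"
        insertions.append(PlantedInsertion(fam.name, coord, motif, orientation))

    templates = []
    for ins in insertions:
        templates.extend(junction_templates(genome, fam_by_name[ins.family_name], ins, flank))
    reads, provenance = simulate_reads(templates, config, rng)
    return InfectionDataset(
        config=config,
        genome=genome,
        families=families,
        tsd_of=tsd_of,
        insertions=insertions,
        reads=reads,
        provenance=provenance,
    )


@dataclass
class ChimeraRun:
    alignments: list[chimera.ReadAlignment]
    chimeras: list[chimera.ChimericRead]
    calls: list[tsd.InsertionCall]
    summary: tsd.InsertionSummary


def run_chimera_pipeline(
    dataset: InfectionDataset,
    reads: Sequence[tuple[str, str, str]] | None = None,
    min_segment: int = chimera.DEFAULT_MIN_SEGMENT,
    overlap_tol: int = chimera.DEFAULT_OVERLAP_TOL,
    tip_tol: int = chimera.DEFAULT_TIP_TOL,
    max_delta: int = tsd.DEFAULT_MAX_DELTA,
) -> ChimeraRun:
    """Align reads, call chimeras, pair junctions and extract TSD motifs."""
    if reads is None:
        reads = dataset.reads
    virus_index = align.SeedIndex({"virus": dataset.genome}, "virus")
    te_index = align.SeedIndex({f.name: f.consensus for f in dataset.families}, "te")
    alignments = align.align_reads(reads, [virus_index, te_index], min_length=min_segment)
    chimeras = chimera.detect_chimeras(
        alignments,
        dataset.te_lengths,
        min_segment=min_segment,
        overlap_tol=overlap_tol,
        tip_tol=tip_tol,
    )
    calls = tsd.pair_junctions(chimeras, max_delta=max_delta)
    tsd.annotate_motifs(calls, dataset.genome)
    return ChimeraRun(
        alignments=alignments,
        chimeras=chimeras,
        calls=calls,
        summary=tsd.count_distinct_insertions(calls),
    )


def score_recovery(dataset: InfectionDataset, run: ChimeraRun) -> dict[str, float]:
    """Score insertion calls against planted truth.

    Returns exact-coordinate recovery and motif accuracy as fractions,
    plus the raw counts of planted sites, calls and spurious calls.
    """
    truth = dataset.planted_truth()
    planted = {
        (r.family, r.orientation, r.viral_coord_5p, r.viral_coord_3p): r.tsd_motif
        for r in truth.itertuples()
    }
    recovered = {
        (c.family_name, c.orientation, c.viral_coord_5p, c.viral_coord_3p): c.tsd_motif
        for c in run.calls
    }
    hits = set(planted) & set(recovered)
    motifs_ok = sum(planted[k] == recovered[k] for k in hits)
    return {
        "n_planted": len(planted),
        "n_calls": len(recovered),
        "n_recovered_exact": len(hits),
        "n_spurious": len(set(recovered) - set(planted)),
        "recovery": len(hits) / len(planted) if planted else float("nan"),
        "motif_accuracy": motifs_ok / len(hits) if hits else float("nan"),
    }
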