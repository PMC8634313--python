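import numpy as np
import pytest

from tevex import sim, workflows


@pytest.fixture(scope="session")
def infection_dataset() -> workflows.InfectionDataset:
    """100-kb viral genome, 6 TE families, 20 planted insertions with
    TSDs in {TTAA, ATAA, TTA, ''}, error-free 101-bp reads at 30x
    junction coverage."""
    cfg = sim.SimConfig(seed=11, viral_length=100_000, read_length=101, depth=30.0, error_rate=0.0)
    return workflows.simulate_infection_dataset(cfg, n_families=6, n_insertions=20)


@pytest.fixture(scope="session")
def chimera_run(infection_dataset) -> workflows.ChimeraRun:
    return workflows.run_chimera_pipeline(infection_dataset)


@pytest.fixture(scope="session")
def negative_reads(infection_dataset):
    """Reads from the same virus and TE library with no planted insertion."""
    ds = infection_dataset
    templates = [("virus_only", ds.genome[4000:12000], "virus", None)]
    templates += [(f"{f.name}_only", f.consensus, "te", None) for f in ds.families]
    reads, _ = sim.simulate_reads(templates, ds.config, np.random.default_rng(97))
    return reads


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
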