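"""Shared fixtures: toy anatomies and simulated assays with known truth."""

import pytest

from shmkit.assay import map_features, normalize
from shmkit.simulate import make_toy_asvg, simulate_bulk, simulate_cells

FEATURES = ["brain", "liver", "lung", "kidney", "colon"]


@pytest.fixture(scope="session")
def toy_doc():
    """Five-feature anatomy with ids renamed to organ labels."""
    doc = make_toy_asvg(5, seed=1)
    for f, name in zip(doc.features, FEATURES):
        f.id = name
    return doc


@pytest.fixture(scope="session")
def bulk_sim():
    """Medium bulk simulation: 300 genes, 5 features x 4 replicates."""
    assay, truth = simulate_bulk(
        300, FEATURES, replicates=4, planted_frac=0.1, lfc=3.0, seed=11
    )
    return assay, truth


@pytest.fixture(scope="session")
def log_assay(bulk_sim):
    assay, _ = bulk_sim
    return normalize(assay, method="cpm", log2=True)


@pytest.fixture(scope="session")
def fmap(log_assay, toy_doc):
    return map_features(log_assay, toy_doc)


@pytest.fixture(scope="session")
def sc_sim(bulk_sim):
    """Cells drawn from the bulk feature profiles, with spatial coords."""
    _, truth = bulk_sim
    sc = simulate_cells(truth, cells_per_group=40, spatial=True, seed=12)
    return sc, truth
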