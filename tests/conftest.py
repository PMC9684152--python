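import numpy as np
import pytest

from gutrace import (FeatureMatrix, SimulationSpec, TaxonTable,
                     simulate_dataset)

#: Desk-scale taxonomy used by simulation-based tests.
SMALL_SHAPE = (6, 12, 20, 32, 48, 72)


@pytest.fixture()
def toy_table() -> TaxonTable:
    """Three fully/partially assigned taxa over two samples."""
    return TaxonTable(
        taxon_ids=["t1", "t2", "t3"],
        lineages=[
            "k__Bacteria; p__A; c__X",
            "k__Bacteria; p__A; c__Y",
            "k__Bacteria; p__B; c__Z",
        ],
        sample_ids=["S1", "S2"],
        values=np.array([[3, 0], [1, 2], [5, 5]]),
        value_kind="counts",
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One synthetic study at desk scale, shared across tests."""
    spec = SimulationSpec(
        n_host_species=8, taxonomy_shape=SMALL_SHAPE, samples_per_cell=3,
        areas_per_species=4, seed=11,
    )
    return simulate_dataset(spec)


def separated_clusters(rng: np.random.Generator, n_per: int = 10, p: int = 3,
                       g: int = 3, sep: float = 50.0):
    """Synthetic classes whose mean separation dwarfs the within-class SD."""
    X = np.vstack([rng.normal(size=(n_per, p)) + sep * k for k in range(g)])
    y = np.repeat([f"c{k}" for k in range(g)], n_per)
    fm = FeatureMatrix(X, [f"f{j}" for j in range(p)],
                       [f"s{i}" for i in range(g * n_per)])
    return fm, y
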