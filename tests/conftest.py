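import numpy as np
import pandas as pd
import pytest

from ferretmeth.pedigree import additive_relationship
from ferretmeth.samples import load_reference_table
from ferretmeth.simulate import SimulationConfig, simulate_dataset, simulate_pedigree


@pytest.fixture(scope="session")
def table1():
    return load_reference_table()


@pytest.fixture(scope="session")
def trio_pedigree():
    """Two founders and four full-sib offspring."""
    return pd.DataFrame(
        {
            "id": ["P1", "P2", "O1", "O2", "O3", "O4"],
            "sire": [None, None, "P1", "P1", "P1", "P1"],
            "dam": [None, None, "P2", "P2", "P2", "P2"],
        }
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Three-tissue, 6-individual dataset with a few causal sites."""
    ped = simulate_pedigree(4, 1, seed=2, offspring_per_generation=2)
    cfg = SimulationConfig(
        n_individuals=6,
        n_sites=40,
        n_scaffolds=2,
        n_lambda_sites=50,
        n_noncg_sites=10,
        seed=7,
    )
    return simulate_dataset(cfg, ped)


@pytest.fixture(scope="session")
def small_kinship(small_dataset):
    A = additive_relationship(small_dataset.pedigree)
    ind_of = dict(
        zip(small_dataset.phenotypes["sample_id"], small_dataset.phenotypes["studbook_no"])
    )
    return A, ind_of


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
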