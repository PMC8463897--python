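import warnings

import numpy as np
import pandas as pd
import pytest

from meselson.genotypes import GenotypeMatrix, SampleMetadata
from meselson.pipeline import dataset_from_simulation
from meselson.simulate import oppiella_like_config, simulate_dataset


def make_matrix(calls, depth=None, individuals=None, scaffold="s1"):
    """GenotypeMatrix from a nested list of genotype codes (sites x inds)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_sites, n_ind = calls.shape
    if depth is None:
        depth = np.full(calls.shape, 30, dtype=np.int32)
    else:
        depth = np.asarray(depth, dtype=np.int32)
    if individuals is None:
        individuals = [f"i{j}" for j in range(n_ind)]
    sites = pd.DataFrame(
        {
            "scaffold": scaffold,
            "pos": np.arange(n_sites),
            "ref": "A",
            "alt": "G",
            "is_indel": False,
            "n_alleles": 2,
        }
    )
    return GenotypeMatrix(sites=sites, individuals=list(individuals),
                          calls=calls, depth=depth)


def make_metadata(pop_of, lineage_of=None):
    lineage_of = lineage_of or {}
    rows = [(i, p, lineage_of.get(i, pd.NA)) for i, p in pop_of.items()]
    return SampleMetadata(
        pd.DataFrame(rows, columns=["individual", "population", "lineage"])
    )


@pytest.fixture(scope="session")
def asex_sim():
    cfg = oppiella_like_config(
        "asexual", n_regions=8, region_length_bp=300, seed=42
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def sex_sim():
    # population differentiation (~55% among-population variance) needs a few
    # more regions than the clonal fixture before Monte-Carlo noise can no
    # longer push the among-population share below the within-individual one
    cfg = oppiella_like_config(
        "sexual", n_regions=20, region_length_bp=400, seed=42
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def asex_dataset(asex_sim):
    return dataset_from_simulation(asex_sim)


@pytest.fixture(scope="session")
def sex_dataset(sex_sim):
    return dataset_from_simulation(sex_sim)
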