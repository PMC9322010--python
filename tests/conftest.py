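import numpy as np
import pandas as pd
import pytest

from distdecay.dataset import CommunityDataset, DatasetMeta
from distdecay.simulate import SimulationParams, simulate_dataset


@pytest.fixture(scope="session")
def sim_dataset():
    """A mid-sized simulated dataset with both spatial and environmental structure."""
    return simulate_dataset(SimulationParams(n_sites=15, n_species=30, seed=42))


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset for the slower (hypervolume) paths."""
    return simulate_dataset(SimulationParams(n_sites=10, n_species=20, seed=7))


@pytest.fixture()
def toy_dataset():
    """Hand-built 3-site, 5-species dataset with known overlaps."""
    sites = ["A", "B", "C"]
    species = [f"sp{i}" for i in range(1, 6)]
    abundance = pd.DataFrame(
        [
            [3.0, 1.0, 0.0, 0.0, 2.0],
            [0.0, 1.0, 4.0, 0.0, 2.0],
            [0.0, 0.0, 0.0, 5.0, 1.0],
        ],
        index=sites,
        columns=species,
    )
    traits = pd.DataFrame(
        {
            "size": [1.0, 2.0, 3.0, 4.0, 5.0],
            "shape": [0.0, 1.0, 0.0, 1.0, 0.0],
            "habit": ["x", "y", "x", "y", "x"],
        },
        index=species,
    )
    coords = pd.DataFrame(
        {"latitude": [0.0, 0.5, 1.0], "longitude": [0.0, 0.5, 1.0]}, index=sites
    )
    env = pd.DataFrame(
        {"temp": [10.0, 12.0, 20.0], "ph": [6.5, 7.0, 8.0]}, index=sites
    )
    return CommunityDataset(abundance, traits, coords, env, meta=DatasetMeta())


@pytest.fixture()
def disjoint_identical_traits_dataset():
    """Two sites sharing no species, but each species has a functional twin in
    the other community: taxonomic similarity 0, functional similarity high."""
    species = [f"s{i}" for i in range(8)]
    abundance = pd.DataFrame(
        [[1, 1, 1, 1, 0, 0, 0, 0], [0, 0, 0, 0, 1, 1, 1, 1]],
        index=["A", "B"],
        columns=species,
        dtype=float,
    )
    base = np.column_stack(
        [np.array([0.0, 1.0, 2.0, 3.0]), np.array([1.0, 0.0, 1.0, 0.0]), np.array([2.0, 1.0, 0.0, 3.0])]
    )
    traits = pd.DataFrame(
        np.vstack([base, base]), index=species, columns=["t1", "t2", "t3"]
    )
    coords = pd.DataFrame({"latitude": [0.0, 0.2], "longitude": [0.0, 0.2]}, index=["A", "B"])
    env = pd.DataFrame({"e1": [0.0, 1.0], "e2": [1.0, 0.0]}, index=["A", "B"])
    return CommunityDataset(abundance, traits, coords, env)
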