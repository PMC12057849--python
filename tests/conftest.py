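import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ecoassembly.io import CommunityTable, PhyloTree
from skbio import TreeNode
from io import StringIO


@pytest.fixture
def toy_table():
    """3 samples x 4 taxa count table, two groups."""
    data = pd.DataFrame(
        [[2, 2, 6, 0], [1, 0, 3, 6], [5, 5, 0, 0]],
        index=["s1", "s2", "s3"], columns=["A", "B", "C", "D"], dtype=float,
    )
    groups = pd.Series({"s1": "G1", "s2": "G1", "s3": "G2"})
    return CommunityTable(data, groups)


@pytest.fixture
def toy_tree():
    """((A:1,B:1):1,(C:1,D:1):1); patristic d(A,B)=2, d(A,C)=4."""
    return PhyloTree(TreeNode.read(StringIO("((A:1,B:1):1,(C:1,D:1):1);")))


@pytest.fixture(scope="session")
def small_sim():
    """One small selection-regime dataset shared across tests."""
    from ecoassembly.simulate import SimConfig, simulate_dataset

    cfg = SimConfig(
        n_taxa=120, n_groups=2, reps_per_group=(5, 5), depth=3000,
        selection_strength=0.8, dispersal_rate=0.3,
        env_gradient=(-2.0, 2.0), seed=2024)
    return simulate_dataset(cfg)


def random_table(rng, n_samples=6, n_taxa=20, groups=2):
    data = pd.DataFrame(
        rng.integers(0, 50, (n_samples, n_taxa)) + (rng.random((n_samples, n_taxa)) < 0.5),
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"t{j:02d}" for j in range(n_taxa)], dtype=float,
    )
    data.iloc[:, 0] += 1  # guarantee nonzero rows
    labels = pd.Series({f"s{i}": f"G{i % groups}" for i in range(n_samples)})
    return CommunityTable(data, labels)
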