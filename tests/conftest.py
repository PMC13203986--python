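import numpy as np
import pandas as pd
import pytest
from io import StringIO
from skbio import TreeNode

import neutralcore as nc


@pytest.fixture()
def toy_tree() -> TreeNode:
    """Four-leaf balanced tree, every branch length 1, total length 6."""
    tree = TreeNode.read(StringIO("((A:1,B:1):1,(C:1,D:1):1):0;"))
    return tree


@pytest.fixture()
def toy_table() -> nc.FeatureTable:
    frame = pd.DataFrame(
        [[4, 0, 0, 0], [0, 4, 0, 0], [0, 0, 4, 0], [2, 2, 0, 0]],
        index=["s1", "s2", "s3", "s4"],
        columns=["A", "B", "C", "D"],
    )
    return nc.FeatureTable(frame)


@pytest.fixture(scope="session")
def neutral_sim():
    """One medium neutral community shared across read-only tests:
    1000 taxa, 60 samples, depth 4000, m = 0.05."""
    profile = nc.simulate_metacommunity(1000, sigma=2.0, seed=11)
    table = nc.simulate_neutral_local_communities(profile, 60, 4000, 0.05, seed=11)
    return profile, table


@pytest.fixture(scope="session")
def small_survey():
    """Reduced invasion survey for pipeline-level tests."""
    spec = nc.SimulationSpec(
        n_taxa=300,
        reads_per_sample=500,
        plots_per_cell=4,
        design={
            2019: (("L1", "L2", "L3"), ("uninvaded", "invaded")),
            2022: (("L4", "L5", "L6"), ("uninvaded", "invaded", "rhizosphere")),
        },
        n_selected=5,
        rng_seed=21,
    )
    return nc.simulate_invasion_design(spec)
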