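import numpy as np
import pandas as pd
import pytest

import fluvimyco as fm


@pytest.fixture
def three_tip_tree() -> fm.PhyloTree:
    return fm.PhyloTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def small_table() -> fm.OtuTable:
    counts = pd.DataFrame(
        [[4, 1, 0], [0, 2, 6], [3, 3, 3]],
        index=["s1", "s2", "s3"], columns=["A", "B", "C"])
    return fm.OtuTable(counts)


@pytest.fixture
def small_env() -> fm.EnvTable:
    rng = np.random.default_rng(0)
    data = pd.DataFrame({
        "salinity": [0.2, 8.0, 31.5],
        "temperature": [20.0, 19.0, 17.5],
        "depth": [2.0, 9.0, 15.0],
    }, index=["s1", "s2", "s3"])
    return fm.EnvTable(data, pd.Series([0.0, 100.0, 217.8],
                                       index=data.index, name="channel_km"))


def random_tree_table(n_tips: int, n_samples: int, seed: int,
                      depth: int = 200):
    """A random (tree, table) instance for oracle comparisons."""
    rng = np.random.default_rng(seed)
    tree = fm.simulate_tree(n_tips, seed=seed)
    counts = rng.integers(0, 20, size=(n_samples, n_tips))
    # guarantee nonzero rows
    counts[counts.sum(axis=1) == 0, 0] = 1
    table = fm.OtuTable(pd.DataFrame(
        counts, index=[f"s{i}" for i in range(n_samples)],
        columns=tree.tip_labels))
    return tree, table
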