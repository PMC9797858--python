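import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from ecoassembly import CommunityTable, SampleMetadata


@pytest.fixture
def tiny_table():
    """3 taxa x 2 samples, hand-checkable counts."""
    return CommunityTable(
        pd.DataFrame(
            [[1, 2, 3], [3, 2, 1]],
            index=["s1", "s2"],
            columns=["A", "B", "C"],
        )
    )


@pytest.fixture
def cherry_tree():
    return TreeNode.read(["(A:1,B:1);"])


@pytest.fixture
def four_tip_tree():
    return TreeNode.read(["((A:1,B:1):1,(C:2,D:0.5):1);"])


@pytest.fixture
def grouped_table():
    """6 samples in 3 groups over 4 taxa, clear group structure."""
    rng = np.random.default_rng(42)
    base = {
        "g1": np.array([50, 5, 1, 1]),
        "g2": np.array([1, 50, 5, 1]),
        "g3": np.array([1, 1, 5, 50]),
    }
    rows, ids, groups = [], [], []
    for g, profile in base.items():
        for r in range(2):
            rows.append(profile + rng.integers(0, 3, size=4))
            ids.append(f"{g}_r{r}")
            groups.append(g)
    table = CommunityTable(
        pd.DataFrame(rows, index=ids, columns=["A", "B", "C", "D"])
    )
    meta = SampleMetadata(
        pd.DataFrame({"group": groups}, index=pd.Index(ids, name="sample_id"))
    )
    return table, meta


def random_tree_and_counts(rng, n_taxa, n_samples, depth=200):
    """Small random instance for oracle comparisons."""
    from ecoassembly import simulate_phylogeny

    tree = simulate_phylogeny(n_taxa, seed=rng.integers(2**31))
    labels = sorted(t.name for t in tree.tips())
    counts = rng.integers(0, 20, size=(n_samples, n_taxa))
    # ensure no empty samples
    for i in range(n_samples):
        if counts[i].sum() == 0:
            counts[i, rng.integers(n_taxa)] = 1
    table = CommunityTable(
        pd.DataFrame(counts, index=[f"s{i}" for i in range(n_samples)], columns=labels)
    )
    return tree, table
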