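"""Shared fixtures: all test data are generated programmatically."""

import numpy as np
import pandas as pd
import pytest

from ecoassembly import CommunityMatrix, Phylogeny


@pytest.fixture
def small_tree() -> Phylogeny:
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree() -> Phylogeny:
    return Phylogeny.from_newick("(A:1.5,B:1.5,C:1.5,D:1.5);")


@pytest.fixture
def small_community() -> CommunityMatrix:
    data = pd.DataFrame(
        [[4, 1, 0], [0, 2, 2], [1, 1, 1]],
        index=["s1", "s2", "s3"],
        columns=["A", "B", "C"],
    )
    return CommunityMatrix(data)


def random_instance(seed: int, n_sites: int = 2, n_taxa: int = 8, total: int = 50):
    """A random tree plus a patchy community for oracle comparisons.

    Each site holds a random subset of the taxa so occupancy varies --
    fully saturated tables make every pair degenerate under tip
    shuffling (shared taxa are fixed points of the null).
    """
    from ecoassembly import simulate_tree

    rng = np.random.default_rng(seed)
    tree = simulate_tree(n_taxa, seed=seed)
    taxa = sorted(tree.tip_labels)
    counts = np.zeros((n_sites, n_taxa), dtype=int)
    for k in range(n_sites):
        richness = int(rng.integers(2, max(3, n_taxa // 2 + 2)))
        members = rng.choice(n_taxa, size=richness, replace=False)
        counts[k, members] = rng.multinomial(total, rng.dirichlet(np.ones(richness)))
        if counts[k].sum() == 0:
            counts[k, members[0]] = 1
    table = pd.DataFrame(counts, index=[f"s{i}" for i in range(n_sites)], columns=taxa)
    table = table.loc[:, table.sum(axis=0) > 0]
    return CommunityMatrix(table), tree


@pytest.fixture
def pair_label_frame() -> pd.DataFrame:
    """Hand-written classified pairs over four sites A-D."""
    rows = [
        ("A", "B", "heterogeneous_selection"),
        ("A", "C", "heterogeneous_selection"),
        ("A", "D", "drift"),
        ("B", "C", "drift"),
        ("B", "D", "dispersal_limitation"),
        ("C", "D", "homogeneous_selection"),
    ]
    df = pd.DataFrame(rows, columns=["site_a", "site_b", "process"])
    df["status"] = "ok"
    return df
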