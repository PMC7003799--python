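import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from interactome import synthetic as syn


@pytest.fixture(scope="session")
def small_survey():
    """A compact synthetic survey with contaminants, shared by I/O tests."""
    cfg = syn.AssemblyConfig(
        n_tips=80, n_sites=4, richness_per_site=20, depth_mean=3000, seed=11
    )
    return syn.simulate_survey(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_table(rng, n_samples=4, n_taxa=8, prefix="T"):
    counts = rng.integers(0, 50, size=(n_samples, n_taxa))
    counts[:, 0] += 1  # no all-zero sample
    return pd.DataFrame(
        counts,
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"{prefix}{j + 1:02d}" for j in range(n_taxa)],
    )


def tree_from_newick(newick: str) -> TreeNode:
    return TreeNode.read([newick])
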