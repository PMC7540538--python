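import numpy as np
import pandas as pd
import pytest

from lakeassembly import (
    CommunityTable,
    PhylogeneticTree,
    SampleMetadata,
    generate_fixture,
)
from skbio import TreeNode


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The deterministic two-lake miniature dataset, written once."""
    out = tmp_path_factory.mktemp("fixture")
    generate_fixture(out)
    return out


@pytest.fixture
def small_table():
    counts = pd.DataFrame(
        [[5, 3, 1, 1], [2, 8, 0, 0], [0, 0, 7, 3]],
        index=["s1", "s2", "s3"],
        columns=["a", "b", "c", "d"],
    )
    return CommunityTable(counts)


@pytest.fixture
def small_tree():
    return PhylogeneticTree(
        TreeNode.read(["((a:0.1,b:0.2):0.3,(c:0.15,d:0.25):0.35);"])
    )


@pytest.fixture
def small_metadata(small_table):
    df = pd.DataFrame(
        {
            "date": ["2015-01-01", "2015-02-01", "2015-03-01"],
            "lake": "L",
            "scale": "annual",
            "temperature": [2.0, 8.0, 14.0],
            "pH": [7.1, 7.3, 7.6],
            "ice_cover": [True, False, False],
        },
        index=small_table.sample_ids,
    )
    return SampleMetadata(df)


def random_table(rng, n_samples=6, n_taxa=10, depth=2000):
    """Random community table helper used across test modules."""
    p = rng.dirichlet(np.ones(n_taxa))
    counts = rng.multinomial(depth, p, size=n_samples)
    counts[:, 0] += 1  # keep at least one taxon always present
    return CommunityTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"t{j:02d}" for j in range(n_taxa)],
        )
    )


def brute_force_bmntd(counts, dist, weighted=True):
    """Independent double-loop betaMNTD (oracle shared across test modules)."""
    n = counts.shape[0]
    out = np.zeros((n, n))
    for k in range(n):
        for l in range(n):
            if k == l:
                continue
            total = 0.0
            for a, b in ((k, l), (l, k)):
                present_b = np.where(counts[b] > 0)[0]
                if weighted:
                    w = counts[a] / counts[a].sum()
                else:
                    w = (counts[a] > 0) / (counts[a] > 0).sum()
                for i in np.where(counts[a] > 0)[0]:
                    total += w[i] * min(dist[i, j] for j in present_b)
            out[k, l] = total / 2.0
    return out
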