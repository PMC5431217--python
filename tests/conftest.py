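import logging

import numpy as np
import pytest

from temporal_beta import CommunityMatrix, SyntheticConfig, generate_dataset

logging.getLogger("temporal_beta").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix():
    """A tiny 4-year, 5-taxon community with full validity."""
    counts = np.array(
        [
            [3, 0, 2, 1, 0],
            [2, 1, 0, 1, 4],
            [0, 2, 1, 1, 3],
            [1, 1, 2, 0, 2],
        ]
    )
    return CommunityMatrix(
        site_id="A",
        years=np.arange(2000, 2004),
        taxa=["t1", "t2", "t3", "t4", "t5"],
        counts=counts,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One study-sized synthetic dataset shared across tests."""
    return generate_dataset(SyntheticConfig(seed=101))


@pytest.fixture(scope="session")
def one_site(default_dataset):
    return default_dataset.matrices[0]
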