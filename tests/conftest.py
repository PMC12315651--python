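import numpy as np
import pytest

import scnmorph as sm


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition synthetic cohort (52 controls / 103 cases)."""
    return sm.generate_cohort(sm.CohortSpec(seed=11))


@pytest.fixture(scope="session")
def null_spec():
    """Spec with no planted group differences (exact null)."""
    return sm.CohortSpec(
        seed=7,
        thinning_effects={},
        topology_b=sm.TopologyParams(k=12, p=0.1, s=0.5),
        chain_coefs=sm.ChainCoefs(a1=0.0, d21=0.0, b2=0.0, b1=0.0, c_prime=0.0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_adjacency(n, p, rng):
    """Simple undirected random adjacency matrix."""
    a = (rng.random((n, n)) < p).astype(float)
    a = np.triu(a, k=1)
    return a + a.T
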