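import numpy as np
import pytest

from powerep import (
    BetaParams,
    ReplicationPair,
    StudySummary,
    UNIFORM_ALPHA_PRIOR,
    labels_pair,
)


@pytest.fixture(scope="session")
def labels():
    """The three original/replication pairs of the Labels experiment."""
    return {k: labels_pair(k) for k in (1, 2, 3)}


@pytest.fixture(scope="session")
def uniform_prior():
    return UNIFORM_ALPHA_PRIOR


@pytest.fixture(scope="session")
def random_pairs():
    """A reproducible batch of random study pairs spanning moderate conflict."""
    rng = np.random.default_rng(20230921)
    pairs = []
    for _ in range(20):
        to = rng.uniform(-1.0, 1.0)
        tr = to + rng.normal(0.0, 0.3)
        so = rng.uniform(0.02, 0.5)
        sr = rng.uniform(0.02, 0.5)
        pairs.append(ReplicationPair(StudySummary(to, so), StudySummary(tr, sr)))
    return pairs


@pytest.fixture(scope="session")
def random_priors():
    rng = np.random.default_rng(11)
    return [BetaParams(rng.uniform(0.5, 5.0), rng.uniform(0.5, 5.0)) for _ in range(20)]
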