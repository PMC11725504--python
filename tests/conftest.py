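import numpy as np
import pytest

from trajalign import AlignmentConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def config():
    return AlignmentConfig(n_interp_points=10, seed=7)


@pytest.fixture(scope="session")
def battery():
    """The full 7-pattern simulation battery, aligned once per session.

    Shared by the acceptance tests for the per-pattern accuracy check and
    the clustering check.
    """
    from trajalign import align_pair, simulate_battery

    pairs = simulate_battery(n_per_pattern=500, seed=42)
    results = [align_pair(p, m=15) for p in pairs]
    return pairs, results
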