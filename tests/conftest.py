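import numpy as np
import pytest

from netstress import (NetworkAtlas, ParcelTimeseries, SimConfig,
                       make_default_atlas, simulate_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_atlas():
    """4-node atlas: 2 DMN, 2 VI."""
    nodes = ("a", "b", "c", "d")
    return NetworkAtlas(node_ids=nodes,
                        affiliation={"a": "DMN", "b": "DMN", "c": "VI", "d": "VI"})


@pytest.fixture
def small_ts(rng):
    """5-node, 50-frame random scan."""
    return ParcelTimeseries(values=rng.standard_normal((5, 50)),
                            node_ids=tuple("abcde"), tr_seconds=0.7,
                            scan_label="pre")


@pytest.fixture(scope="session")
def reduced_atlas():
    return make_default_atlas(60)


@pytest.fixture(scope="session")
def simulated_cohort():
    """One reduced-scale timeseries-mode cohort, reused across tests."""
    return simulate_cohort(SimConfig(seed=11), keep_timeseries=True)
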