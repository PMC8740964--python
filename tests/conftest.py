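import numpy as np
import pytest

from podsim import BeliefSpace, make_fixture, preset


@pytest.fixture
def space():
    return BeliefSpace()


@pytest.fixture
def dcc():
    return preset("dcc")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def line_chain():
    """Institution -> 6-5-4-3-2-1-0 belief-graded chain."""
    return make_fixture("line-chain")


@pytest.fixture
def two_cluster():
    """Two 5-cliques (levels 6 and 0) bridged by one edge."""
    return make_fixture("two-cluster")


@pytest.fixture
def fig2_toy():
    """Ten-agent toy: institution, three subscribers, second-hop neighbors."""
    return make_fixture("fig2-toy")
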