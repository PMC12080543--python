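import numpy as np
import pytest
from hypothesis import settings

from egosign.signed_graph import SignedDigraph

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def hand_graph():
    """3-node graph with edges A->B:+, A->C:-, B->C:+, C->B:+ (A,B,C = 0,1,2).

    Hand enumeration of its ego-triads: only node 0 has two out-links, so
    the focal triples are (0,1,2) with inner 1->2 giving signs (+,-,+)
    (unbalanced nonhierarchical, UN1) and (0,2,1) with inner 2->1 giving
    signs (-,+,+) (unbalanced hierarchical, UH1).
    """
    return SignedDigraph(3, src=[0, 0, 1, 2], dst=[1, 2, 2, 1],
                         sign=[1, -1, 1, 1])


@pytest.fixture
def triangle_plus_dangling():
    """Closed triad on {0,1,2} plus a dangling edge 3->0 in no ego-triad."""
    return SignedDigraph(4, src=[0, 0, 1, 3], dst=[1, 2, 2, 0],
                         sign=[1, 1, -1, 1])
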