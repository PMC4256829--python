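import pytest
from hypothesis import settings

from fflrx.regnet import EdgeType, RegulatoryNetwork

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


def build_network(edges):
    """Construct a network from (source, target, edge_type) triples."""
    net = RegulatoryNetwork()
    for s, t, et in edges:
        net.add_edge(s, t, EdgeType(et))
    return net


@pytest.fixture
def planted_composite_net():
    """One composite FFL: m1 <-> t1 co-regulating g1, g2."""
    return build_network([
        ("m1", "t1", "MIR_TF"),
        ("t1", "m1", "TF_MIR"),
        ("m1", "g1", "MIR_GENE"),
        ("m1", "g2", "MIR_GENE"),
        ("t1", "g1", "TF_GENE"),
        ("t1", "g2", "TF_GENE"),
    ])
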