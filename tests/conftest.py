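import networkx as nx
import pytest

from icdomain import SimulationParams, simulate
from icdomain.annotation import annotate_bins, assign_states, classify_elements, make_promoters
from icdomain.network import ChromatinNetwork, build_network


def _toy_graph() -> nx.Graph:
    """4-node network: b1-b2 w5, b1-b3 w2, b2-b3 w1, b3-b4 w4."""
    g = nx.Graph()
    classes = {1: "P", 2: "E", 3: "E", 4: "P"}
    for k, cls in classes.items():
        g.add_node(("chr1", k), element_class=cls, gene_ids=frozenset(), state=None)
    g.add_edge(("chr1", 1), ("chr1", 2), weight=5)
    g.add_edge(("chr1", 1), ("chr1", 3), weight=2)
    g.add_edge(("chr1", 2), ("chr1", 3), weight=1)
    g.add_edge(("chr1", 3), ("chr1", 4), weight=4)
    return g


@pytest.fixture
def toy_network() -> ChromatinNetwork:
    return ChromatinNetwork(graph=_toy_graph())


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic bundle (300 genes, planted hubs), seed 1."""
    return simulate(SimulationParams(seed=1))


def build_default_network(bundle):
    promoters = make_promoters(bundle.tss, chrom_sizes=bundle.scheme.chrom_sizes)
    elements = classify_elements(bundle.atac_peaks, promoters)
    annotation = annotate_bins(
        bundle.scheme, bundle.loops, elements, cre_set=bundle.cre_set
    )
    annotation = assign_states(
        annotation, bundle.states, bundle.super_enhancers, bundle.broad_peaks
    )
    return build_network(bundle.loops, annotation), annotation


@pytest.fixture(scope="session")
def default_network(default_bundle):
    net, annotation = build_default_network(default_bundle)
    return net, annotation
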