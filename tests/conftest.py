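import numpy as np
import pytest

from ccsconv import PhyloTree, SpeciesDesign, build_model, default_topology


@pytest.fixture(scope="session")
def jtt_model():
    return build_model("jtt-default", alpha=0.8, k=4)


@pytest.fixture(scope="session")
def topo17():
    """Default 17-taxon study tree and design."""
    return default_topology()


@pytest.fixture
def reduced_design():
    """Nine-taxon design with cluster size 2 (outgroup + 2+2+2+2)."""
    return SpeciesDesign(
        "out",
        (["p1a", "p1b"], ["p2a", "p2b"]),
        (["a1a", "a1b"], ["a2a", "a2b"]),
    )


@pytest.fixture
def five_taxon_tree():
    """Trifurcating 5-taxon tree on which every branch is identifiable."""
    return PhyloTree.from_newick("((a:0.1,b:0.2):0.08,(c:0.15,d:0.25):0.12,e:0.3);")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
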