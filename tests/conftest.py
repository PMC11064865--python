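import numpy as np
import pytest

from cubevb.matrix_gaussian import TreeSample
from cubevb.treespace import TimeTree, TreeMatrix, single_link_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


def cherry(taxa=("A", "B"), height=1.0) -> TimeTree:
    return single_link_tree(TreeMatrix(2, {(0, 1): height}, taxa=list(taxa)))


def three_taxon(h_ab=1.0, h_root=2.0, taxa=("A", "B", "C")) -> TimeTree:
    """((A,B):h_ab, C):h_root."""
    return single_link_tree(
        TreeMatrix(3, {(0, 1): h_ab, (1, 2): h_root}, taxa=list(taxa))
    )


@pytest.fixture
def abc_tree():
    return three_taxon()


def three_topology_sample(weights=(0.6, 0.3, 0.1), m=10) -> TreeSample:
    """Sample over the three rooted 3-taxon topologies with given mass.

    Topologies in order: ((A,B),C), (A,(B,C)), ((A,C),B).
    """
    taxa = ["A", "B", "C"]
    t1 = single_link_tree(TreeMatrix(3, {(0, 1): 1.0, (1, 2): 2.0}, taxa=taxa))
    t2 = single_link_tree(TreeMatrix(3, {(1, 2): 1.0, (0, 1): 2.0}, taxa=taxa))
    t3 = single_link_tree(TreeMatrix(3, {(0, 2): 1.0, (0, 1): 2.0}, taxa=taxa))
    return TreeSample([t1, t2, t3], weights=np.asarray(weights))
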