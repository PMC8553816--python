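import logging

import numpy as np
import pytest

from thermovar import trees


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    # curation deliberately warns on suspect records; keep test output clean
    logging.getLogger("thermovar").setLevel(logging.ERROR)
    yield


@pytest.fixture
def three_taxon_tree():
    """((A:1,B:1):1,C:2); — ultrametric, depth 2, cov(A,B)=1."""
    return trees.read_newick("((A:1,B:1):1,C:2);")


def brute_force_vcv(tree):
    """Independent shared-path oracle: walk root->tip paths explicitly.

    For every tip pair, the covariance is the summed length of the edges
    the two root paths share (the root-to-MRCA distance); the diagonal is
    the full root-to-tip path.  Deliberately O(n^2 * depth) and free of
    any code shared with trees.vcv_from_tree.
    """
    d = tree.dendropy_tree
    paths = {}
    for leaf in d.leaf_node_iter():
        path = []
        node = leaf
        while node.parent_node is not None:
            path.append(node)
            node = node.parent_node
        paths[leaf.taxon.label] = list(reversed(path))
    taxa = tree.tip_labels
    n = len(taxa)
    V = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            shared = 0.0
            for na, nb in zip(paths[a], paths[b]):
                if na is not nb:
                    break
                shared += na.edge.length
            V[i, j] = shared
    return V


def random_tree(rng, n_tips=None, max_tips=12):
    """Random Yule tree with random branch-length rescaling."""
    if n_tips is None:
        n_tips = int(rng.integers(2, max_tips + 1))
    t = trees.simulate_yule(n_tips, float(rng.uniform(0.5, 2.0)),
                            int(rng.integers(0, 2**31)))
    scale = float(rng.uniform(0.2, 3.0))
    for node in t.dendropy_tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length *= scale
    return trees.Phylogeny(t.dendropy_tree)
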