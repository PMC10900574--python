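import numpy as np
import pytest

from phylodisc.trees import Node, Tree


def random_tree(labels, rng, with_lengths=True):
    """Random rooted binary tree by sequential pair joining."""
    nodes = [Node(l, float(rng.uniform(0.1, 2.0)) if with_lengths else None) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(None, float(rng.uniform(0.1, 2.0)) if with_lengths else None)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i] = parent
        nodes.pop(j)
    nodes[0].length = None
    return Tree(nodes[0])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
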