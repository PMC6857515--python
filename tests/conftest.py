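import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ilskit.treecore import GeneTreeSet, Node, RootedTree, parse_newick

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_binary_tree(labels, rng, with_lengths=False):
    """Random rooted binary topology by sequential random attachment."""
    labels = list(labels)
    root = Node(labels[0])
    for label in labels[1:]:
        nodes = list(root.postorder())
        target = nodes[int(rng.integers(len(nodes)))]
        joint = Node()
        if target.parent is None:
            joint.add(target)
            joint.add(Node(label))
            root = joint
        else:
            parent = target.parent
            idx = parent.children.index(target)
            parent.children[idx] = joint
            joint.parent = parent
            target.parent = None
            joint.add(target)
            joint.add(Node(label))
    tree = RootedTree(root, validate=False)
    if with_lengths:
        for node in tree.root.postorder():
            if node is not tree.root:
                node.length = float(np.round(rng.uniform(0.01, 5.0), 4))
    return tree


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def caterpillar():
    return parse_newick("((((A,B),C),D),E);")


@pytest.fixture(scope="session")
def small_scenario():
    from ilskit.synthetic import make_scenario

    return make_scenario({"scale": 0.01}, seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_scenario):
    from ilskit.synthetic import build_bundle

    return build_bundle(small_scenario)
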