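import numpy as np
import pytest

from loopnest import (
    ModelSpec,
    assign_model_weights,
    decompose,
    triangular_lattice_hex,
)


@pytest.fixture(scope="session")
def lattice16():
    return triangular_lattice_hex(16)


@pytest.fixture(scope="session")
def gradient16_tree(lattice16):
    return decompose(assign_model_weights(lattice16, ModelSpec("gradient")))


@pytest.fixture(scope="session")
def nested16_tree(lattice16):
    return decompose(assign_model_weights(lattice16, ModelSpec("nested")))


@pytest.fixture(scope="session")
def peaks16_tree(lattice16):
    return decompose(assign_model_weights(lattice16, ModelSpec("peaks")))


def random_binary_tree(n_leaves: int, seed: int):
    """Random full binary tree by repeated random pairwise joins."""
    from loopnest import NestingNode, NestingTree

    rng = np.random.default_rng(seed)
    nodes = {}
    roots = []
    for i in range(n_leaves):
        nodes[i] = NestingNode(i, (), 1.0, 1, None, False, face=i)
        roots.append(i)
    nid = n_leaves
    h = 0.0
    while len(roots) > 1:
        i, j = sorted(rng.choice(len(roots), size=2, replace=False))
        b = roots.pop(j)
        a = roots.pop(i)
        h += 1.0
        l, r = nodes[a], nodes[b]
        nodes[nid] = NestingNode(nid, (a, b), l.area + r.area,
                                 l.degree + r.degree, h, False)
        roots.append(nid)
        nid += 1
    return NestingTree(nodes, roots[0], provenance={"builder": "random"})
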