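import numpy as np
import pytest

from arborstat.model import DENDRITE, SOMA, NeuronNode, NeuronTree, Point3
from arborstat.synthetic_data import GrowthParams, grow_neuron


def build_tree(rows, soma_id=1):
    """Build a NeuronTree from (id, parent_or_None, (x, y, z)) rows; the
    first row is the soma."""
    nodes = [
        NeuronNode(id=i, position=Point3.of(p),
                   kind=SOMA if parent is None else DENDRITE, parent_id=parent)
        for i, parent, p in rows
    ]
    return NeuronTree(nodes, soma_id=soma_id)


@pytest.fixture
def single_edge_tree():
    """soma(0,0,0) -> d1(3,4,0): one segment of length 5 (3-4-5 triangle)."""
    return build_tree([(1, None, (0, 0, 0)), (2, 1, (3, 4, 0))])


@pytest.fixture
def binary_depth2_tree():
    """Soma with two children, each with two children: 6 edges, 4 leaves.
    Edge lengths are all distinct so length sums are easy to cross-check."""
    return build_tree([
        (1, None, (0, 0, 0)),
        (2, 1, (10, 0, 0)),
        (3, 1, (0, 20, 0)),
        (4, 2, (10, 0, 5)),
        (5, 2, (14, 3, 0)),
        (6, 3, (0, 20, 7)),
        (7, 3, (0, 26, 0)),
    ])


@pytest.fixture
def chain10_tree():
    """Unbranched radial chain of 10 dendrite nodes along +x, 10 µm apart."""
    rows = [(1, None, (0.0, 0.0, 0.0))]
    rows += [(i, i - 1, (10.0 * (i - 1), 0.0, 0.0)) for i in range(2, 12)]
    return build_tree(rows)


def random_tree(seed, **overrides):
    """A small random neuron for property tests."""
    params = GrowthParams(**{"n_stems": 3, "max_order": 3, **overrides})
    return grow_neuron(params, seed=seed)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
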