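import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from canalkit.boolean_core import BooleanNetwork, node_from_outputs


@pytest.fixture
def or2():
    return node_from_outputs(2, "0111", name="OR2")


@pytest.fixture
def and2():
    return node_from_outputs(2, "0001", name="AND2")


@pytest.fixture
def xor2():
    return node_from_outputs(2, "0110", name="XOR2")


@pytest.fixture
def or3():
    return node_from_outputs(3, "01111111", name="OR3")


@pytest.fixture
def maj3():
    """Majority-of-3: (x1&x2)|(x2&x3)|(x1&x3)."""
    return node_from_outputs(3, "00010111", name="MAJ3")


@pytest.fixture
def mutual_activation():
    """A' = A|B, B' = A&B: fixed points 00, 10, 11."""
    return BooleanNetwork(nodes=(
        node_from_outputs(2, "0111", name="A", input_labels=("A", "B")),
        node_from_outputs(2, "0001", name="B", input_labels=("A", "B")),
    ))


@pytest.fixture
def copy_loop():
    """A' = B, B' = A (mutual copying): fixed points 00/11 plus a 2-cycle."""
    return BooleanNetwork(nodes=(
        node_from_outputs(1, "01", name="A", input_labels=("B",)),
        node_from_outputs(1, "01", name="B", input_labels=("A",)),
    ))


@pytest.fixture
def repressilator3():
    """Odd negative 3-loop: each node is the negation of its predecessor."""
    return BooleanNetwork(nodes=(
        node_from_outputs(1, "10", name="A", input_labels=("C",)),
        node_from_outputs(1, "10", name="B", input_labels=("A",)),
        node_from_outputs(1, "10", name="C", input_labels=("B",)),
    ))


@pytest.fixture
def toy_networks(mutual_activation, copy_loop, repressilator3):
    """Fixture networks (<=4 nodes) used for exhaustive fidelity checks."""
    mixed = BooleanNetwork(nodes=(
        node_from_outputs(3, "01111111", name="A", input_labels=("A", "B", "C")),
        node_from_outputs(2, "0110", name="B", input_labels=("A", "C")),
        node_from_outputs(0, "1", name="C", input_labels=()),
        node_from_outputs(2, "0010", name="D", input_labels=("B", "D")),
    ))
    return [mutual_activation, copy_loop, repressilator3, mixed]
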