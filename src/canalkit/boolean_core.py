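"""Boolean automata and networks as explicit lookup tables.

A :class:`BooleanNode` is a ``k``-input automaton stored as the output
column over all ``2**k`` input configurations.  Row ``i`` of the lookup
table (LUT) corresponds to the input configuration obtained by writing
``i`` in binary with **input 0 as the most significant digit**, so for
``k=2`` the rows are ``00, 01, 10, 11``.  Input indices are 0-based
throughout the package.

The module also provides the ensemble primitives used by the null-model
analysis: random functions with a target bias, and exact output-column
shuffles that preserve in-degree and bias.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BooleanNode",
    "BooleanNetwork",
    "MonotonicityReport",
    "node_from_outputs",
    "bias",
    "is_essential",
    "monotonicity",
    "random_node",
    "shuffle_outputs",
]

BOOLEAN_ALPHABET: tuple[str, str] = ("0", "1")


@dataclasses.dataclass(frozen=True)
class BooleanNode:
    """A single automaton: ``k`` ordered inputs and a full output column.

    Parameters
    ----------
    name:
        Label of the automaton (the regulated variable).
    k:
        In-degree, i.e. number of inputs.
    input_labels:
        Ordered labels of the inputs; in a network these name the source
        nodes and define the wiring.
    outputs:
        Output symbol for every input configuration, in canonical row
        order (row index = integer value of the configuration, input 0
        as most significant digit).  Length must be ``2**k``.
    """

    name: str
    k: int
    input_labels: tuple[str, ...]
    outputs: tuple[str, ...]
    alphabet: tuple[str, ...] = BOOLEAN_ALPHABET

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("in-degree k must be >= 0")
        expected = len(self.alphabet) ** self.k
        if len(self.outputs) != expected:
            raise ValueError(
                f"node {self.name!r}: expected {expected} output rows for "
                f"k={self.k}, got {len(self.outputs)}"
            )
        if len(self.input_labels) != self.k:
            raise ValueError(
                f"node {self.name!r}: {self.k} inputs but "
                f"{len(self.input_labels)} input labels"
            )
        bad = set(self.outputs) - set(self.alphabet)
        if bad:
            raise ValueError(f"node {self.name!r}: outputs {sorted(bad)} not in alphabet")

    # -- configuration indexing -------------------------------------------
    def config(self, row: int) -> str:
        """Input configuration string of LUT row ``row``."""
        if not 0 <= row < len(self.outputs):
            raise IndexError(f"row {row} out of range for k={self.k}")
        if len(self.alphabet) == 2:
            return format(row, f"0{self.k}b") if self.k else ""
        digits = []
        base = len(self.alphabet)
        for _ in range(self.k):
            digits.append(str(row % base))
            row //= base
        return "".join(reversed(digits))

    def row_of(self, config: str) -> int:
        """LUT row index of an input configuration string."""
        if len(config) != self.k:
            raise ValueError(f"configuration {config!r} has length != k={self.k}")
        base = len(self.alphabet)
        return int(config, base) if self.k else 0

    def configs(self) -> Iterable[str]:
        """All input configurations, in canonical row order."""
        return (self.config(r) for r in range(len(self.outputs)))

    def output_of(self, config: str) -> str:
        """Output symbol for an input configuration."""
        return self.outputs[self.row_of(config)]

    def evaluate(self, input_states: Sequence[str]) -> str:
        """Output for input states given in ``input_labels`` order."""
        return self.output_of("".join(input_states))


@dataclasses.dataclass(frozen=True)
class BooleanNetwork:
    """A collection of wired automata.

    Each node's ``input_labels`` must name nodes of the network; the
    label order defines the wiring and matches the LUT column order.
    """

    nodes: tuple[BooleanNode, ...]

    def __post_init__(self) -> None:
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate node names in network")
        known = set(names)
        for node in self.nodes:
            missing = set(node.input_labels) - known
            if missing:
                raise ValueError(
                    f"node {node.name!r} wired to unknown sources {sorted(missing)}"
                )

    def __iter__(self):
        return iter(self.nodes)

    def __len__(self) -> int:
        return len(self.nodes)

    def __getitem__(self, name: str) -> BooleanNode:
        for node in self.nodes:
            if node.name == name:
                return node
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes)


@dataclasses.dataclass(frozen=True)
class MonotonicityReport:
    """Per-input regulatory roles of a Boolean automaton.

    ``roles[i]`` is one of ``"activator"``, ``"inhibitor"``, ``"dual"``
    or ``"inessential"``.  A function is unate (monotone) when every
    essential input is unambiguously an activator or an inhibitor.
    """

    roles: tuple[str, ...]
    is_unate: bool


def node_from_outputs(
    k: int,
    outputs: Sequence[str | int],
    name: str = "f",
    input_labels: Sequence[str] | None = None,
) -> BooleanNode:
    """Build a Boolean node from its output column.

    ``outputs`` may hold ints or strings; it must have length ``2**k``
    and is read in canonical row order (``00, 01, 10, 11`` for k=2).
    """
    out = tuple(str(v) for v in outputs)
    if len(out) != 2**k:
        raise ValueError(f"expected {2**k} outputs for k={k}, got {len(out)}")
    labels = tuple(input_labels) if input_labels is not None else tuple(
        f"x{i + 1}" for i in range(k)
    )
    return BooleanNode(name=name, k=k, input_labels=labels, outputs=out)


def bias(node: BooleanNode) -> float:
    """Bias rho: fraction of LUT rows with output 1."""
    return node.outputs.count("1") / len(node.outputs)


def _flip_row(node: BooleanNode, row: int, i: int) -> int:
    """Row index with input ``i`` flipped (Boolean alphabet only)."""
    return row ^ (1 << (node.k - 1 - i))


def is_essential(node: BooleanNode, i: int) -> bool:
    """Whether input ``i`` (0-based) ever changes the output when flipped."""
    if not 0 <= i < node.k:
        raise IndexError(f"input index {i} out of range for k={node.k}")
    return any(
        node.outputs[row] != node.outputs[_flip_row(node, row, i)]
        for row in range(len(node.outputs))
    )


def monotonicity(node: BooleanNode) -> MonotonicityReport:
    """Classify each input as activator, inhibitor, dual or inessential.

    Input ``i`` is an activator if flipping it 0->1 (others held fixed)
    never decreases the output and sometimes increases it; an inhibitor
    in the mirror case; dual if both strict directions occur.
    """
    roles = []
    for i in range(node.k):
        up = down = False
        for row in range(len(node.outputs)):
            if (row >> (node.k - 1 - i)) & 1:
                continue  # visit each 0->1 flip once, from the 0 side
            lo, hi = node.outputs[row], node.outputs[_flip_row(node, row, i)]
            if lo == "0" and hi == "1":
                up = True
            elif lo == "1" and hi == "0":
                down = True
        if up and down:
            roles.append("dual")
        elif up:
            roles.append("activator")
        elif down:
            roles.append("inhibitor")
        else:
            roles.append("inessential")
    is_unate = "dual" not in roles
    return MonotonicityReport(roles=tuple(roles), is_unate=is_unate)


def random_node(
    k: int,
    rho: float,
    seed: int | np.random.Generator,
    name: str = "f",
) -> BooleanNode:
    """Random k-input function with outputs drawn i.i.d. Bernoulli(rho)."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"bias rho must lie in [0, 1], got {rho}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    draws = rng.random(2**k) < rho
    return node_from_outputs(k, ["1" if d else "0" for d in draws], name=name)


def shuffle_outputs(
    node: BooleanNode,
    n_shuffles: int = 12,
    seed: int | np.random.Generator = 0,
) -> list[BooleanNode]:
    """Degree-and-bias matched null rules for a node.

    Each returned node's output column is an independent uniform random
    permutation of the original column, so in-degree and bias are
    preserved exactly (the output multiset is unchanged).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = np.array(node.outputs)
    shuffles = []
    for j in range(n_shuffles):
        perm = rng.permutation(len(out))
        shuffles.append(
            BooleanNode(
                name=f"{node.name}~shuffle{j}",
                k=node.k,
                input_labels=node.input_labels,
                outputs=tuple(out[perm]),
                alphabet=node.alphabet,
            )
        )
    return shuffles


def all_nodes(k: int) -> Iterable[BooleanNode]:
    """Every Boolean function of ``k`` inputs (2**2**k nodes); small k only."""
    for bits in itertools.product("01", repeat=2**k):
        yield node_from_outputs(k, bits)
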