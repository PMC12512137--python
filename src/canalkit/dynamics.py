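"""Synchronous Boolean network dynamics.

Trajectories, exhaustive attractor/basin enumeration over the full
state-transition graph, pinned-node (clamped) simulation, and
perturbation-response measures: per-node sensitivity to single input
flips and the one-step Derrida response of a whole network.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .boolean_core import BooleanNetwork, BooleanNode

__all__ = [
    "NetworkState",
    "Attractor",
    "AttractorSet",
    "step",
    "trajectory",
    "attractors",
    "node_sensitivity",
    "derrida_step",
]

NetworkState = dict[str, str]

EXHAUSTIVE_NODE_LIMIT = 20
EXHAUSTIVE_TRANSITION_LIMIT = 2**16


@dataclasses.dataclass(frozen=True)
class Attractor:
    """An ordered state cycle (length 1 = fixed point) with its basin size."""

    states: tuple[str, ...]
    basin_size: int

    @property
    def period(self) -> int:
        return len(self.states)


@dataclasses.dataclass(frozen=True)
class AttractorSet:
    """All attractors of a network; basins partition the state space."""

    attractors: tuple[Attractor, ...]
    n_states: int

    def __iter__(self):
        return iter(self.attractors)

    def __len__(self) -> int:
        return len(self.attractors)


def _pack(network: BooleanNetwork, state: NetworkState) -> str:
    return "".join(state[name] for name in network.names)


def _unpack(network: BooleanNetwork, packed: str) -> NetworkState:
    return dict(zip(network.names, packed))


def step(
    network: BooleanNetwork,
    state: NetworkState,
    pinned: dict[str, str] | None = None,
) -> NetworkState:
    """One synchronous update; pinned nodes are clamped *after* the update.

    Clamping after (rather than before) the step means a pinned node's
    current value is still visible to its targets during this update;
    from the next step on the clamp has fully propagated.
    """
    missing = set(n.name for n in network) - set(state)
    if missing:
        raise ValueError(f"state missing nodes {sorted(missing)}")
    if pinned:
        unknown = set(pinned) - set(network.names)
        if unknown:
            raise ValueError(f"unknown pinned nodes {sorted(unknown)}")
    nxt = {
        node.name: node.evaluate([state[src] for src in node.input_labels])
        for node in network
    }
    if pinned:
        nxt.update(pinned)
    return nxt


def trajectory(
    network: BooleanNetwork,
    state: NetworkState,
    n_steps: int,
    pinned: dict[str, str] | None = None,
) -> list[NetworkState]:
    """States visited over ``n_steps`` synchronous updates (inclusive of start)."""
    states = [dict(state)]
    for _ in range(n_steps):
        states.append(step(network, states[-1], pinned))
    return states


def attractors(network: BooleanNetwork, node_limit: int = EXHAUSTIVE_NODE_LIMIT) -> AttractorSet:
    """Exhaustive attractors and exact basin sizes of the synchronous dynamics.

    Traverses the full state-transition graph (``2**n`` states); guarded
    by ``node_limit`` — for larger networks sample trajectories with
    :func:`trajectory` instead.
    """
    n = len(network)
    if n > node_limit:
        raise ValueError(
            f"exhaustive enumeration limited to {node_limit} nodes "
            f"(network has {n}); use trajectory sampling instead"
        )
    successor: dict[str, str] = {}
    for i in range(2**n):
        packed = format(i, f"0{n}b") if n else ""
        successor[packed] = _pack(
            network, step(network, _unpack(network, packed))
        )

    attractor_of: dict[str, int] = {}
    cycles: list[tuple[str, ...]] = []
    for start in successor:
        if start in attractor_of:
            continue
        path = []
        seen_at = {}
        s = start
        while s not in attractor_of and s not in seen_at:
            seen_at[s] = len(path)
            path.append(s)
            s = successor[s]
        if s in attractor_of:
            label = attractor_of[s]
        else:  # new cycle discovered on this path
            label = len(cycles)
            cycle = tuple(path[seen_at[s] :])
            # canonical rotation: start the cycle at its smallest state
            pivot = cycle.index(min(cycle))
            cycles.append(cycle[pivot:] + cycle[:pivot])
        for s2 in path:
            attractor_of[s2] = label

    basin = [0] * len(cycles)
    for label in attractor_of.values():
        basin[label] += 1
    found = tuple(
        Attractor(states=cycles[i], basin_size=basin[i]) for i in range(len(cycles))
    )
    return AttractorSet(attractors=found, n_states=2**n)


def node_sensitivity(node: BooleanNode) -> float:
    """Fraction of (row, input) pairs where a single bit-flip changes the output."""
    if node.k == 0:
        return 0.0
    changes = 0
    for row in range(len(node.outputs)):
        for i in range(node.k):
            if node.outputs[row] != node.outputs[row ^ (1 << (node.k - 1 - i))]:
                changes += 1
    return changes / (len(node.outputs) * node.k)


def derrida_step(
    network: BooleanNetwork,
    n_samples: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Expected normalized Hamming distance one step after a 1-bit perturbation.

    Exhaustive over all (state, flipped bit) pairs when that count stays
    below ``2**16``; otherwise Monte Carlo with the given seed.
    """
    n = len(network)
    if n == 0:
        raise ValueError("empty network")
    names = network.names

    def distance_after(packed: str, i: int) -> int:
        perturbed = packed[:i] + ("1" if packed[i] == "0" else "0") + packed[i + 1 :]
        a = _pack(network, step(network, _unpack(network, packed)))
        b = _pack(network, step(network, _unpack(network, perturbed)))
        return sum(x != y for x, y in zip(a, b))

    total_pairs = (2**n) * n
    if total_pairs <= EXHAUSTIVE_TRANSITION_LIMIT:
        total = sum(
            distance_after(format(s, f"0{n}b"), i)
            for s in range(2**n)
            for i in range(n)
        )
        return total / (total_pairs * n)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    total = 0
    for _ in range(n_samples):
        packed = "".join(rng.choice(["0", "1"], size=n))
        total += distance_after(packed, int(rng.integers(n)))
    return total / (n_samples * n)
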