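"""Macro-level causal maps: the effective graph and the dynamics canalizing map.

The **effective graph** weights each regulatory edge ``j -> i`` by its
effectiveness ``e_ij = 1 - r_ij``, where ``r_ij`` is the mean, over the
LUT rows of node ``i``, of the probability that input ``j`` is a
wildcard in the schema selected to redescribe that row (same selection
rule as input redundancy, so the incoming effectiveness of a node sums
to its effective connectivity ``k_e``).  Inessential inputs get
``e_ij = 0``.

The **dynamics canalizing map** (DCM) is an exact threshold-network
representation: state units (*s-units*, one per node-state literal) feed
transition units (*t-units*, one per two-symbol schema per node per
output) which in turn drive the target node's state.  A t-unit fires
when all its mandatory literals hold and, for each permutable group,
at least as many group inputs carry each required literal as the
group's symbol multiset demands.  Firing conditions are exactly the
schema's expansion, so threshold evaluation over the DCM reproduces the
network's synchronous dynamics.
"""

from __future__ import annotations

import dataclasses

import networkx as nx

from .boolean_core import BooleanNetwork, BooleanNode
from .measures import _row_wildcard_stats, two_symbol_schemata
from .prime_implicants import WILDCARD
from .two_symbol import TwoSymbolSchema

__all__ = ["effective_graph", "node_edge_effectiveness", "DCM", "TUnit", "dcm", "dcm_step"]


def node_edge_effectiveness(node: BooleanNode, bound: str = "min") -> dict[str, float]:
    """Effectiveness of each input edge of one node, keyed by input label."""
    r = [0.0] * node.k
    n_rows = len(node.outputs)
    for _, pairs in _row_wildcard_stats(node, bound):
        for schema, weight in pairs:
            for j, sym in enumerate(schema):
                if sym == WILDCARD:
                    r[j] += weight / n_rows
    return {label: 1.0 - r[j] for j, label in enumerate(node.input_labels)}


def effective_graph(network: BooleanNetwork, bound: str = "min") -> nx.DiGraph:
    """Directed graph with edge attribute ``effectiveness`` in [0, 1].

    Edges with zero effectiveness (inessential inputs) are retained so
    the structural wiring stays visible; filter on the attribute to
    obtain the purely effective topology.
    """
    g = nx.DiGraph()
    g.add_nodes_from(network.names)
    for node in network:
        for label, e in node_edge_effectiveness(node, bound).items():
            g.add_edge(label, node.name, effectiveness=e)
    return g


@dataclasses.dataclass(frozen=True)
class TUnit:
    """A transition unit of the DCM: the threshold form of one schema.

    ``literals`` are mandatory (source label, state) pairs from the
    ungrouped non-# positions.  Each entry of ``group_requirements``
    constrains one permutable group: over the listed source labels, at
    least ``count`` inputs must carry ``state``, for every (state,
    count) requirement of the group's symbol multiset.  ``tau`` is the
    unit's threshold: the total number of required literals.
    """

    target: str
    output: str
    schema: TwoSymbolSchema
    literals: tuple[tuple[str, str], ...]
    group_requirements: tuple[tuple[tuple[str, ...], tuple[tuple[str, int], ...]], ...]
    tau: int

    def fires(self, input_states: dict[str, str]) -> bool:
        if any(input_states[src] != state for src, state in self.literals):
            return False
        for sources, requirements in self.group_requirements:
            for state, count in requirements:
                if sum(input_states[s] == state for s in sources) < count:
                    return False
        return True


@dataclasses.dataclass(frozen=True)
class DCM:
    """Dynamics canalizing map: all t-units of a network."""

    t_units: tuple[TUnit, ...]

    def for_node(self, name: str) -> tuple[TUnit, ...]:
        return tuple(t for t in self.t_units if t.target == name)

    def to_graph(self) -> nx.DiGraph:
        """Bipartite s-unit / t-unit graph (DOT/GraphML-exportable)."""
        g = nx.DiGraph()
        for idx, t in enumerate(self.t_units):
            t_id = f"t{idx}:{t.target}={t.output}"
            g.add_node(t_id, kind="t-unit", tau=t.tau, schema=str(t.schema))
            target_s = f"{t.target}={t.output}"
            g.add_node(target_s, kind="s-unit")
            g.add_edge(t_id, target_s)
            for src, state in t.literals:
                s_id = f"{src}={state}"
                g.add_node(s_id, kind="s-unit")
                g.add_edge(s_id, t_id, mode="literal")
            for gi, (sources, requirements) in enumerate(t.group_requirements):
                for state, count in requirements:
                    for src in sources:
                        s_id = f"{src}={state}"
                        g.add_node(s_id, kind="s-unit")
                        g.add_edge(s_id, t_id, mode=f"group{gi}:>={count}")
        return g


def _t_unit(node: BooleanNode, schema: TwoSymbolSchema) -> TUnit:
    grouped = {p for g in schema.groups for p in g}
    literals = tuple(
        (node.input_labels[p], sym)
        for p, sym in enumerate(schema.base)
        if sym != WILDCARD and p not in grouped
    )
    group_reqs = []
    for g in schema.groups:
        sources = tuple(node.input_labels[p] for p in g)
        symbols = [schema.base[p] for p in g]
        requirements = tuple(
            (state, symbols.count(state))
            for state in sorted(set(symbols))
            if state != WILDCARD
        )
        group_reqs.append((sources, requirements))
    tau = sum(1 for sym in schema.base if sym != WILDCARD)
    return TUnit(
        target=node.name,
        output=schema.output,
        schema=schema,
        literals=literals,
        group_requirements=tuple(group_reqs),
        tau=tau,
    )


def dcm(network: BooleanNetwork) -> DCM:
    """Build the dynamics canalizing map of a network."""
    units = []
    for node in network:
        for ts in two_symbol_schemata(node).values():
            for schema in ts:
                units.append(_t_unit(node, schema))
    return DCM(t_units=tuple(units))


def dcm_step(network: BooleanNetwork, map_: DCM, state: dict[str, str]) -> dict[str, str]:
    """One synchronous step evaluated through DCM t-units only.

    For every node exactly one output value's t-units fire (schemata of
    each output tile the LUT), so the update is well defined; used to
    cross-check DCM fidelity against direct LUT evaluation.
    """
    nxt = {}
    for node in network:
        fired = {
            t.output
            for t in map_.for_node(node.name)
            if t.fires({src: state[src] for src in node.input_labels})
        }
        if len(fired) != 1:
            raise RuntimeError(
                f"DCM inconsistency at node {node.name!r}: outputs {sorted(fired)}"
            )
        nxt[node.name] = fired.pop()
    return nxt
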