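"""Canalization measures of a Boolean automaton.

Micro-level canalization is quantified per node from its schema
redescription:

* **input redundancy** ``k_r`` — mean, over all LUT rows, of the number
  of wildcards in the one-symbol schema selected to redescribe that
  row.  When several prime implicants cover a row, a configurable bound
  picks among them (fewest wildcards by default; most, or the midpoint
  of the two, as alternatives).
* **effective connectivity** ``k_e = k - k_r`` — how many inputs the
  function effectively depends on, once redundancy is removed.
* **input symmetry** ``k_s`` — the average size of the permutation
  group an input participates in across the function's two-symbol
  schemata (both output values).  An input outside every group
  contributes 1 (it "permutes" only with itself); group members
  contribute the group size.  Per-input aggregation is by default the
  mean weighted by the number of LUT rows each schema covers;
  unweighted mean and maximum are available.  ``k_s`` is the mean over
  inputs and ``k_s / k`` its normalized form in ``[0, 1]``.

Two classifier flags summarize the kinds of symmetry present: whether
any group permutes an essential literal with a wildcard, and whether
any group permutes a 0 with a 1 (characteristic of non-monotone,
XOR-like logic).
"""

from __future__ import annotations

import dataclasses
from fractions import Fraction
from statistics import mean

from .boolean_core import BooleanNode
from .prime_implicants import WILDCARD, covers, expand_schema, one_symbol_schemata
from .two_symbol import TwoSymbolSchema, compress_two_symbol

__all__ = [
    "CanalizationSummary",
    "input_redundancy",
    "effective_connectivity",
    "input_symmetry",
    "normalized_input_symmetry",
    "schema_threshold",
    "has_literal_wildcard_group",
    "has_zero_one_group",
    "two_symbol_schemata",
    "summarize_node",
]


@dataclasses.dataclass(frozen=True)
class CanalizationSummary:
    """Per-node canalization measures and symmetry classifier flags."""

    name: str
    k: int
    k_r: float
    k_e: float
    k_s: float
    ks_over_k: float
    has_literal_wildcard_group: bool
    has_zero_one_group: bool
    is_unate: bool


def _schemata_by_output(node: BooleanNode) -> dict[str, frozenset[str]]:
    return {v: one_symbol_schemata(node, v) for v in node.alphabet}


def two_symbol_schemata(node: BooleanNode) -> dict[str, tuple[TwoSymbolSchema, ...]]:
    """Two-symbol schemata of a node for every output value that occurs."""
    result = {}
    for v, pis in _schemata_by_output(node).items():
        if pis:
            result[v] = compress_two_symbol(pis, output=v)
    return result


def _row_wildcard_stats(node: BooleanNode, bound: str):
    """Per LUT row: (selected wildcard count, achiever schemata).

    ``bound`` selects among the prime implicants covering a row by their
    wildcard count: ``"min"`` (fewest), ``"max"`` (most) or ``"mean"``
    (midpoint of the two, achievers from both extremes).  The achiever
    list pairs each schema with its weight in per-input attribution;
    weights sum to 1 per row.
    """
    if bound not in ("min", "max", "mean"):
        raise ValueError(f"unknown bound {bound!r}")
    pis = _schemata_by_output(node)
    for row, out in enumerate(node.outputs):
        config = node.config(row)
        covering = [s for s in pis[out] if covers(s, config)]
        counts = {s: s.count(WILDCARD) for s in covering}
        lo, hi = min(counts.values()), max(counts.values())
        if bound == "min":
            chosen = [s for s in covering if counts[s] == lo]
            value = float(lo)
            pairs = [(s, 1.0 / len(chosen)) for s in chosen]
        elif bound == "max":
            chosen = [s for s in covering if counts[s] == hi]
            value = float(hi)
            pairs = [(s, 1.0 / len(chosen)) for s in chosen]
        else:
            los = [s for s in covering if counts[s] == lo]
            his = [s for s in covering if counts[s] == hi]
            value = (lo + hi) / 2
            pairs = [(s, 0.5 / len(los)) for s in los] + [
                (s, 0.5 / len(his)) for s in his
            ]
        yield value, pairs


def input_redundancy(node: BooleanNode, bound: str = "min") -> float:
    """Mean wildcard count of the per-row selected schema redescription."""
    if node.k == 0:
        return 0.0
    return mean(v for v, _ in _row_wildcard_stats(node, bound))


def effective_connectivity(node: BooleanNode, bound: str = "min") -> float:
    """Effective in-degree ``k_e = k - k_r``."""
    return node.k - input_redundancy(node, bound)


def _covered_rows(schema: TwoSymbolSchema) -> int:
    """Number of distinct LUT rows covered by a two-symbol schema."""
    configs: set[str] = set()
    for one_symbol in schema.expand():
        configs |= expand_schema(one_symbol)
    return len(configs)


def input_symmetry(
    node: BooleanNode,
    aggregation: str = "mean",
    weighting: str = "entry-weighted",
    exact: bool = False,
) -> float | Fraction:
    """Input symmetry ``k_s``: average permutation-group size per input.

    For input ``i`` and two-symbol schema ``T``, ``s_i(T)`` is the size
    of the group of ``T`` containing ``i`` (1 if ungrouped).  Schemata
    of both output values contribute.  With ``exact=True`` the value is
    returned as a :class:`fractions.Fraction` (the default aggregation
    is rational), which the null-model comparison uses for exact
    equality classification.
    """
    if aggregation not in ("mean", "max"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if weighting not in ("entry-weighted", "unweighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if node.k == 0:
        return Fraction(0) if exact else 0.0
    schemata = [t for ts in two_symbol_schemata(node).values() for t in ts]
    weights = [
        _covered_rows(t) if weighting == "entry-weighted" else 1 for t in schemata
    ]
    per_input = []
    for i in range(node.k):
        sizes = []
        for t in schemata:
            size = 1
            for g in t.groups:
                if i in g:
                    size = len(g)
                    break
            sizes.append(size)
        if aggregation == "max":
            per_input.append(Fraction(max(sizes)))
        else:
            per_input.append(
                Fraction(sum(w * s for w, s in zip(weights, sizes)), sum(weights))
            )
    ks = sum(per_input, Fraction(0)) / node.k
    return ks if exact else float(ks)


def normalized_input_symmetry(node: BooleanNode, exact: bool = False, **kwargs) -> float | Fraction:
    """``k_s / k``, the normalized input symmetry in ``[0, 1]``."""
    ks = input_symmetry(node, exact=True, **kwargs)
    value = ks / node.k
    return value if exact else float(value)


def schema_threshold(schema: TwoSymbolSchema) -> int:
    """Activation threshold of an output-1 schema: ON literals in the base.

    Group-invariant, since permutations rearrange but never change the
    symbol multiset.  A threshold-τ function's schema has exactly τ
    ones, e.g. a 3-input disjunction gives 1 and a 3-input majority
    gives 2.
    """
    if schema.output not in (None, "1"):
        raise ValueError("threshold is defined for activating (output-1) schemata")
    return schema.base.count("1")


def _any_group(node: BooleanNode, predicate) -> bool:
    for ts in two_symbol_schemata(node).values():
        for t in ts:
            for g in t.groups:
                if predicate(set(t.base[p] for p in g)):
                    return True
    return False


def has_literal_wildcard_group(node: BooleanNode) -> bool:
    """Whether any group permutes an essential literal (0 or 1) with a wildcard."""
    return _any_group(
        node, lambda syms: WILDCARD in syms and bool(syms & {"0", "1"})
    )


def has_zero_one_group(node: BooleanNode) -> bool:
    """Whether any group permutes a 0 with a 1 (XOR-like symmetry)."""
    return _any_group(node, lambda syms: {"0", "1"} <= syms)


def summarize_node(node: BooleanNode, kr_bound: str = "min", **ks_kwargs) -> CanalizationSummary:
    """All per-node canalization measures in one record."""
    from .boolean_core import monotonicity

    k_r = input_redundancy(node, kr_bound)
    ks = float(input_symmetry(node, **ks_kwargs))
    return CanalizationSummary(
        name=node.name,
        k=node.k,
        k_r=k_r,
        k_e=node.k - k_r,
        k_s=ks,
        ks_over_k=ks / node.k if node.k else float("nan"),
        has_literal_wildcard_group=has_literal_wildcard_group(node),
        has_zero_one_group=has_zero_one_group(node),
        is_unate=monotonicity(node).is_unate,
    )
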