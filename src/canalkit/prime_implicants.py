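"""One-symbol schemata: all prime implicants of a function and its negation.

A one-symbol schema is a string over ``{0, 1, #}`` of length ``k`` where
``#`` means "don't care"; it compresses the set of input configurations
obtained by substituting every combination of literals for the
wildcards.  A prime implicant is a schema that covers only rows of one
output value and cannot be widened (no literal can be replaced by ``#``
without covering a row of another output).

We enumerate ALL prime implicants by Quine-McCluskey pairwise merging,
with no cover minimization: the two-symbol compression stage needs the
complete set so that symmetric siblings (e.g. both ``1#`` and ``#1`` for
the 2-input OR) are present.
"""

from __future__ import annotations

import itertools
from typing import Iterable

from .boolean_core import BooleanNode

__all__ = ["one_symbol_schemata", "covers", "expand_schema", "schema_sort_key"]

WILDCARD = "#"

# deterministic serialization order: 0 < 1 < ... < '#'
def schema_sort_key(schema: str) -> tuple[int, ...]:
    """Sort key placing literal symbols in natural order and ``#`` last."""
    return tuple(0x10FFFF if c == WILDCARD else ord(c) for c in schema)


def covers(schema: str, config: str) -> bool:
    """True iff every non-# position of ``schema`` matches ``config``."""
    if len(schema) != len(config):
        raise ValueError(
            f"schema {schema!r} and configuration {config!r} differ in length"
        )
    return all(s == WILDCARD or s == c for s, c in zip(schema, config))


def expand_schema(schema: str, alphabet: Iterable[str] = ("0", "1")) -> frozenset[str]:
    """All input configurations covered by a schema."""
    alphabet = tuple(alphabet)
    positions = [i for i, s in enumerate(schema) if s == WILDCARD]
    configs = set()
    for fill in itertools.product(alphabet, repeat=len(positions)):
        chars = list(schema)
        for p, sym in zip(positions, fill):
            chars[p] = sym
        configs.add("".join(chars))
    return frozenset(configs)


def _merge(a: str, b: str) -> str | None:
    """Merge two schemata differing in exactly one literal position."""
    diff = -1
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            if x == WILDCARD or y == WILDCARD or diff >= 0:
                return None
            diff = i
    if diff < 0:
        return None
    return a[:diff] + WILDCARD + a[diff + 1 :]


def one_symbol_schemata(node: BooleanNode, output: str | int) -> frozenset[str]:
    """All prime implicants of ``node`` for the given output value.

    Returns the empty set when the output value never occurs.  Constant
    functions yield the single all-# schema for the constant output.
    """
    if node.alphabet != ("0", "1"):
        raise ValueError("prime-implicant merging is defined for Boolean nodes")
    output = str(output)
    current = {
        node.config(row)
        for row, out in enumerate(node.outputs)
        if out == output
    }
    primes: set[str] = set()
    while current:
        merged: set[str] = set()
        nxt: set[str] = set()
        items = sorted(current)
        for i, a in enumerate(items):
            for b in items[i + 1 :]:
                m = _merge(a, b)
                if m is not None:
                    nxt.add(m)
                    merged.add(a)
                    merged.add(b)
        primes |= current - merged
        current = nxt
    return frozenset(primes)
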