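"""Two-symbol schemata: exact compression of permutation symmetries.

A two-symbol schema annotates a one-symbol schema (the *base*) with
disjoint *position groups*.  Within a group, the symbols occupying the
group's positions may appear in any arrangement of their multiset; the
expansion of the schema is the set of one-symbol schemata reachable by
independently rearranging every group.  For example, base ``1#`` with
group ``{0, 1}`` expands to ``{1#, #1}``: the 2-input OR's output-1
implicants collapse to a single schema in which the two inputs are
interchangeable.

Groups must be *faithful*: a group whose positions all carry the same
symbol admits only permutations that fix every string, conveys no
information, and is excluded.  Operationally a group must contain at
least two distinct symbols.

:func:`compress_two_symbol` finds, for a set ``S`` of same-output
one-symbol schemata, every *maximal* valid schema — one whose expansion
lies inside ``S`` and is not strictly contained in the expansion of
another valid schema.  The union of the returned expansions is exactly
``S``.  The search is exact: it enumerates candidate group structures
per base string by a canonical set-partition DFS, pruning any partial
structure whose orbit already escapes ``S`` (validity is monotone:
shrinking a group structure shrinks the orbit).  Because a permutation
of symbols preserves the symbol multiset, the search space is first
partitioned by multiset, which keeps orbit membership checks small.

:func:`brute_force_two_symbol` is an independent oracle with the same
contract, implemented by blunt enumeration of all set partitions and
position-permutation orbits; it carries tractability guards and exists
to cross-validate the pruned search.

The machinery works over arbitrary symbol alphabets (e.g. ``{0,1,2,#}``
for multi-valued logic); nothing below assumes Boolean symbols.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Sequence

from .prime_implicants import schema_sort_key

__all__ = [
    "TwoSymbolSchema",
    "expand_two_symbol",
    "compress_two_symbol",
    "brute_force_two_symbol",
    "minimal_cover",
]


@dataclasses.dataclass(frozen=True)
class TwoSymbolSchema:
    """A base one-symbol schema plus disjoint permutable position groups.

    ``groups`` holds sorted tuples of 0-based positions; each group's
    symbols (read off the base) may permute freely.  ``output`` is the
    output value the schema maps to, when known.
    """

    base: str
    groups: tuple[tuple[int, ...], ...] = ()
    output: str | None = None

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for g in self.groups:
            if len(g) < 2:
                raise ValueError(f"group {g} has fewer than 2 positions")
            if any(not 0 <= p < len(self.base) for p in g):
                raise ValueError(f"group {g} positions out of range")
            if seen & set(g):
                raise ValueError("groups overlap")
            seen |= set(g)
            if len({self.base[p] for p in g}) < 2:
                raise ValueError(
                    f"group {g} is not faithful (all symbols identical)"
                )

    def expand(self) -> frozenset[str]:
        return expand_two_symbol(self)

    def group_symbols(self, group: tuple[int, ...]) -> tuple[str, ...]:
        """The symbol multiset (sorted) occupying a group's positions."""
        return tuple(sorted((self.base[p] for p in group), key=schema_sort_key))

    def __str__(self) -> str:
        markers = "°^*'·"  # degree, caret, ... one marker per group
        chars = []
        for i, c in enumerate(self.base):
            chars.append(c)
            for gi, g in enumerate(self.groups):
                if i in g:
                    chars.append(markers[gi % len(markers)])
        s = "".join(chars)
        return s if self.output is None else f"{s}↦{self.output}"


def expand_two_symbol(schema: TwoSymbolSchema) -> frozenset[str]:
    """All one-symbol schemata reachable by rearranging each group.

    Rearrangements of the symbol multiset are applied independently per
    group; ungrouped positions are fixed.  Duplicates collapse, so a
    group with repeated symbols (e.g. ``1 1 #``) contributes only its
    distinct arrangements.
    """
    results = {schema.base}
    for group in schema.groups:
        symbols = tuple(schema.base[p] for p in group)
        arrangements = set(itertools.permutations(symbols))
        nxt = set()
        for s in results:
            chars = list(s)
            for arr in arrangements:
                for p, sym in zip(group, arr):
                    chars[p] = sym
                nxt.add("".join(chars))
        results = nxt
    return frozenset(results)


# ---------------------------------------------------------------------------
# exact compression
# ---------------------------------------------------------------------------

def _orbit(base: str, blocks: Sequence[Sequence[int]]) -> frozenset[str]:
    """Orbit of ``base`` under independent multiset rearrangement per block."""
    results = {base}
    for block in blocks:
        symbols = tuple(base[p] for p in block)
        if len(set(symbols)) == 1:
            continue
        arrangements = set(itertools.permutations(symbols))
        nxt = set()
        for s in results:
            chars = list(s)
            for arr in arrangements:
                for p, sym in zip(block, arr):
                    chars[p] = sym
                nxt.add("".join(chars))
        results = nxt
    return frozenset(results)


def _schema_key(base: str, groups: tuple[tuple[int, ...], ...]):
    return (schema_sort_key(base), groups)


def _canonical(
    expansion: frozenset[str],
    groups: tuple[tuple[int, ...], ...],
    output: str | None,
) -> TwoSymbolSchema:
    """Canonical representative: lexicographically smallest base, sorted groups.

    The orbit of a group structure is base-independent (any member
    regenerates the same expansion), so re-basing preserves semantics.
    """
    base = min(expansion, key=schema_sort_key)
    groups = tuple(sorted((tuple(sorted(g)) for g in groups)))
    return TwoSymbolSchema(base=base, groups=groups, output=output)


def _candidate_structures(base: str, members: frozenset[str]):
    """DFS over set partitions of positions, pruned by orbit validity.

    Enumerates every partition of ``range(k)`` exactly once via
    restricted growth (each position joins an existing block or opens a
    new one); blocks that end with a single position are ungrouped.  A
    branch is cut as soon as the orbit of its size->=2 blocks leaves
    ``members`` — enlarging blocks only enlarges the orbit, so no valid
    structure is missed.  Yields ``(groups, expansion)`` for structures
    whose every size->=2 block is faithful.
    """
    k = len(base)
    blocks: list[list[int]] = []

    def dfs(p: int):
        if p == k:
            groups = [b for b in blocks if len(b) >= 2]
            if all(len({base[q] for q in b}) >= 2 for b in groups):
                yield (
                    tuple(sorted(tuple(b) for b in groups)),
                    _orbit(base, groups),
                )
            return
        for b in blocks:
            b.append(p)
            big = [blk for blk in blocks if len(blk) >= 2]
            if _orbit(base, big) <= members:
                yield from dfs(p + 1)
            b.pop()
        blocks.append([p])
        yield from dfs(p + 1)
        blocks.pop()

    yield from dfs(0)


def _select_maximal(
    candidates: dict[frozenset[str], tuple[tuple[int, ...], ...]],
    output: str | None,
) -> tuple[TwoSymbolSchema, ...]:
    """Drop expansion-dominated candidates; canonicalize and sort."""
    expansions = list(candidates)
    keep = []
    for e in expansions:
        if not any(e < other for other in expansions):
            keep.append(e)
    schemata = [_canonical(e, candidates[e], output) for e in keep]
    return tuple(sorted(schemata, key=lambda t: _schema_key(t.base, t.groups)))


def _better_structure(a: tuple[tuple[int, ...], ...], b: tuple[tuple[int, ...], ...]) -> bool:
    """Prefer structures grouping more positions in fewer groups (tie: lexicographic)."""
    ka = (sum(len(g) for g in a), -len(a))
    kb = (sum(len(g) for g in b), -len(b))
    return (ka, [tuple(-p for p in g) for g in a]) > (kb, [tuple(-p for p in g) for g in b])


def compress_two_symbol(
    schemata: Iterable[str],
    output: str | None = None,
) -> tuple[TwoSymbolSchema, ...]:
    """Compress same-output one-symbol schemata into maximal two-symbol schemata.

    Parameters
    ----------
    schemata:
        Non-empty collection of equal-length strings over any symbol
        alphabet (``#`` treated like any other symbol here; its meaning
        is downstream).
    output:
        Output value to record on the returned schemata.

    Returns
    -------
    A deterministic, canonically ordered tuple of all maximal valid
    schemata.  Their expansions each lie inside the input set, jointly
    cover it exactly, every group is faithful, and no expansion is a
    strict subset of another returned expansion.  Distinct maximal
    schemata may overlap in coverage; see :func:`minimal_cover` for a
    greedy reduction.
    """
    S = frozenset(schemata)
    if not S:
        raise ValueError("schema set is empty")
    lengths = {len(s) for s in S}
    if len(lengths) != 1:
        raise ValueError(f"schemata have mixed lengths {sorted(lengths)}")

    # permutations preserve the symbol multiset: search each class separately
    classes: dict[tuple[str, ...], set[str]] = {}
    for s in S:
        classes.setdefault(tuple(sorted(s)), set()).add(s)

    candidates: dict[frozenset[str], tuple[tuple[int, ...], ...]] = {}
    for members in classes.values():
        fmembers = frozenset(members)
        for base in sorted(members, key=schema_sort_key):
            for groups, expansion in _candidate_structures(base, fmembers):
                prev = candidates.get(expansion)
                if prev is None or _better_structure(groups, prev):
                    candidates[expansion] = groups
    return _select_maximal(candidates, output)


def minimal_cover(
    schemata: Sequence[TwoSymbolSchema],
    target: Iterable[str],
) -> tuple[TwoSymbolSchema, ...]:
    """Greedy set-cover reduction of a maximal schema family.

    Repeatedly keeps the schema covering the most still-uncovered
    one-symbol schemata (largest expansion first, canonical order as
    tie-break) until the target set is covered.
    """
    remaining = set(target)
    ordered = sorted(
        schemata,
        key=lambda t: (-len(t.expand()), _schema_key(t.base, t.groups)),
    )
    chosen = []
    for schema in ordered:
        exp = schema.expand()
        if exp & remaining:
            chosen.append(schema)
            remaining -= exp
        if not remaining:
            break
    return tuple(sorted(chosen, key=lambda t: _schema_key(t.base, t.groups)))


# ---------------------------------------------------------------------------
# independent brute-force oracle
# ---------------------------------------------------------------------------

def _set_partitions(items: Sequence[int]):
    """All set partitions of ``items`` (blocks as tuples)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + (first,)] + part[i + 1 :]
        yield part + [(first,)]


def _permutation_orbit(base: str, blocks: Sequence[tuple[int, ...]]) -> frozenset[str]:
    """Orbit of ``base`` under the direct product of symmetric groups.

    Applies every position permutation (per-block permutations composed
    across blocks) to the string — the group-action definition, distinct
    from the multiset-rearrangement route used by the main algorithm.
    """
    orbit = set()
    per_block = [list(itertools.permutations(b)) for b in blocks]
    for combo in itertools.product(*per_block):
        chars = list(base)
        for block, image in zip(blocks, combo):
            for src, dst in zip(block, image):
                chars[dst] = base[src]
        orbit.add("".join(chars))
    return frozenset(orbit)


def brute_force_two_symbol(
    schemata: Iterable[str],
    output: str | None = None,
    max_k: int = 6,
    max_size: int = 64,
) -> tuple[TwoSymbolSchema, ...]:
    """Oracle-by-enumeration with the same contract as :func:`compress_two_symbol`.

    Enumerates, for every base string and every set partition of the
    positions, the orbit under per-block position permutations; keeps
    candidates whose orbit stays inside the input set and whose
    size->=2 blocks are faithful; discards expansion-dominated
    candidates.  Guarded to small problems (``k <= max_k``,
    ``|S| <= max_size``).
    """
    S = frozenset(schemata)
    if not S:
        raise ValueError("schema set is empty")
    k = len(next(iter(S)))
    if any(len(s) != k for s in S):
        raise ValueError("schemata have mixed lengths")
    if k > max_k or len(S) > max_size:
        raise ValueError(
            f"brute force guarded to k<={max_k}, |S|<={max_size} "
            f"(got k={k}, |S|={len(S)})"
        )

    candidates: dict[frozenset[str], tuple[tuple[int, ...], ...]] = {}
    for base in S:
        for part in _set_partitions(tuple(range(k))):
            blocks = [b for b in part if len(b) >= 2]
            if any(len({base[p] for p in b}) < 2 for b in blocks):
                continue
            orbit = _permutation_orbit(base, blocks)
            if not orbit <= S:
                continue
            groups = tuple(sorted(tuple(sorted(b)) for b in blocks))
            prev = candidates.get(orbit)
            if prev is None or _better_structure(groups, prev):
                candidates[orbit] = groups
    return _select_maximal(candidates, output)
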