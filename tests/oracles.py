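"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the package's algorithms: prime implicants are
found by enumerating all 3^k candidate schemata and filtering; input
roles are found by direct pointwise comparison over configurations.
"""

from __future__ import annotations

import itertools


def brute_force_prime_implicants(outputs: str, k: int, value: str) -> set[str]:
    """All prime implicants of the function, by 3^k candidate enumeration."""

    def expansion(schema: str) -> set[int]:
        rows = set()
        for fill in itertools.product("01", repeat=schema.count("#")):
            chars, it = list(schema), iter(fill)
            for i, c in enumerate(chars):
                if c == "#":
                    chars[i] = next(it)
            rows.add(int("".join(chars), 2) if k else 0)
        return rows

    def pure(schema: str) -> bool:
        return all(outputs[r] == value for r in expansion(schema))

    implicants = [
        "".join(s)
        for s in itertools.product("01#", repeat=k)
        if pure("".join(s)) and expansion("".join(s))
    ]

    def widen(schema: str):
        for i, c in enumerate(schema):
            if c != "#":
                yield schema[:i] + "#" + schema[i + 1 :]

    return {s for s in implicants if not any(pure(w) for w in widen(s))}


def brute_force_roles(outputs: str, k: int) -> list[str]:
    """Per-input role by pointwise comparison of all 0->1 flips."""
    roles = []
    for i in range(k):
        up = down = False
        for cfg in itertools.product("01", repeat=k):
            if cfg[i] == "1":
                continue
            lo = outputs[int("".join(cfg), 2)]
            flipped = cfg[:i] + ("1",) + cfg[i + 1 :]
            hi = outputs[int("".join(flipped), 2)]
            if (lo, hi) == ("0", "1"):
                up = True
            if (lo, hi) == ("1", "0"):
                down = True
        roles.append(
            "dual" if up and down else "activator" if up
            else "inhibitor" if down else "inessential"
        )
    return roles
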