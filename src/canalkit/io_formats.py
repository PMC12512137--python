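"""Readers and writers for automata, networks and analysis artifacts.

Two input formats are supported:

* **LUT files** — explicit lookup tables.  A block starts with a header
  ``node <name> <k> <comma-separated input labels>`` followed by
  ``2**k`` rows ``<k binary digits> <output digit>``.  Rows may appear
  in any order but must be complete and free of duplicates.  Blank
  lines separate blocks; lines starting with ``%`` are comments.
* **Rule files** — the widely used "targets, factors" dialect: one line
  ``target, expression`` per node with operators ``&``/``AND``,
  ``|``/``OR``, ``!``/``NOT``, parentheses, and the constants 0 and 1.
  Inputs are ordered by first appearance in the expression.  Sources
  that never appear as targets get implicit identity rules so the
  network is closed.

Schemata are serialized to JSON (expansion-equivalent after reload) and
graphs to DOT or GraphML.
"""

from __future__ import annotations

import itertools
import json
import re
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .boolean_core import BooleanNetwork, BooleanNode, is_essential
from .two_symbol import TwoSymbolSchema

__all__ = [
    "ParseError",
    "read_lut_file",
    "write_lut_file",
    "read_rules_file",
    "read_network",
    "write_schemata_json",
    "read_schemata_json",
    "write_graph",
]


class ParseError(ValueError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        where = f"line {line}: " if line is not None else ""
        super().__init__(f"{where}{message}")


# ---------------------------------------------------------------------------
# LUT files
# ---------------------------------------------------------------------------

def read_lut_file(path: str | Path) -> BooleanNetwork:
    """Parse a LUT file into a network (see module docstring for grammar)."""
    nodes = []
    header: tuple[str, int, tuple[str, ...]] | None = None
    rows: dict[str, str] = {}
    header_line = 0

    def close_block(line_no: int) -> None:
        nonlocal header, rows
        if header is None:
            return
        name, k, labels = header
        if len(rows) != 2**k:
            raise ParseError(
                f"node {name!r}: expected {2**k} rows, got {len(rows)}", line_no
            )
        outputs = tuple(
            rows["".join(cfg)] for cfg in itertools.product("01", repeat=k)
        )
        nodes.append(
            BooleanNode(name=name, k=k, input_labels=labels, outputs=outputs)
        )
        header, rows = None, {}

    text = Path(path).read_text()
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        if line.startswith("node "):
            close_block(line_no)
            parts = line.split(None, 3)
            if len(parts) < 4:
                raise ParseError(
                    "header must be 'node <name> <k> <input labels>'", line_no
                )
            _, name, k_str, label_str = parts
            try:
                k = int(k_str)
            except ValueError:
                raise ParseError(f"in-degree {k_str!r} is not an integer", line_no)
            labels = tuple(s.strip() for s in label_str.split(","))
            if len(labels) != k or any(not s for s in labels):
                raise ParseError(
                    f"expected {k} comma-separated input labels", line_no
                )
            header = (name, k, labels)
            header_line = line_no
            continue
        if header is None:
            raise ParseError("LUT row before any 'node' header", line_no)
        parts = line.split()
        k = header[1]
        if len(parts) != 2 or len(parts[0]) != k or len(parts[1]) != 1:
            raise ParseError(
                f"expected '<{k} binary digits> <output digit>'", line_no
            )
        config, out = parts
        if set(config) - {"0", "1"} or out not in "01":
            raise ParseError(f"unknown symbols in row {line!r}", line_no)
        if config in rows:
            raise ParseError(f"duplicate configuration {config!r}", line_no)
        rows[config] = out
    close_block(len(text.splitlines()) + 1)
    if not nodes:
        raise ParseError("no node blocks found")
    return BooleanNetwork(nodes=tuple(nodes))


def write_lut_file(network: BooleanNetwork, path: str | Path) -> None:
    """Write a network in the LUT format (lossless round-trip)."""
    lines = []
    for node in network:
        lines.append(f"node {node.name} {node.k} {', '.join(node.input_labels)}")
        for row, out in enumerate(node.outputs):
            lines.append(f"{node.config(row)} {out}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# rule ("targets, factors") files
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\s*(\w+|[&|!()])")
_WORD_OPS = {"AND": "&", "OR": "|", "NOT": "!"}


def _compile_expression(expr: str, line_no: int):
    """Translate a rule expression to a Python callable plus its input order."""
    tokens = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN.match(expr, pos)
        if m is None:
            raise ParseError(f"cannot tokenize {expr[pos:]!r}", line_no)
        tokens.append(m.group(1))
        pos = m.end()
    inputs: list[str] = []
    py = []
    for tok in tokens:
        tok = _WORD_OPS.get(tok, tok)
        if tok == "&":
            py.append(" and ")
        elif tok == "|":
            py.append(" or ")
        elif tok == "!":
            py.append(" not ")
        elif tok in "()":
            py.append(tok)
        elif tok in ("0", "1"):
            py.append(" False " if tok == "0" else " True ")
        elif re.fullmatch(r"\w+", tok):
            if tok not in inputs:
                inputs.append(tok)
            py.append(f" _v[{inputs.index(tok)!r}] ")
        else:  # pragma: no cover - tokenizer admits nothing else
            raise ParseError(f"unexpected token {tok!r}", line_no)
    source = "".join(py).strip()
    try:
        code = compile(source, f"<rules line {line_no}>", "eval")
    except SyntaxError as err:
        raise ParseError(f"syntax error in expression {expr!r}: {err.msg}", line_no)
    return code, inputs


def read_rules_file(path: str | Path) -> BooleanNetwork:
    """Parse a "targets, factors" rule file into a network of LUT nodes.

    Each expression is compiled to a lookup table over its inputs in
    order of first appearance.  A warning is emitted for inessential
    inputs (the expression mentions a variable its value never uses).
    """
    nodes: list[BooleanNode] = []
    targets: set[str] = set()
    referenced: list[str] = []
    for line_no, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("%"):
            continue
        if "," not in line:
            raise ParseError("expected 'target, expression'", line_no)
        target, expr = (s.strip() for s in line.split(",", 1))
        if target.lower() == "targets" and expr.lower() == "factors":
            continue  # BoolNet column header
        if not re.fullmatch(r"\w+", target or ""):
            raise ParseError(f"bad target name {target!r}", line_no)
        if target in targets:
            raise ParseError(f"duplicate rule for {target!r}", line_no)
        code, inputs = _compile_expression(expr, line_no)
        k = len(inputs)
        outputs = []
        for cfg in itertools.product("01", repeat=k):
            _v = {i: c == "1" for i, c in enumerate(cfg)}
            outputs.append("1" if eval(code, {"__builtins__": {}}, {"_v": _v}) else "0")
        node = BooleanNode(
            name=target, k=k, input_labels=tuple(inputs), outputs=tuple(outputs)
        )
        for i, label in enumerate(inputs):
            if not is_essential(node, i):
                warnings.warn(
                    f"rule for {target!r}: input {label!r} is inessential",
                    stacklevel=2,
                )
        nodes.append(node)
        targets.add(target)
        referenced.extend(inputs)
    if not nodes:
        raise ParseError("no rules found")
    # close the network: implicit identity rules for pure inputs
    for label in dict.fromkeys(referenced):
        if label not in targets:
            nodes.append(
                BooleanNode(
                    name=label, k=1, input_labels=(label,), outputs=("0", "1")
                )
            )
    return BooleanNetwork(nodes=tuple(nodes))


def read_network(path: str | Path) -> BooleanNetwork:
    """Dispatch on extension: ``.lut`` -> LUT grammar, otherwise rules."""
    path = Path(path)
    if path.suffix == ".lut":
        return read_lut_file(path)
    return read_rules_file(path)


# ---------------------------------------------------------------------------
# schemata JSON
# ---------------------------------------------------------------------------

def write_schemata_json(
    schemata: dict[str, Sequence[TwoSymbolSchema]],
    path: str | Path,
    node_name: str | None = None,
) -> None:
    """Serialize two-symbol schemata keyed by output value.

    Groups are recorded as 0-based position lists; the document reloads
    expansion-equivalently via :func:`read_schemata_json`.
    """
    doc = {
        "node": node_name,
        "schemata": {
            out: [
                {"base": t.base, "groups": [list(g) for g in t.groups]}
                for t in ts
            ]
            for out, ts in schemata.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_schemata_json(path: str | Path) -> dict[str, tuple[TwoSymbolSchema, ...]]:
    doc = json.loads(Path(path).read_text())
    return {
        out: tuple(
            TwoSymbolSchema(
                base=item["base"],
                groups=tuple(tuple(g) for g in item["groups"]),
                output=out,
            )
            for item in items
        )
        for out, items in doc["schemata"].items()
    }


# ---------------------------------------------------------------------------
# graphs
# ---------------------------------------------------------------------------

def _dot_escape(s: str) -> str:
    return '"' + str(s).replace('"', '\\"') + '"'


def write_graph(graph: nx.DiGraph, path: str | Path, fmt: str = "dot") -> None:
    """Write a directed graph as DOT or GraphML; attributes are preserved."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(graph, path)
        return
    if fmt != "dot":
        raise ValueError(f"unknown graph format {fmt!r}")
    lines = ["digraph G {"]
    for n, data in graph.nodes(data=True):
        attrs = ", ".join(f"{k}={_dot_escape(v)}" for k, v in data.items())
        lines.append(f"  {_dot_escape(n)}" + (f" [{attrs}]" if attrs else "") + ";")
    for u, v, data in graph.edges(data=True):
        attrs = ", ".join(f"{k}={_dot_escape(val)}" for k, val in data.items())
        lines.append(
            f"  {_dot_escape(u)} -> {_dot_escape(v)}"
            + (f" [{attrs}]" if attrs else "")
            + ";"
        )
    lines.append("}")
    path.write_text("\n".join(lines))
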