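"""Reading and writing Boolean network models and results as plain text.

Two input dialects are supported:

* line rules — one ``name = expression`` per line, ``#`` comments;
* BoolNet-compatible tables — a ``targets, factors`` header followed by one
  ``name, expression`` row per node.

Expressions use ``&``/``AND``, ``|``/``OR``, ``!``/``NOT``, ``^``/``XOR``
(keywords case-insensitive), the literals ``0``/``1`` and parentheses, with
precedence NOT > AND > XOR > OR.
"""

from __future__ import annotations

import json
import re
from typing import Union

from .core import (
    And,
    AndNotNetwork,
    BooleanNetwork,
    Const,
    Expr,
    Not,
    Or,
    SignedDigraph,
    SteadyStateSet,
    Var,
    Xor,
    NAME_RE,
)
from .errors import InputError, ParseError

# ---------------------------------------------------------------------------
# Expression parsing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_]*)|(?P<const>[01])"
    r"|(?P<op>[&|!^()])|(?P<bad>\S))"
)

_KEYWORDS = {"and": "&", "or": "|", "not": "!", "xor": "^"}


def _tokenize(text: str, line: int) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        pos = m.end()
        if m.lastgroup == "bad":
            raise ParseError(f"unexpected character {m.group('bad')!r}", line)
        if m.lastgroup == "name":
            word = m.group("name")
            tokens.append(_KEYWORDS.get(word.lower(), word))
        else:
            tokens.append(m.group(m.lastgroup))
    return tokens


class _ExprParser:
    """Recursive-descent parser with precedence NOT > AND > XOR > OR."""

    def __init__(self, tokens: list[str], line: int):
        self.tokens = tokens
        self.pos = 0
        self.line = line

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ParseError("unexpected end of expression", self.line)
        self.pos += 1
        return tok

    def parse(self) -> Expr:
        e = self.parse_or()
        if self.peek() is not None:
            raise ParseError(f"unexpected token {self.peek()!r}", self.line)
        return e

    def _nary(self, sub, op: str, cls) -> Expr:
        parts = [sub()]
        while self.peek() == op:
            self.take()
            parts.append(sub())
        return parts[0] if len(parts) == 1 else cls(tuple(parts))

    def parse_or(self) -> Expr:
        return self._nary(self.parse_xor, "|", Or)

    def parse_xor(self) -> Expr:
        return self._nary(self.parse_and, "^", Xor)

    def parse_and(self) -> Expr:
        return self._nary(self.parse_unary, "&", And)

    def parse_unary(self) -> Expr:
        if self.peek() == "!":
            self.take()
            return Not(self.parse_unary())
        return self.parse_atom()

    def parse_atom(self) -> Expr:
        tok = self.take()
        if tok == "(":
            e = self.parse_or()
            if self.take() != ")":
                raise ParseError("missing closing parenthesis", self.line)
            return e
        if tok in ("0", "1"):
            return Const(int(tok))
        if NAME_RE.match(tok):
            return Var(tok)
        raise ParseError(f"unexpected token {tok!r}", self.line)


def parse_expression(text: str, line: int = 0) -> Expr:
    tokens = _tokenize(text, line)
    if not tokens:
        raise ParseError("empty expression", line)
    return _ExprParser(tokens, line).parse()


# ---------------------------------------------------------------------------
# Rule files
# ---------------------------------------------------------------------------

_BOOLNET_HEADER = re.compile(r"targets\s*[,\t]\s*factors\s*$", re.IGNORECASE)


def _strip(line: str) -> str:
    return line.split("#", 1)[0].strip()


def parse_rules(text: str) -> BooleanNetwork:
    """Parse rule text (line rules or a BoolNet table) into a network.

    Raises :class:`ParseError` with a line number on syntax errors,
    duplicate definitions, and references to undefined symbols.
    """
    lines = text.splitlines()
    boolnet = False
    start = 0
    for i, raw in enumerate(lines):
        body = _strip(raw)
        if not body:
            continue
        if _BOOLNET_HEADER.match(body):
            boolnet = True
            start = i + 1
        break

    order: list[str] = []
    functions: dict[str, Expr] = {}
    for i in range(start, len(lines)):
        lineno = i + 1
        body = _strip(lines[i])
        if not body:
            continue
        sep = "," if boolnet else "="
        if sep not in body:
            raise ParseError(f"expected {sep!r} in rule", lineno)
        name, rhs = body.split(sep, 1)
        name = name.strip()
        if not NAME_RE.match(name):
            raise ParseError(f"invalid node name {name!r}", lineno)
        if name in functions:
            raise ParseError(f"duplicate definition of {name!r}", lineno)
        order.append(name)
        functions[name] = parse_expression(rhs, lineno)

    if not order:
        raise ParseError("no rules found")
    declared = set(order)
    for name in order:
        from .core import expr_variables

        undefined = expr_variables(functions[name]) - declared
        if undefined:
            raise ParseError(
                f"rule for {name!r} references undefined symbol(s) "
                f"{sorted(undefined)}; declare inputs as 'x = x' or constants"
            )
    return BooleanNetwork(tuple(order), functions)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

_PREC = {Or: 1, Xor: 2, And: 3, Not: 4}


def format_expression(e: Expr) -> str:
    def fmt(node: Expr, parent_prec: int) -> str:
        if isinstance(node, Var):
            return node.name
        if isinstance(node, Const):
            return str(node.value)
        if isinstance(node, Not):
            return "!" + fmt(node.child, _PREC[Not])
        op = {And: " & ", Or: " | ", Xor: " ^ "}[type(node)]
        prec = _PREC[type(node)]
        body = op.join(fmt(c, prec) for c in node.children)
        return f"({body})" if prec < parent_prec else body

    return fmt(e, 0)


def _andnot_expr(fn) -> str:
    if isinstance(fn, int):
        return str(fn)
    return " & ".join(
        (src if sign > 0 else f"!{src}") for src, sign in fn.items()
    )


def write_rules(network: Union[BooleanNetwork, AndNotNetwork]) -> str:
    """Render a network in the line-rule dialect (round-trips via parse)."""
    lines = []
    for v in network.variables:
        fn = network.functions[v]
        rhs = _andnot_expr(fn) if isinstance(network, AndNotNetwork) else \
            format_expression(fn)
        lines.append(f"{v} = {rhs}")
    return "\n".join(lines) + "\n"


def write_steady_states(states: SteadyStateSet, format: str = "csv") -> str:
    """Serialize a steady-state set; states sorted as ascending binary ints."""
    rows = states.sorted_states()
    if format == "bits":
        return "\n".join("".join(str(b) for b in s) for s in rows) + (
            "\n" if rows else ""
        )
    if format == "csv":
        out = [",".join(states.variables)]
        out += [",".join(str(b) for b in s) for s in rows]
        return "\n".join(out) + "\n"
    if format == "json":
        return json.dumps(
            [dict(zip(states.variables, map(int, s))) for s in rows],
            indent=None,
        )
    raise InputError(f"unknown steady-state format {format!r}")


def export_digraph(d: SignedDigraph, dialect: str = "sif") -> str:
    """Render a signed digraph as SIF (``activates``/``inhibits``) or DOT."""
    edges = d.sorted_edges()
    if dialect == "sif":
        word = {1: "activates", -1: "inhibits"}
        return "\n".join(f"{s} {word[g]} {t}" for s, t, g in edges) + (
            "\n" if edges else ""
        )
    if dialect == "dot":
        lines = ["digraph wiring {"]
        for node in d.nodes:
            lines.append(f'  "{node}";')
        for s, t, g in edges:
            sign = "+" if g > 0 else "-"
            style = "normal" if g > 0 else "tee"
            lines.append(
                f'  "{s}" -> "{t}" [sign="{sign}", arrowhead={style}];'
            )
        lines.append("}")
        return "\n".join(lines) + "\n"
    raise InputError(f"unknown digraph dialect {dialect!r}")
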