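"""Text rule-file dialect: one ``name, expression`` line per variable.

The dialect follows the widely used "targets, factors" Boolean-rule text
format: ``!`` for NOT, ``&`` for AND, ``|`` for OR, parentheses for
grouping, plus a ``MAJ(...)`` extension for the rounded-mean threshold
operator. Precedence is NOT > AND > OR.

Metadata lines:

* ``#% network: NAME`` — network name;
* ``#@ VAR key=value ...`` — per-variable tags (``role``, ``group``);
* plain ``#`` lines are comments and are ignored.

Writing always produces canonical form (sorted tags, minimal but
structure-preserving parentheses), and ``parse(write(net))`` reproduces
the network exactly — up to free-text annotations, which are not
serialized.

Example::

    #% network: toy
    targets, factors
    #@ RAS role=intervention
    BF, !RAS & !MVrare
    MVrare, MAJ(BF, !RAS)
    RAS, RAS
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .expressions import And, BooleanExpression, Majority, Not, Or, Var
from .network import BooleanNetwork, VariableSpec

__all__ = ["parse_rules", "write_rules", "format_expression", "RuleSyntaxError"]

_NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_HEADER = "targets, factors"


class RuleSyntaxError(ValueError):
    """Malformed rule file; carries 1-based line and column."""

    def __init__(self, message: str, line: int, column: int | None = None):
        at = f"line {line}" + (f", column {column}" if column is not None else "")
        super().__init__(f"{message} ({at})")
        self.line = line
        self.column = column


# ---------------------------------------------------------------------------
# parsing


@dataclass
class _Tok:
    kind: str  # NAME LPAREN RPAREN COMMA NOT AND OR MAJ END
    text: str
    column: int


def _tokenize(text: str, line_no: int) -> list[_Tok]:
    toks: list[_Tok] = []
    i = 0
    while i < len(text):
        c = text[i]
        if c.isspace():
            i += 1
            continue
        col = i + 1
        if c == "(":
            toks.append(_Tok("LPAREN", c, col))
        elif c == ")":
            toks.append(_Tok("RPAREN", c, col))
        elif c == ",":
            toks.append(_Tok("COMMA", c, col))
        elif c == "!":
            toks.append(_Tok("NOT", c, col))
        elif c == "&":
            toks.append(_Tok("AND", c, col))
        elif c == "|":
            toks.append(_Tok("OR", c, col))
        else:
            m = _NAME_RE.match(text, i)
            if not m:
                raise RuleSyntaxError(f"unexpected character {c!r}", line_no, col)
            word = m.group(0)
            toks.append(_Tok("MAJ" if word == "MAJ" else "NAME", word, col))
            i = m.end()
            continue
        i += 1
    toks.append(_Tok("END", "", len(text) + 1))
    return toks


class _Parser:
    def __init__(self, toks: list[_Tok], line_no: int, resolve):
        self.toks = toks
        self.pos = 0
        self.line_no = line_no
        self.resolve = resolve  # name -> Var

    def peek(self) -> _Tok:
        return self.toks[self.pos]

    def take(self, kind: str) -> _Tok:
        tok = self.toks[self.pos]
        if tok.kind != kind:
            raise RuleSyntaxError(
                f"expected {kind}, found {tok.text or 'end of line'!r}",
                self.line_no,
                tok.column,
            )
        self.pos += 1
        return tok

    def parse(self) -> BooleanExpression:
        expr = self.or_expr()
        tok = self.peek()
        if tok.kind != "END":
            raise RuleSyntaxError(
                f"unexpected trailing {tok.text!r}", self.line_no, tok.column
            )
        return expr

    def or_expr(self) -> BooleanExpression:
        parts = [self.and_expr()]
        while self.peek().kind == "OR":
            self.take("OR")
            parts.append(self.and_expr())
        return parts[0] if len(parts) == 1 else Or(*parts)

    def and_expr(self) -> BooleanExpression:
        parts = [self.unary()]
        while self.peek().kind == "AND":
            self.take("AND")
            parts.append(self.unary())
        return parts[0] if len(parts) == 1 else And(*parts)

    def unary(self) -> BooleanExpression:
        if self.peek().kind == "NOT":
            self.take("NOT")
            return Not(self.unary())
        return self.atom()

    def atom(self) -> BooleanExpression:
        tok = self.peek()
        if tok.kind == "LPAREN":
            self.take("LPAREN")
            expr = self.or_expr()
            self.take("RPAREN")
            return expr
        if tok.kind == "MAJ":
            self.take("MAJ")
            self.take("LPAREN")
            children = [self.or_expr()]
            while self.peek().kind == "COMMA":
                self.take("COMMA")
                children.append(self.or_expr())
            self.take("RPAREN")
            return Majority(*children)
        if tok.kind == "NAME":
            self.take("NAME")
            return self.resolve(tok.text, tok.column)
        raise RuleSyntaxError(
            f"expected an expression, found {tok.text or 'end of line'!r}",
            self.line_no,
            tok.column,
        )


def parse_rules(text: str, name: str | None = None) -> BooleanNetwork:
    """Parse a rule file into a validated :class:`BooleanNetwork`.

    Variable order follows the order of definition lines; operands must
    all be defined somewhere in the file (forward references are fine).
    """
    net_name = name or "network"
    tags: dict[str, dict[str, str]] = {}
    defs: list[tuple[int, str, str]] = []  # line_no, name, expr text
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#%"):
            m = re.match(r"#%\s*network\s*:\s*(\S+)\s*$", line)
            if m and name is None:
                net_name = m.group(1)
            continue
        if line.startswith("#@"):
            body = line[2:].strip().split()
            if not body:
                raise RuleSyntaxError("empty #@ tag line", line_no)
            var, *pairs = body
            entry = tags.setdefault(var, {})
            for pair in pairs:
                if "=" not in pair:
                    raise RuleSyntaxError(f"malformed tag {pair!r}", line_no)
                k, v = pair.split("=", 1)
                entry[k] = v
            continue
        if line.startswith("#"):
            continue
        line = line.split("#", 1)[0].strip()  # trailing comments
        if line.lower() == _HEADER:
            continue
        if "," not in line:
            raise RuleSyntaxError("expected 'name, expression'", line_no)
        lhs, rhs = line.split(",", 1)
        lhs = lhs.strip()
        if not _NAME_RE.fullmatch(lhs):
            raise RuleSyntaxError(f"invalid variable name {lhs!r}", line_no)
        if lhs in (d[1] for d in defs):
            raise RuleSyntaxError(f"duplicate definition of {lhs!r}", line_no)
        defs.append((line_no, lhs, rhs))

    if not defs:
        raise RuleSyntaxError("no variables defined", 1)

    index_of = {vname: i for i, (_, vname, _) in enumerate(defs, start=1)}

    variables = []
    for i, (_, vname, _) in enumerate(defs, start=1):
        tag = tags.get(vname, {})
        role = tag.get("role", "biological")
        if role not in ("biological", "intervention"):
            raise RuleSyntaxError(f"unknown role {role!r} for {vname!r}", 1)
        variables.append(
            VariableSpec(index=i, name=vname, role=role, group=tag.get("group", ""))
        )
    unknown_tags = set(tags) - set(index_of)
    if unknown_tags:
        raise RuleSyntaxError(
            f"#@ tags for undefined variables: {sorted(unknown_tags)}", 1
        )

    rules: dict[int, BooleanExpression] = {}
    for i, (line_no, vname, rhs) in enumerate(defs, start=1):

        def resolve(word: str, column: int, _line=line_no):
            try:
                return Var(index_of[word])
            except KeyError:
                raise RuleSyntaxError(
                    f"unknown operand {word!r}", _line, column
                ) from None

        rules[i] = _Parser(_tokenize(rhs, line_no), line_no, resolve).parse()

    return BooleanNetwork(variables, rules, name=net_name).require_valid()


# ---------------------------------------------------------------------------
# writing

_PREC = {"or": 1, "and": 2, "not": 3, "atom": 4}


def format_expression(expr: BooleanExpression, names: tuple[str, ...]) -> str:
    """Canonical text for one expression (``!``/``&``/``|``/``MAJ``)."""

    def fmt(node: BooleanExpression, parent_prec: int) -> str:
        if isinstance(node, Var):
            return names[node.index - 1]
        if isinstance(node, Majority):
            inner = ", ".join(fmt(c, _PREC["or"]) for c in node.children)
            return f"MAJ({inner})"
        if isinstance(node, Not):
            text = "!" + fmt(node.child, _PREC["not"])
            prec = _PREC["not"]
        elif isinstance(node, And):
            text = " & ".join(fmt(c, _PREC["and"] + 1) for c in node.children)
            prec = _PREC["and"]
        else:  # Or
            text = " | ".join(fmt(c, _PREC["or"] + 1) for c in node.children)
            prec = _PREC["or"]
        # parenthesize when precedence would not reparse to the same tree;
        # equal precedence needs parens too (nested And inside And must
        # survive the round trip rather than flatten)
        return f"({text})" if prec < parent_prec else text

    return fmt(expr, 0)


def write_rules(network: BooleanNetwork) -> str:
    """Serialize a network to canonical rule-file text."""
    network.require_valid()
    lines = [f"#% network: {network.name}", _HEADER]
    for v in network.variables:
        tag_parts = []
        if v.role != "biological":
            tag_parts.append(f"role={v.role}")
        if v.group:
            tag_parts.append(f"group={v.group}")
        if tag_parts:
            lines.append(f"#@ {v.name} " + " ".join(tag_parts))
    for v in network.variables:
        lines.append(f"{v.name}, {format_expression(network.rules[v.index], network.names)}")
    return "\n".join(lines) + "\n"
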