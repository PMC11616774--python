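"""Boolean rule expressions: AST, evaluation, parsing, and rendering.

The expression language is the one used by BoolNet-style rule files:
identifiers, the constants ``0``/``1``, negation ``!``, conjunction ``&``,
disjunction ``|``, and parentheses.  Operator precedence is ``!`` > ``&`` >
``|``.  Identifiers are case-sensitive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping

from .errors import ExpressionParseError

__all__ = [
    "Expr",
    "Const",
    "Var",
    "Not",
    "And",
    "Or",
    "parse_expression",
    "expression_variables",
]


class Expr:
    """Base class for expression tree nodes."""

    #: rendering precedence; higher binds tighter
    _prec: int = 4

    def evaluate(self, env: Mapping[str, int]) -> int:
        raise NotImplementedError

    def iter_variables(self) -> Iterator[str]:
        """Yield variable names in depth-first (textual) order, with repeats."""
        raise NotImplementedError

    def _render(self) -> str:
        raise NotImplementedError

    def __str__(self) -> str:
        return self._render()


@dataclass(frozen=True)
class Const(Expr):
    value: int

    def __post_init__(self):
        if self.value not in (0, 1):
            raise ValueError("Boolean constant must be 0 or 1")

    def evaluate(self, env):
        return self.value

    def iter_variables(self):
        return iter(())

    def _render(self):
        return str(self.value)


@dataclass(frozen=True)
class Var(Expr):
    name: str

    def evaluate(self, env):
        try:
            return env[self.name]
        except KeyError:
            from .errors import UnresolvedSymbolError

            raise UnresolvedSymbolError(f"unknown variable {self.name!r}") from None

    def iter_variables(self):
        yield self.name

    def _render(self):
        return self.name


@dataclass(frozen=True)
class Not(Expr):
    child: Expr
    _prec = 3

    def evaluate(self, env):
        return 1 - self.child.evaluate(env)

    def iter_variables(self):
        return self.child.iter_variables()

    def _render(self):
        inner = self.child._render()
        if self.child._prec < self._prec:
            inner = f"({inner})"
        return f"!{inner}"


class _NaryOp(Expr):
    op: str
    children: tuple[Expr, ...]

    def iter_variables(self):
        for c in self.children:
            yield from c.iter_variables()

    def _render(self):
        parts = []
        for c in self.children:
            s = c._render()
            if c._prec < self._prec:
                s = f"({s})"
            parts.append(s)
        return f" {self.op} ".join(parts)


@dataclass(frozen=True)
class And(_NaryOp):
    children: tuple[Expr, ...]
    op = "&"
    _prec = 2

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("AND requires at least two operands")

    def evaluate(self, env):
        for c in self.children:
            if not c.evaluate(env):
                return 0
        return 1


@dataclass(frozen=True)
class Or(_NaryOp):
    children: tuple[Expr, ...]
    op = "|"
    _prec = 1

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("OR requires at least two operands")

    def evaluate(self, env):
        for c in self.children:
            if c.evaluate(env):
                return 1
        return 0


def expression_variables(expr: Expr) -> list[str]:
    """Distinct variables of *expr* in first-occurrence order."""
    seen: list[str] = []
    for name in expr.iter_variables():
        if name not in seen:
            seen.append(name)
    return seen


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<ident>[A-Za-z_][A-Za-z0-9_.]*)|(?P<const>[01])(?![0-9])"
    r"|(?P<op>[!&|()])|(?P<bad>\S))"
)


def _tokenize(text: str, line: int | None) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        if m.group("bad") is not None:
            ch = m.group("bad")
            if ch == ",":
                raise ExpressionParseError(
                    "unexpected ',' in rule expression (probabilistic BoolNet "
                    "rules are not supported)",
                    line,
                )
            if ch in "[]":
                raise ExpressionParseError(
                    "temporal-operator syntax is not supported", line
                )
            raise ExpressionParseError(f"unexpected character {ch!r}", line)
        for kind in ("ident", "const", "op"):
            if m.group(kind) is not None:
                tokens.append((kind, m.group(kind)))
                break
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser for the rule grammar.

    expr   := term ('|' term)*
    term   := factor ('&' factor)*
    factor := '!' factor | '(' expr ')' | IDENT | '0' | '1'
    """

    def __init__(self, tokens: list[tuple[str, str]], line: int | None):
        self.tokens = tokens
        self.pos = 0
        self.line = line

    def _peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, None)

    def _next(self):
        tok = self._peek()
        self.pos += 1
        return tok

    def _expect_op(self, op: str):
        kind, val = self._next()
        if kind != "op" or val != op:
            raise ExpressionParseError(
                f"expected {op!r}, found {val!r}" if val else f"expected {op!r}",
                self.line,
            )

    def parse(self) -> Expr:
        expr = self._expr()
        kind, val = self._peek()
        if kind is not None:
            raise ExpressionParseError(f"unexpected trailing token {val!r}", self.line)
        return expr

    def _expr(self) -> Expr:
        terms = [self._term()]
        while self._peek() == ("op", "|"):
            self._next()
            terms.append(self._term())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def _term(self) -> Expr:
        factors = [self._factor()]
        while self._peek() == ("op", "&"):
            self._next()
            factors.append(self._factor())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def _factor(self) -> Expr:
        kind, val = self._next()
        if kind == "op" and val == "!":
            return Not(self._factor())
        if kind == "op" and val == "(":
            inner = self._expr()
            self._expect_op(")")
            return inner
        if kind == "ident":
            return Var(val)
        if kind == "const":
            return Const(int(val))
        raise ExpressionParseError(
            f"unexpected token {val!r}" if val else "unexpected end of expression",
            self.line,
        )


def parse_expression(text: str, line: int | None = None) -> Expr:
    """Parse a rule expression; *line* is used only for error messages."""
    tokens = _tokenize(text, line)
    if not tokens:
        raise ExpressionParseError("empty expression", line)
    return _Parser(tokens, line).parse()
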