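"""Boolean network container and readers/writers for the supported formats.

Two on-disk formats are supported:

* the plain-text rule format of the BoolNet R package — a ``targets, factors``
  header followed by one ``<target>, <expression>`` line per node;
* SBML Level 3 with the ``qual`` package, restricted to two-level
  (Boolean) qualitative species.

Rules are compiled to truth tables at load time.  The bit-order convention is
fixed and observable throughout the package: **the first listed input is the
least-significant bit** of the truth-table index, so ``table[b]`` is the rule
value when input ``j`` carries bit ``j`` of ``b``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

from .errors import (
    ExpressionParseError,
    FormatError,
    UnresolvedSymbolError,
    UnsupportedConstructError,
    UnsupportedModelError,
)
from .expressions import (
    And,
    Const,
    Expr,
    Not,
    Or,
    Var,
    expression_variables,
    parse_expression,
)

__all__ = [
    "Rule",
    "BooleanNetwork",
    "compile_truth_table",
    "expression_from_table",
    "parse_boolnet",
    "write_boolnet",
    "parse_sbml_qual",
]


def compile_truth_table(expr: Expr, inputs: Iterable[str]) -> tuple[int, ...]:
    """Evaluate *expr* on every assignment of *inputs*.

    Returns a bit vector of length ``2**k``; entry ``b`` is the value of the
    expression with input ``j`` set to bit ``j`` of ``b`` (first input =
    least-significant bit).  Raises :class:`UnresolvedSymbolError` if the
    expression mentions a variable outside *inputs*.
    """
    inputs = list(inputs)
    extra = set(expression_variables(expr)) - set(inputs)
    if extra:
        raise UnresolvedSymbolError(
            f"expression references undeclared inputs: {sorted(extra)}"
        )
    k = len(inputs)
    table = []
    for b in range(2**k):
        env = {name: (b >> j) & 1 for j, name in enumerate(inputs)}
        table.append(expr.evaluate(env))
    return tuple(table)


def expression_from_table(inputs: Iterable[str], table: Iterable[int]) -> Expr:
    """Synthesize an expression (full-minterm DNF) realizing *table*.

    Every declared input appears in the result even when non-essential, so a
    rule written out and re-parsed recovers the same input list: constant-0
    tables become ``0 & x1 & …`` and constant-1 tables ``1 | x1 | …``.
    """
    inputs = list(inputs)
    table = list(table)
    k = len(inputs)
    if len(table) != 2**k:
        raise ValueError(f"table length {len(table)} != 2^{k}")
    if k == 0:
        return Const(table[0])
    ones = [b for b, v in enumerate(table) if v]
    vars_ = [Var(name) for name in inputs]
    if not ones:
        return And(tuple([Const(0), *vars_]))
    if len(ones) == len(table):
        return Or(tuple([Const(1), *vars_]))

    def minterm(b: int) -> Expr:
        lits: list[Expr] = [
            vars_[j] if (b >> j) & 1 else Not(vars_[j]) for j in range(k)
        ]
        return lits[0] if k == 1 else And(tuple(lits))

    terms = [minterm(b) for b in ones]
    return terms[0] if len(terms) == 1 else Or(tuple(terms))


@dataclass(frozen=True)
class Rule:
    """Update rule of one node: ordered distinct inputs, expression, table."""

    inputs: tuple[str, ...]
    expr: Expr
    table: tuple[int, ...]

    def __post_init__(self):
        if len(set(self.inputs)) != len(self.inputs):
            raise ValueError("rule inputs must be distinct")
        if len(self.table) != 2 ** len(self.inputs):
            raise ValueError("truth table length must be 2^k")

    @classmethod
    def from_expression(cls, expr: Expr) -> "Rule":
        inputs = tuple(expression_variables(expr))
        return cls(inputs, expr, compile_truth_table(expr, inputs))


@dataclass
class BooleanNetwork:
    """A synchronous Boolean network ``x(t+1) = f(x(t))``.

    ``nodes`` fixes the state-vector coordinate order; ``rules`` maps each
    node name to its update rule.
    """

    nodes: tuple[str, ...]
    rules: dict[str, Rule] = field(repr=False)

    def __post_init__(self):
        self.nodes = tuple(self.nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise FormatError("node names must be unique")
        if any(not n for n in self.nodes):
            raise FormatError("node names must be non-empty")
        if set(self.rules) != set(self.nodes):
            raise FormatError("rules must cover exactly the declared nodes")
        for name, rule in self.rules.items():
            missing = set(rule.inputs) - set(self.nodes)
            if missing:
                raise UnresolvedSymbolError(
                    f"rule for {name!r} references undefined node(s) "
                    f"{sorted(missing)}"
                )

    @property
    def n(self) -> int:
        return len(self.nodes)

    def __eq__(self, other):
        if not isinstance(other, BooleanNetwork):
            return NotImplemented
        return self.nodes == other.nodes and all(
            self.rules[v].inputs == other.rules[v].inputs
            and self.rules[v].table == other.rules[v].table
            for v in self.nodes
        )


_IDENT_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_.]*\Z")
_HEADER_RE = re.compile(r"targets\s*,\s*factors\s*\Z", re.IGNORECASE)


def parse_boolnet(source: str | IO[str]) -> BooleanNetwork:
    """Parse a BoolNet-format rule file.

    Lines starting with ``#`` and blank lines are ignored.  The first content
    line must be the ``targets, factors`` header.  Identifiers are
    case-sensitive.  Probabilistic rules and temporal operators — extras of
    some BoolNet dialects — are rejected with explicit errors.
    """
    text = source if isinstance(source, str) else source.read()
    names: list[str] = []
    exprs: dict[str, Expr] = {}
    header_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            if not _HEADER_RE.match(line):
                raise FormatError(
                    f"line {lineno}: expected 'targets, factors' header, "
                    f"found {line!r}"
                )
            header_seen = True
            continue
        if "," not in line:
            raise FormatError(
                f"line {lineno}: expected '<target>, <expression>', found {line!r}"
            )
        target, expr_text = line.split(",", 1)
        target = target.strip()
        if not _IDENT_RE.match(target):
            raise FormatError(f"line {lineno}: invalid target name {target!r}")
        if target in exprs:
            raise FormatError(f"line {lineno}: duplicate target {target!r}")
        exprs[target] = parse_expression(expr_text, line=lineno)
        names.append(target)
    if not header_seen:
        raise FormatError("missing 'targets, factors' header")
    if not names:
        raise FormatError("no rule lines found")
    for target, expr in exprs.items():
        undefined = set(expression_variables(expr)) - set(names)
        if undefined:
            raise UnresolvedSymbolError(
                f"rule for {target!r} references undefined node(s) "
                f"{sorted(undefined)}"
            )
    rules = {t: Rule.from_expression(e) for t, e in exprs.items()}
    return BooleanNetwork(tuple(names), rules)


def write_boolnet(net: BooleanNetwork) -> str:
    """Serialize *net* to BoolNet text; ``parse_boolnet`` round-trips it."""
    lines = ["targets, factors"]
    for name in net.nodes:
        lines.append(f"{name}, {net.rules[name].expr}")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# SBML Level 3 qual
# --------------------------------------------------------------------------

_MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _localname(tag) -> str:
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


def _attr(el, name: str, default: str | None = None) -> str | None:
    """Fetch an attribute regardless of namespace prefixing."""
    for key, value in el.attrib.items():
        if key == name or key.endswith("}" + name):
            return value
    return default


def _find_children(el, localname: str):
    return [c for c in el if _localname(c.tag) == localname]


def _find_descendants(el, localname: str):
    return [c for c in el.iter() if _localname(c.tag) == localname]


_BOOL_MATHML_OPS = {"and", "or", "not", "xor", "eq", "neq", "geq", "leq", "gt", "lt"}


def _eval_mathml(el, env: Mapping[str, int]) -> int:
    name = _localname(el.tag)
    if name == "math":
        children = list(el)
        if len(children) != 1:
            raise UnsupportedConstructError("<math> must contain one expression")
        return _eval_mathml(children[0], env)
    if name == "ci":
        ident = (el.text or "").strip()
        if ident not in env:
            raise UnresolvedSymbolError(f"unknown species {ident!r} in rule math")
        return env[ident]
    if name == "cn":
        value = int(float((el.text or "").strip()))
        return value
    if name == "true":
        return 1
    if name == "false":
        return 0
    if name == "apply":
        children = list(el)
        op = _localname(children[0].tag)
        args = children[1:]
        if op not in _BOOL_MATHML_OPS:
            raise UnsupportedConstructError(
                f"MathML operator <{op}> has no Boolean interpretation"
            )
        vals = [_eval_mathml(a, env) for a in args]
        if op == "not":
            if len(vals) != 1:
                raise UnsupportedConstructError("<not> takes one argument")
            return 1 - vals[0]
        if op == "and":
            return int(all(vals))
        if op == "or":
            return int(any(vals))
        if op == "xor":
            return sum(vals) % 2
        if len(vals) != 2:
            raise UnsupportedConstructError(f"<{op}> takes two arguments")
        a, b = vals
        return int(
            {"eq": a == b, "neq": a != b, "geq": a >= b,
             "leq": a <= b, "gt": a > b, "lt": a < b}[op]
        )
    raise UnsupportedConstructError(f"unsupported MathML element <{name}>")


def _mathml_species(el) -> list[str]:
    """Distinct <ci> identifiers in document order."""
    seen: list[str] = []
    for ci in _find_descendants(el, "ci"):
        ident = (ci.text or "").strip()
        if ident and ident not in seen:
            seen.append(ident)
    return seen


def parse_sbml_qual(source: str | bytes | IO) -> BooleanNetwork:
    """Parse an SBML Level 3 ``qual`` document into a Boolean network.

    Every qualitative species must have ``maxLevel`` ≤ 1.  One node is created
    per species (the SBML ``id``, which is unique by schema, is the node
    name).  Each transition's function terms are evaluated exhaustively to a
    truth table; the ``defaultTerm`` supplies the value for input assignments
    not covered by any function term.  Species without a transition become
    constant nodes fixed at their ``initialLevel`` (0 when unset).
    """
    import xml.etree.ElementTree as ET

    if hasattr(source, "read"):
        source = source.read()
    if isinstance(source, bytes):
        text = source.decode("utf-8")
    else:
        text = source
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise FormatError(f"malformed SBML XML: {exc}") from exc

    species_els = _find_descendants(root, "qualitativeSpecies")
    if not species_els:
        raise FormatError("document contains no qualitative species")

    names: list[str] = []
    initial: dict[str, int] = {}
    for sp in species_els:
        sid = _attr(sp, "id")
        if not sid:
            raise FormatError("qualitativeSpecies without an id")
        max_level = _attr(sp, "maxLevel")
        if max_level is not None and int(max_level) > 1:
            raise UnsupportedModelError(
                f"species {sid!r} has maxLevel {max_level}; only Boolean "
                "(two-level) models are supported"
            )
        init = _attr(sp, "initialLevel")
        level = int(init) if init is not None else 0
        if level > 1:
            raise UnsupportedModelError(
                f"species {sid!r} has initialLevel {level} > 1"
            )
        if sid in initial:
            raise FormatError(f"duplicate qualitative species id {sid!r}")
        names.append(sid)
        initial[sid] = level

    rules: dict[str, Rule] = {}
    for tr in _find_descendants(root, "transition"):
        input_order: list[str] = []
        for inp in _find_descendants(tr, "input"):
            ident = _attr(inp, "qualitativeSpecies")
            if ident and ident not in input_order:
                input_order.append(ident)
        outputs = [
            _attr(out, "qualitativeSpecies")
            for out in _find_descendants(tr, "output")
        ]
        outputs = [o for o in outputs if o]
        if not outputs:
            raise FormatError("transition without an output species")

        terms = []  # (math element or None for default, result level)
        default_level: int | None = None
        for ft in _find_descendants(tr, "functionTerm"):
            level = int(_attr(ft, "resultLevel", "0"))
            if level > 1:
                raise UnsupportedModelError(
                    f"functionTerm resultLevel {level} > 1 is not Boolean"
                )
            maths = _find_children(ft, "math")
            if len(maths) != 1:
                raise FormatError("functionTerm must contain exactly one <math>")
            terms.append((maths[0], level))
        for dt in _find_descendants(tr, "defaultTerm"):
            level = int(_attr(dt, "resultLevel", "0"))
            if level > 1:
                raise UnsupportedModelError(
                    f"defaultTerm resultLevel {level} > 1 is not Boolean"
                )
            default_level = level
        if default_level is None:
            default_level = 0

        # inputs: declared listOfInputs order, extended by any species the
        # math mentions but the list omits
        math_species: list[str] = []
        for math_el, _ in terms:
            for ident in _mathml_species(math_el):
                if ident not in math_species:
                    math_species.append(ident)
        inputs = list(input_order)
        for ident in math_species:
            if ident not in inputs:
                inputs.append(ident)
        unknown = [i for i in inputs if i not in initial]
        if unknown:
            raise UnresolvedSymbolError(
                f"transition references undeclared species {unknown}"
            )

        k = len(inputs)
        table = []
        for b in range(2**k):
            env = {name: (b >> j) & 1 for j, name in enumerate(inputs)}
            value = default_level
            for math_el, level in terms:
                if _eval_mathml(math_el, env):
                    value = level
                    break
            table.append(value)
        rule = Rule(tuple(inputs), expression_from_table(inputs, table),
                    tuple(table))
        for out in outputs:
            if out not in initial:
                raise UnresolvedSymbolError(
                    f"transition output {out!r} is not a declared species"
                )
            if out in rules:
                raise FormatError(f"species {out!r} has more than one transition")
            rules[out] = rule

    for name in names:
        if name not in rules:
            rules[name] = Rule((), Const(initial[name]), (initial[name],))
    return BooleanNetwork(tuple(names), rules)
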