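"""Model input/output: text SOP dialect, SBML-qual, and structural checks.

Text dialect
------------
One equation per line, ``TARGET = A & !B | C``; ``&`` (AND) binds tighter
than ``|`` (OR) and ``!`` marks an inhibiting literal.  Parentheses are
accepted on input and normalized to SOP by distribution.  ``#`` starts a
comment; nodes that only ever appear on right-hand sides become input nodes.
The writer canonicalizes clause and literal order so round-trips are stable,
and emits a ``# @nodes:`` header recording node order, which the parser
honors when present (it is the only way an input node referenced by no rule
survives a round-trip).

SBML-qual
---------
Level-3 qualitative models with Boolean (max level 1) species.  Function
terms may use any and/or/not combination of ``eq``/``geq``/``leq``
comparisons against 0/1 (or bare ``ci`` symbols); they are normalized to SOP
on read.  Unknown annotations are ignored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from lxml import etree

from .model import (
    And,
    BooleanNetwork,
    ContradictionError,
    Expr,
    Literal,
    NetworkError,
    Not,
    Or,
    UpdateRule,
    Var,
    _canonical_clause,
    to_sop,
)

__all__ = [
    "ParseError",
    "parse_boolean_equations",
    "write_boolean_equations",
    "read_sbml_qual",
    "write_sbml_qual",
    "ValidationReport",
    "validate_network",
]


class ParseError(NetworkError):
    """Syntax or structural error in a model document, with location."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(
            message if line is None else f"line {line}: {message}"
        )


# ---------------------------------------------------------------------------
# Text dialect
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(?:(?P<op>[&|!()=])|(?P<name>[^\s&|!()=#]+))")


def _tokenize(line: str, lineno: int) -> list[str]:
    tokens, pos = [], 0
    stripped = line.split("#", 1)[0].rstrip()
    while pos < len(stripped):
        m = _TOKEN_RE.match(stripped, pos)
        if m is None:
            raise ParseError(f"unexpected character {stripped[pos]!r}", lineno)
        tokens.append(m.group("op") or m.group("name"))
        pos = m.end()
    return tokens


class _LineParser:
    """Recursive-descent parser for one equation's right-hand side."""

    def __init__(self, tokens: list[str], lineno: int):
        self.tokens = tokens
        self.pos = 0
        self.lineno = lineno

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ParseError("unexpected end of equation", self.lineno)
        self.pos += 1
        return tok

    def parse(self) -> Expr:
        expr = self.parse_or()
        if self.peek() is not None:
            raise ParseError(f"trailing token {self.peek()!r}", self.lineno)
        return expr

    def parse_or(self) -> Expr:
        terms = [self.parse_and()]
        while self.peek() == "|":
            self.take()
            terms.append(self.parse_and())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_and(self) -> Expr:
        factors = [self.parse_factor()]
        while self.peek() == "&":
            self.take()
            factors.append(self.parse_factor())
        # a conjunction written purely of literals is checked as-written so
        # "A & !A" is reported as a contradiction, not silently dropped
        if all(
            isinstance(f, Var) or (isinstance(f, Not) and isinstance(f.operand, Var))
            for f in factors
        ):
            lits = [
                Literal(f.name) if isinstance(f, Var)
                else Literal(f.operand.name, negated=True)
                for f in factors
            ]
            try:
                _canonical_clause(lits)
            except ContradictionError as exc:
                raise ParseError(str(exc), self.lineno) from exc
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def parse_factor(self) -> Expr:
        tok = self.take()
        if tok == "!":
            return Not(self.parse_factor())
        if tok == "(":
            expr = self.parse_or()
            if self.take() != ")":
                raise ParseError("missing closing parenthesis", self.lineno)
            return expr
        if tok in "&|)=":
            raise ParseError(f"unexpected token {tok!r}", self.lineno)
        return Var(tok)


_NODES_DIRECTIVE = re.compile(r"#\s*@nodes:\s*(.*)$")


def parse_boolean_equations(text: str) -> BooleanNetwork:
    """Parse a text SOP document into a validated :class:`BooleanNetwork`.

    Raises :class:`ParseError` with a line number on syntax errors,
    duplicate target definitions, and contradictory clauses.
    """
    rules: dict[str, UpdateRule] = {}
    order: list[str] = []  # first-appearance order of node ids
    declared: list[str] | None = None

    def note(name: str) -> None:
        if name not in seen:
            seen.add(name)
            order.append(name)

    seen: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        directive = _NODES_DIRECTIVE.match(raw.strip())
        if directive:
            declared = directive.group(1).split()
            continue
        tokens = _tokenize(raw, lineno)
        if not tokens:
            continue
        if "=" not in tokens:
            raise ParseError("expected 'TARGET = expression'", lineno)
        eq = tokens.index("=")
        if eq != 1:
            raise ParseError("left-hand side must be a single node", lineno)
        target = tokens[0]
        if target in "&|!()":
            raise ParseError(f"invalid target {target!r}", lineno)
        if target in rules:
            raise ParseError(f"duplicate definition of {target!r}", lineno)
        expr = _LineParser(tokens[eq + 1:], lineno).parse()
        try:
            rule = to_sop(expr, target)
        except NetworkError as exc:
            raise ParseError(str(exc), lineno) from exc
        rules[target] = rule
        note(target)
        for reg in rule.regulators:
            note(reg)

    nodes = tuple(declared) if declared is not None else tuple(order)
    if declared is not None:
        missing = set(order) - set(declared)
        if missing:
            raise ParseError(
                f"@nodes directive omits referenced nodes {sorted(missing)}"
            )
    return BooleanNetwork(nodes=nodes, rules=rules)


def write_boolean_equations(network: BooleanNetwork) -> str:
    """Serialize to the text dialect (canonical clause/literal order)."""
    lines = ["# @nodes: " + " ".join(network.nodes)]
    for node in network.nodes:
        if node in network.rules:
            lines.append(str(network.rules[node]))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# SBML-qual
# ---------------------------------------------------------------------------

_SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
_QUAL_NS = "http://www.sbml.org/sbml/level3/version1/qual/version1"
_MATH_NS = "http://www.w3.org/1998/Math/MathML"
_NSMAP = {None: _SBML_NS, "qual": _QUAL_NS}


def _q(tag: str) -> str:
    return f"{{{_QUAL_NS}}}{tag}"


def _m(tag: str) -> str:
    return f"{{{_MATH_NS}}}{tag}"


def _s(tag: str) -> str:
    return f"{{{_SBML_NS}}}{tag}"


def write_sbml_qual(network: BooleanNetwork) -> str:
    """Serialize a network as an SBML-qual level-3 document (UTF-8 string)."""
    sbml = etree.Element(_s("sbml"), nsmap=_NSMAP)
    sbml.set("level", "3")
    sbml.set("version", "1")
    sbml.set(f"{{{_QUAL_NS}}}required", "true")
    model = etree.SubElement(sbml, _s("model"))
    model.set("id", "qualnet_model")

    comps = etree.SubElement(model, _s("listOfCompartments"))
    comp = etree.SubElement(comps, _s("compartment"))
    comp.set("id", "default")
    comp.set("constant", "true")

    species_list = etree.SubElement(model, _q("listOfQualitativeSpecies"))
    inputs = set(network.inputs)
    for node in network.nodes:
        sp = etree.SubElement(species_list, _q("qualitativeSpecies"))
        sp.set(_q("id"), node)
        sp.set(_q("compartment"), "default")
        sp.set(_q("constant"), "true" if node in inputs else "false")
        sp.set(_q("maxLevel"), "1")

    transitions = etree.SubElement(model, _q("listOfTransitions"))
    for node in network.nodes:
        rule = network.rules.get(node)
        if rule is None:
            continue
        tr = etree.SubElement(transitions, _q("transition"))
        tr.set(_q("id"), f"tr_{node}")
        in_list = etree.SubElement(tr, _q("listOfInputs"))
        signs: dict[str, set[bool]] = {}
        for lit in rule.literals():
            signs.setdefault(lit.node, set()).add(lit.negated)
        for reg in rule.regulators:
            inp = etree.SubElement(in_list, _q("input"))
            inp.set(_q("id"), f"in_{node}_{reg}")
            inp.set(_q("qualitativeSpecies"), reg)
            inp.set(_q("transitionEffect"), "none")
            neg = signs[reg]
            inp.set(
                _q("sign"),
                "dual" if len(neg) == 2
                else ("negative" if True in neg else "positive"),
            )
        out_list = etree.SubElement(tr, _q("listOfOutputs"))
        out = etree.SubElement(out_list, _q("output"))
        out.set(_q("id"), f"out_{node}")
        out.set(_q("qualitativeSpecies"), node)
        out.set(_q("transitionEffect"), "assignmentLevel")
        terms = etree.SubElement(tr, _q("listOfFunctionTerms"))
        default = etree.SubElement(terms, _q("defaultTerm"))
        default.set(_q("resultLevel"), "0")
        fterm = etree.SubElement(terms, _q("functionTerm"))
        fterm.set(_q("resultLevel"), "1")
        math = etree.SubElement(fterm, _m("math"))
        math.append(_rule_to_mathml(rule))

    return etree.tostring(
        sbml, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")


def _literal_to_mathml(lit: Literal) -> etree._Element:
    apply_ = etree.Element(_m("apply"))
    etree.SubElement(apply_, _m("eq"))
    ci = etree.SubElement(apply_, _m("ci"))
    ci.text = f" {lit.node} "
    cn = etree.SubElement(apply_, _m("cn"))
    cn.set("type", "integer")
    cn.text = " 0 " if lit.negated else " 1 "
    return apply_


def _rule_to_mathml(rule: UpdateRule) -> etree._Element:
    def clause_node(clause):
        if len(clause) == 1:
            return _literal_to_mathml(clause[0])
        apply_ = etree.Element(_m("apply"))
        etree.SubElement(apply_, _m("and"))
        for lit in clause:
            apply_.append(_literal_to_mathml(lit))
        return apply_

    if len(rule.clauses) == 1:
        return clause_node(rule.clauses[0])
    apply_ = etree.Element(_m("apply"))
    etree.SubElement(apply_, _m("or"))
    for clause in rule.clauses:
        apply_.append(clause_node(clause))
    return apply_


def _mathml_to_expr(elem: etree._Element) -> Expr:
    tag = etree.QName(elem).localname
    if tag == "math":
        children = [c for c in elem if isinstance(c.tag, str)]
        if len(children) != 1:
            raise ParseError("math element must hold one expression")
        return _mathml_to_expr(children[0])
    if tag == "ci":
        return Var(elem.text.strip())
    if tag != "apply":
        raise ParseError(f"unsupported MathML element <{tag}>")
    children = [c for c in elem if isinstance(c.tag, str)]
    op = etree.QName(children[0]).localname
    args = children[1:]
    if op == "and":
        return And(tuple(_mathml_to_expr(a) for a in args))
    if op == "or":
        return Or(tuple(_mathml_to_expr(a) for a in args))
    if op == "not":
        return Not(_mathml_to_expr(args[0]))
    if op in ("eq", "geq", "leq", "gt", "lt"):
        return _comparison_to_expr(op, args)
    raise ParseError(f"function term operator <{op}> not reducible to SOP")


def _comparison_to_expr(op: str, args: list[etree._Element]) -> Expr:
    if len(args) != 2:
        raise ParseError(f"<{op}> needs two operands")
    name = value = None
    for a in args:
        tag = etree.QName(a).localname
        if tag == "ci":
            name = a.text.strip()
        elif tag == "cn":
            value = int(float(a.text.strip()))
        else:
            raise ParseError(f"unsupported <{op}> operand <{tag}>")
    if name is None or value is None:
        raise ParseError(f"<{op}> must compare a species with a constant")
    if value not in (0, 1):
        raise ParseError(
            f"comparison against level {value}: only Boolean species supported"
        )
    active = {  # does the comparison hold when the species is ON (=1)?
        ("eq", 1): True, ("eq", 0): False,
        ("geq", 1): True, ("geq", 0): None,   # always true
        ("leq", 0): False, ("leq", 1): None,  # always true
        ("gt", 0): True, ("lt", 1): False,
    }.get((op, value))
    if active is None:
        raise ParseError(f"trivial comparison <{op}> against {value}")
    return Var(name) if active else Not(Var(name))


def read_sbml_qual(document: str | bytes) -> BooleanNetwork:
    """Parse an SBML-qual document into a :class:`BooleanNetwork`.

    Raises :class:`ParseError` on malformed XML, multivalued (non-Boolean)
    species, and function terms not reducible to SOP.
    """
    if isinstance(document, str):
        document = document.encode("utf-8")
    try:
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML: {exc}") from exc

    nodes: list[str] = []
    for sp in root.iter(_q("qualitativeSpecies")):
        node = sp.get(_q("id"))
        if node is None:
            raise ParseError("qualitativeSpecies without qual:id")
        max_level = sp.get(_q("maxLevel"))
        if max_level is not None and int(max_level) > 1:
            raise ParseError(
                f"species {node!r} has maxLevel {max_level}: "
                "only Boolean (max level 1) species are supported"
            )
        nodes.append(node)

    rules: dict[str, UpdateRule] = {}
    for tr in root.iter(_q("transition")):
        targets = [
            out.get(_q("qualitativeSpecies"))
            for out in tr.iter(_q("output"))
        ]
        if len(targets) != 1:
            raise ParseError("transition must have exactly one output")
        target = targets[0]
        if target in rules:
            raise ParseError(f"duplicate transition for {target!r}")
        expr = _transition_expr(tr, target)
        rules[target] = to_sop(expr, target)
    return BooleanNetwork(nodes=tuple(nodes), rules=rules)


def _transition_expr(tr: etree._Element, target: str) -> Expr:
    default_level = None
    active_math = None
    for term in tr.iter(_q("defaultTerm")):
        default_level = int(term.get(_q("resultLevel")))
    for term in tr.iter(_q("functionTerm")):
        level = int(term.get(_q("resultLevel")))
        math = term.find(_m("math"))
        if math is None:
            raise ParseError(f"functionTerm for {target!r} without math")
        if level == 1:
            active_math = math
    if default_level != 0 or active_math is None:
        raise ParseError(
            f"transition for {target!r}: expected defaultTerm level 0 and a "
            "functionTerm for level 1"
        )
    return _mathml_to_expr(active_math)


# ---------------------------------------------------------------------------
# Validation report
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Report-only structural findings; an empty report means all clear."""

    unreachable: list[str] = field(default_factory=list)
    dangling: list[str] = field(default_factory=list)
    self_loop_only: list[str] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (self.unreachable or self.dangling or self.self_loop_only)

    def __str__(self) -> str:
        if self.is_empty():
            return "validation: no findings"
        parts = []
        if self.unreachable:
            parts.append(f"unreachable from inputs: {self.unreachable}")
        if self.dangling:
            parts.append(f"dangling references: {self.dangling}")
        if self.self_loop_only:
            parts.append(f"self-loop-only rules: {self.self_loop_only}")
        return "validation: " + "; ".join(parts)


def validate_network(network: BooleanNetwork) -> ValidationReport:
    """Structural sanity report: reachability, dangling refs, self-loops.

    A node is *unreachable* when no directed path from any input node
    reaches it (inputs themselves are trivially reachable).  *Dangling*
    references cannot normally survive :class:`BooleanNetwork` validation
    but are re-checked so externally constructed mappings are covered.
    *Self-loop-only* rules reference no node but their own target.
    """
    node_set = set(network.nodes)
    dangling = sorted(
        {
            reg
            for rule in network.rules.values()
            for reg in rule.regulators
            if reg not in node_set
        }
    )

    succ: dict[str, set[str]] = {n: set() for n in network.nodes}
    for target, rule in network.rules.items():
        for reg in rule.regulators:
            if reg in succ:
                succ[reg].add(target)

    reached = set(network.inputs)
    frontier = list(reached)
    while frontier:
        nxt = []
        for n in frontier:
            for m in succ[n]:
                if m not in reached:
                    reached.add(m)
                    nxt.append(m)
        frontier = nxt
    unreachable = [n for n in network.nodes if n not in reached]

    self_loop_only = [
        target
        for target, rule in network.rules.items()
        if rule.regulators == (target,)
    ]
    return ValidationReport(
        unreachable=unreachable,
        dangling=dangling,
        self_loop_only=sorted(self_loop_only),
    )
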