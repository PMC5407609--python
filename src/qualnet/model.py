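"""Core domain types for signed sum-of-product (SOP) Boolean network models.

A Boolean model consists of N nodes (proteins, complexes, signals).  Each
non-input node carries an update rule in sum-of-product form: an OR over
clauses, each clause an AND over signed literals.  A literal is a regulator
together with its sign — activating (plain) or inhibiting (negated).  Input
nodes are exactly the nodes with no rule: no edge points to them and their
value is set from outside (experimental condition or clamp).

The module also provides a tiny Boolean expression AST (:class:`Expr`) used
by the text and SBML-qual readers; arbitrary and/or/not expressions are
normalized to SOP via negation-normal form and distribution.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Literal",
    "Clause",
    "UpdateRule",
    "BooleanNetwork",
    "NetworkError",
    "ContradictionError",
    "Expr",
    "Var",
    "Not",
    "And",
    "Or",
    "to_sop",
    "rule_truth_table",
    "check_discrete_state",
    "check_continuous_state",
]


class NetworkError(ValueError):
    """Structural problem in a Boolean network or one of its rules."""


class ContradictionError(NetworkError):
    """A clause contains the same regulator with both signs (A AND NOT A)."""


@dataclass(frozen=True, order=True)
class Literal:
    """A signed regulator occurrence inside a clause.

    ``negated=False`` is an activating influence, ``negated=True`` an
    inhibiting one.
    """

    node: str
    negated: bool = False

    def __str__(self) -> str:  # text-dialect rendering
        return ("!" if self.negated else "") + self.node


Clause = tuple[Literal, ...]
"""AND-combined literals; the empty clause is not allowed."""


def _canonical_clause(literals: Iterable[Literal]) -> Clause:
    """Sort and de-duplicate literals; reject contradictory clauses."""
    lits = tuple(sorted(set(literals)))
    if not lits:
        raise NetworkError("empty clause")
    seen: dict[str, bool] = {}
    for lit in lits:
        if seen.get(lit.node, lit.negated) != lit.negated:
            raise ContradictionError(
                f"clause contains {lit.node} with both signs"
            )
        seen[lit.node] = lit.negated
    return lits


@dataclass(frozen=True)
class UpdateRule:
    """SOP update rule: OR over ``clauses`` of AND over signed literals.

    Clause and literal order is canonicalized (lexicographic) so that equal
    rules compare and serialize identically.  Duplicate clauses collapse;
    clause structure is otherwise preserved (no absorption), because the
    clause literals define the influencing set of the target.
    """

    target: str
    clauses: tuple[Clause, ...]

    def __post_init__(self) -> None:
        if not self.clauses:
            raise NetworkError(f"rule for {self.target!r} has no clauses")
        canon = tuple(sorted({_canonical_clause(c) for c in self.clauses}))
        object.__setattr__(self, "clauses", canon)

    @property
    def regulators(self) -> tuple[str, ...]:
        """Sorted influencing set: every node appearing in some literal."""
        return tuple(sorted({lit.node for c in self.clauses for lit in c}))

    def literals(self) -> Iterable[Literal]:
        for clause in self.clauses:
            yield from clause

    def __str__(self) -> str:
        return f"{self.target} = " + " | ".join(
            " & ".join(str(lit) for lit in clause) for clause in self.clauses
        )


@functools.lru_cache(maxsize=4096)
def rule_truth_table(rule: UpdateRule) -> np.ndarray:
    """Truth table of ``rule`` over its sorted regulators.

    Entry ``j`` gives the rule value at the corner whose bit ``i`` (least
    significant first) is the value of ``rule.regulators[i]``.  Cached per
    rule; the table is the workhorse for BooleCube interpolation.
    """
    regs = rule.regulators
    index = {n: i for i, n in enumerate(regs)}
    m = len(regs)
    # corner matrix: (2^m, m) of {0,1}
    corners = (np.arange(2**m)[:, None] >> np.arange(m)[None, :]) & 1
    out = np.zeros(2**m, dtype=bool)
    for clause in rule.clauses:
        term = np.ones(2**m, dtype=bool)
        for lit in clause:
            col = corners[:, index[lit.node]].astype(bool)
            term &= ~col if lit.negated else col
        out |= term
    return out.astype(float)


# ---------------------------------------------------------------------------
# Boolean expression AST and SOP normalization
# ---------------------------------------------------------------------------

class Expr:
    """Base class for Boolean expressions (used by the parsers)."""

    __slots__ = ()


@dataclass(frozen=True)
class Var(Expr):
    name: str


@dataclass(frozen=True)
class Not(Expr):
    operand: Expr


@dataclass(frozen=True)
class And(Expr):
    operands: tuple[Expr, ...]


@dataclass(frozen=True)
class Or(Expr):
    operands: tuple[Expr, ...]


def _nnf(expr: Expr, negate: bool = False) -> Expr:
    """Push negations onto variables (De Morgan)."""
    if isinstance(expr, Var):
        return Not(expr) if negate else expr
    if isinstance(expr, Not):
        return _nnf(expr.operand, not negate)
    if isinstance(expr, And):
        ops = tuple(_nnf(o, negate) for o in expr.operands)
        return Or(ops) if negate else And(ops)
    if isinstance(expr, Or):
        ops = tuple(_nnf(o, negate) for o in expr.operands)
        return And(ops) if negate else Or(ops)
    raise TypeError(f"not a Boolean expression: {expr!r}")


def _distribute(expr: Expr) -> list[list[Literal]]:
    """NNF expression -> list of clauses (lists of literals)."""
    if isinstance(expr, Var):
        return [[Literal(expr.name)]]
    if isinstance(expr, Not):
        assert isinstance(expr.operand, Var)
        return [[Literal(expr.operand.name, negated=True)]]
    if isinstance(expr, Or):
        out: list[list[Literal]] = []
        for op in expr.operands:
            out.extend(_distribute(op))
        return out
    if isinstance(expr, And):
        prod: list[list[Literal]] = [[]]
        for op in expr.operands:
            prod = [a + b for a, b in itertools.product(prod, _distribute(op))]
        return prod
    raise TypeError(f"not a Boolean expression: {expr!r}")


def to_sop(expr: Expr, target: str) -> UpdateRule:
    """Normalize an arbitrary and/or/not expression to an SOP update rule.

    Clauses that are internally contradictory (contain ``x`` and ``NOT x``),
    which can arise from distributing products of sums, are dropped as
    identically false.  A rule whose every clause drops is constant false and
    is rejected — a node that is never active should be an input held at 0.
    """
    raw = _distribute(_nnf(expr))
    clauses: list[Clause] = []
    for lits in raw:
        try:
            clauses.append(_canonical_clause(lits))
        except ContradictionError:
            continue  # identically false conjunct
    if not clauses:
        raise NetworkError(f"rule for {target!r} reduces to constant false")
    return UpdateRule(target, tuple(clauses))


# ---------------------------------------------------------------------------
# Network container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BooleanNetwork:
    """An ordered set of nodes plus one SOP update rule per non-input node.

    ``inputs`` is derived, never stored: a node is an input exactly when it
    has no update rule, i.e. no edge points to it.
    """

    nodes: tuple[str, ...]
    rules: Mapping[str, UpdateRule] = field(default_factory=dict)

    def __post_init__(self) -> None:
        nodes = tuple(self.nodes)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "rules", dict(self.rules))
        if len(set(nodes)) != len(nodes):
            dupes = sorted({n for n in nodes if list(nodes).count(n) > 1})
            raise NetworkError(f"duplicate node identifiers: {dupes}")
        for n in nodes:
            if not n or any(ch.isspace() for ch in n):
                raise NetworkError(f"invalid node identifier: {n!r}")
        node_set = set(nodes)
        for target, rule in self.rules.items():
            if target not in node_set:
                raise NetworkError(f"rule target {target!r} not in node list")
            if rule.target != target:
                raise NetworkError(
                    f"rule keyed {target!r} targets {rule.target!r}"
                )
            missing = set(rule.regulators) - node_set
            if missing:
                raise NetworkError(
                    f"rule for {target!r} references unknown nodes "
                    f"{sorted(missing)}"
                )

    @property
    def inputs(self) -> tuple[str, ...]:
        """Nodes with no update rule, in node order."""
        return tuple(n for n in self.nodes if n not in self.rules)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def rule_for(self, node: str) -> UpdateRule:
        try:
            return self.rules[node]
        except KeyError:
            raise KeyError(f"{node!r} is an input node (no update rule)")

    def __contains__(self, node: str) -> bool:
        return node in set(self.nodes)


# ---------------------------------------------------------------------------
# State helpers
# ---------------------------------------------------------------------------

def check_discrete_state(
    network: BooleanNetwork, state: Mapping[str, int]
) -> dict[str, int]:
    """Validate a {0,1} state covering exactly the network's nodes."""
    return _check_state(network, state, discrete=True)


def check_continuous_state(
    network: BooleanNetwork, state: Mapping[str, float]
) -> dict[str, float]:
    """Validate a [0,1] state covering exactly the network's nodes."""
    return _check_state(network, state, discrete=False)


def _check_state(network, state, *, discrete):
    missing = set(network.nodes) - set(state)
    extra = set(state) - set(network.nodes)
    if missing or extra:
        raise NetworkError(
            f"state/node mismatch: missing {sorted(missing)}, "
            f"extra {sorted(extra)}"
        )
    out = {}
    for n in network.nodes:
        v = state[n]
        if discrete:
            if v not in (0, 1):
                raise NetworkError(f"discrete state of {n!r} is {v!r}")
            out[n] = int(v)
        else:
            if not (0.0 <= float(v) <= 1.0):
                raise NetworkError(f"state of {n!r} = {v!r} outside [0,1]")
            out[n] = float(v)
    return out


def state_vector(
    network: BooleanNetwork, state: Mapping[str, float]
) -> np.ndarray:
    """Dense vector in node order (no validation)."""
    return np.array([state[n] for n in network.nodes], dtype=float)


def state_dict(
    network: BooleanNetwork, vector: Sequence[float]
) -> dict[str, float]:
    return {n: float(v) for n, v in zip(network.nodes, vector, strict=True)}
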