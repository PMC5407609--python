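"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive quantities by the most literal
method available (corner sums, exhaustive DFS, boolean matrix closure) so
the library's optimized paths are checked against something that cannot
share their bugs.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from qualnet.dynamics import evaluate_boolean
from qualnet.model import BooleanNetwork, Literal, UpdateRule
from qualnet.synthetic import toy_tcell_like


@pytest.fixture(scope="session")
def toy_net() -> BooleanNetwork:
    return toy_tcell_like()


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def boolecube_corner_sum(rule: UpdateRule, state: dict[str, float]) -> float:
    """Literal corner-sum definition of the multilinear interpolation:
    Σ_corners B(corner) · Π_i (x_i if corner_i else 1-x_i)."""
    regs = rule.regulators
    total = 0.0
    for corner in itertools.product((0, 1), repeat=len(regs)):
        b = evaluate_boolean(rule, dict(zip(regs, corner)))
        weight = 1.0
        for reg, bit in zip(regs, corner):
            weight *= state[reg] if bit else (1.0 - state[reg])
        total += b * weight
    return total


def brute_force_cycles(graph: nx.DiGraph) -> set[tuple[str, ...]]:
    """Exhaustive DFS enumeration of elementary cycles, rotation-canonical.

    Only practical for small graphs; anchors each cycle at its smallest
    node to avoid double counting rotations.
    """
    cycles: set[tuple[str, ...]] = set()

    def extend(path: list[str]) -> None:
        head = path[0]
        for nxt in graph.successors(path[-1]):
            if nxt == head:
                cycles.add(tuple(path))
            elif nxt not in path and nxt > head:
                extend(path + [nxt])

    for start in graph.nodes:
        extend([start])
    return cycles


def reachability_components(graph: nx.DiGraph) -> set[frozenset[str]]:
    """SCC partition from pairwise reachability (boolean matrix closure)."""
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    reach = np.eye(n, dtype=bool)
    for u, v in graph.edges:
        reach[idx[u], idx[v]] = True
    for k in range(n):  # Floyd–Warshall closure
        reach |= reach[:, k:k + 1] & reach[k:k + 1, :]
    mutual = reach & reach.T
    return {
        frozenset(nodes[j] for j in range(n) if mutual[i, j])
        for i in range(n)
    }


def random_rule(rng: np.random.Generator, n_inputs: int,
                target: str = "T") -> UpdateRule:
    """Random SOP rule over regulators X0..X{n-1}, every regulator used."""
    regs = [f"X{i}" for i in range(n_inputs)]
    clauses = []
    unused = set(regs)
    while unused or not clauses:
        size = int(rng.integers(1, n_inputs + 1))
        chosen = [str(r) for r in rng.choice(regs, size=size, replace=False)]
        if unused and not (set(chosen) & unused):
            chosen.append(sorted(unused)[0])  # force coverage of every reg
        clause = tuple(
            Literal(r, negated=bool(rng.random() < 0.4)) for r in chosen
        )
        clauses.append(clause)
        unused -= {lit.node for lit in clause}
    return UpdateRule(target, tuple(clauses))


def random_digraph(rng: np.random.Generator, n: int, p: float) -> nx.DiGraph:
    """Erdős–Rényi style random digraph with string node names."""
    g = nx.DiGraph()
    names = [f"n{i:02d}" for i in range(n)]
    g.add_nodes_from(names)
    for u in names:
        for v in names:
            if u != v and rng.random() < p:
                g.add_edge(u, v, signs=frozenset(
                    {"-" if rng.random() < 0.3 else "+"}
                ))
    return g
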