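"""Interaction-graph structure: signed edges, SCCs, and feedback loops.

The interaction graph of a Boolean model has one signed edge per
(regulator, target) literal occurrence, with AND structure discarded:
``(u, v, +)`` exists iff ``u`` appears activating in some clause of ``v``'s
rule, ``(u, v, -)`` iff it appears inhibiting.  Duplicate occurrences across
clauses collapse to one edge per sign; a regulator used with both signs
yields a *dual* edge.

Feedback loops (FBLs) are elementary directed cycles of the interaction
graph, enumerated sign-blind after input/output peeling: nodes with no
incoming or no outgoing edges cannot lie on a cycle and are removed, by
default iteratively until a fixpoint (removing an output can expose a new
one).  A node's FBL membership count is a centrality measure: proteins on
many loops are candidates for being dynamically essential.
"""

from __future__ import annotations

import io as _io
import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .model import BooleanNetwork

__all__ = [
    "SIGN_ACTIVATING",
    "SIGN_INHIBITING",
    "to_interaction_graph",
    "strongly_connected_components",
    "scc_summary",
    "FeedbackLoop",
    "trim_inputs_outputs",
    "enumerate_feedback_loops",
    "TooManyCyclesError",
    "fbl_membership",
    "fbl_length_summary",
    "loop_parity",
    "to_sif",
    "to_graphml",
]

SIGN_ACTIVATING = "+"
SIGN_INHIBITING = "-"


def to_interaction_graph(network: BooleanNetwork) -> nx.DiGraph:
    """Signed directed graph of regulator → target influences.

    Returns a :class:`networkx.DiGraph` whose every edge carries a
    ``signs`` attribute, a frozenset drawn from ``{"+", "-"}`` (both present
    for dual regulation).  All model nodes are included, regulators or not.
    """
    g = nx.DiGraph()
    g.add_nodes_from(network.nodes)
    for target, rule in network.rules.items():
        for lit in rule.literals():
            sign = SIGN_INHIBITING if lit.negated else SIGN_ACTIVATING
            if g.has_edge(lit.node, target):
                g[lit.node][target]["signs"] = (
                    g[lit.node][target]["signs"] | {sign}
                )
            else:
                g.add_edge(lit.node, target, signs=frozenset({sign}))
    return g


def strongly_connected_components(graph: nx.DiGraph) -> list[set[str]]:
    """Maximal SCCs, largest first (ties broken by smallest member name)."""
    comps = [set(c) for c in nx.strongly_connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def scc_summary(graph: nx.DiGraph) -> dict:
    """Sizes of all SCCs plus node/edge counts of the largest non-trivial one.

    A component is non-trivial when it has more than one node or carries a
    self-loop.  Returns ``{"components", "largest_nodes", "largest_edges"}``
    with zero counts when the graph has no non-trivial component.
    """
    comps = strongly_connected_components(graph)
    nontrivial = [
        c for c in comps
        if len(c) > 1 or any(graph.has_edge(n, n) for n in c)
    ]
    if not nontrivial:
        return {"components": comps, "largest_nodes": 0, "largest_edges": 0}
    largest = nontrivial[0]
    induced = graph.subgraph(largest)
    return {
        "components": comps,
        "largest_nodes": len(largest),
        "largest_edges": induced.number_of_edges(),
    }


@dataclass(frozen=True)
class FeedbackLoop:
    """Elementary directed cycle in rotation-canonical form.

    ``cycle`` starts at its lexicographically smallest node and lists each
    node once; the closing edge (last → first) is implicit.
    """

    cycle: tuple[str, ...]

    def __post_init__(self) -> None:
        cyc = tuple(self.cycle)
        if len(set(cyc)) != len(cyc):
            raise ValueError(f"cycle repeats a node: {cyc}")
        pivot = cyc.index(min(cyc))
        object.__setattr__(self, "cycle", cyc[pivot:] + cyc[:pivot])

    @property
    def length(self) -> int:
        return len(self.cycle)

    def edges(self) -> list[tuple[str, str]]:
        cyc = self.cycle
        return [(cyc[i], cyc[(i + 1) % len(cyc)]) for i in range(len(cyc))]

    def __contains__(self, node: str) -> bool:
        return node in self.cycle


def trim_inputs_outputs(
    graph: nx.DiGraph, iterative: bool = True
) -> nx.DiGraph:
    """Remove pure-input (in-degree 0) and pure-output (out-degree 0) nodes.

    Such nodes cannot lie on any cycle.  With ``iterative=True`` (default)
    the peeling repeats until a fixpoint, since each removal can expose new
    inputs/outputs; ``iterative=False`` does a single pass, exposed for
    comparison.
    """
    g = graph.copy()
    while True:
        doomed = [
            n for n in g.nodes
            if g.in_degree(n) == 0 or g.out_degree(n) == 0
        ]
        g.remove_nodes_from(doomed)
        if not doomed or not iterative:
            return g


class TooManyCyclesError(RuntimeError):
    """Cycle count exceeded the configured resource cap."""


def enumerate_feedback_loops(
    graph: nx.DiGraph,
    iterative_trim: bool = True,
    max_cycles: int = 10**6,
) -> list[FeedbackLoop]:
    """All elementary directed cycles after input/output peeling.

    Enumeration is sign-blind (Johnson's algorithm via networkx).  Results
    are rotation-canonical and sorted (by length, then lexicographically)
    for deterministic output.  Graphs whose cycle count exceeds
    ``max_cycles`` raise :class:`TooManyCyclesError`.
    """
    core = trim_inputs_outputs(graph, iterative=iterative_trim)
    loops: list[FeedbackLoop] = []
    for cyc in nx.simple_cycles(core):
        loops.append(FeedbackLoop(tuple(cyc)))
        if len(loops) > max_cycles:
            raise TooManyCyclesError(
                f"more than {max_cycles} elementary cycles; raise max_cycles "
                "to proceed"
            )
    loops.sort(key=lambda fl: (fl.length, fl.cycle))
    return loops


def fbl_membership(
    loops: Iterable[FeedbackLoop], nodes: Iterable[str] | None = None
) -> dict[str, int]:
    """Per-node count of loops the node lies on.

    ``nodes`` extends the table with zero-count entries (e.g. the full model
    node list, so loop-free proteins are reported explicitly with 0).
    """
    counts: dict[str, int] = {n: 0 for n in (nodes or [])}
    for loop in loops:
        for node in loop.cycle:
            counts[node] = counts.get(node, 0) + 1
    return counts


def fbl_length_summary(loops: Iterable[FeedbackLoop]) -> dict[str, float]:
    """Min/max/mean/median loop length; raises on an empty loop set."""
    lengths = [fl.length for fl in loops]
    if not lengths:
        raise ValueError("no feedback loops: length summary undefined")
    return {
        "count": len(lengths),
        "min": min(lengths),
        "max": max(lengths),
        "mean": round(statistics.fmean(lengths), 1),
        "median": statistics.median(lengths),
    }


def loop_parity(graph: nx.DiGraph, loop: FeedbackLoop) -> int | None:
    """Sign parity of a loop: +1 (positive), -1 (negative), None if any
    edge is dual-signed (parity undefined)."""
    parity = 1
    for u, v in loop.edges():
        signs = graph[u][v]["signs"]
        if len(signs) > 1:
            return None
        parity *= -1 if SIGN_INHIBITING in signs else 1
    return parity


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def to_sif(graph: nx.DiGraph) -> str:
    """SIF serialization, one ``source<TAB>sign<TAB>target`` line per signed
    edge (dual edges emit two lines)."""
    lines = []
    for u, v, data in sorted(graph.edges(data=True)):
        for sign in sorted(data["signs"]):
            lines.append(f"{u}\t{sign}\t{v}")
    return "\n".join(lines) + ("\n" if lines else "")


def to_graphml(graph: nx.DiGraph) -> str:
    """GraphML serialization with a string ``sign`` edge attribute."""
    g = nx.DiGraph()
    g.add_nodes_from(graph.nodes)
    for u, v, data in graph.edges(data=True):
        g.add_edge(u, v, sign="".join(sorted(data["signs"])))
    buf = _io.BytesIO()
    nx.write_graphml(g, buf)
    return buf.getvalue().decode("utf-8")


def graph_report(network: BooleanNetwork) -> dict:
    """Convenience bundle of the structural numbers for a model."""
    ig = to_interaction_graph(network)
    summary = scc_summary(ig)
    return {
        "nodes": ig.number_of_nodes(),
        "edges": ig.number_of_edges(),
        "inputs": len(network.inputs),
        "scc_largest_nodes": summary["largest_nodes"],
        "scc_largest_edges": summary["largest_edges"],
    }
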