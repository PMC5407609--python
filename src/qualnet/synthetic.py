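"""Synthetic model generation: random signed SOP networks and a toy fixture.

The random generator emulates the structural shape the analysis assumes —
designated input nodes, AND/OR clause structure, signed edges, and an
optional cycle-enriched non-input core — so every pipeline stage can be
exercised without any externally supplied model.  Non-input nodes are wired
in a topological order with regulators drawn from earlier nodes, which
guarantees reachability from the inputs by induction; ``cycle_enrichment``
then adds back-edges within the non-input core only, so inputs stay outside
every feedback loop.

``toy_tcell_like`` is a hand-written ~17-node miniature of a two-signal
receptor cascade: two signal inputs, a five-node negative-feedback ring
that produces a limit cycle, three transcription-factor endpoints of which
the NF-κB-like one needs both signals, and a signalosome hub (LAT) whose
knockout silences all endpoints.  Its qualitative behaviors are provable by
construction, which is why it is written by hand rather than generated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import parse_boolean_equations
from .model import BooleanNetwork, Clause, Literal, UpdateRule

__all__ = [
    "GeneratorConfig",
    "generate_network",
    "toy_tcell_like",
    "TOY_TCELL_EQUATIONS",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Shape parameters for random signed SOP networks.

    Identical seeds produce identical networks (byte-identical once
    serialized).  ``cycle_enrichment`` is the per-node probability of
    wiring one extra back-edge clause inside the non-input core.
    """

    n_nodes: int = 30
    n_inputs: int = 6
    max_clauses_per_rule: int = 2
    max_literals_per_clause: int = 2
    inhibition_probability: float = 0.2
    cycle_enrichment: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_inputs < 1:
            raise ValueError(
                "at least one input node is required for reachability"
            )
        if self.n_inputs >= self.n_nodes:
            raise ValueError("n_inputs must be smaller than n_nodes")
        if self.max_clauses_per_rule < 1 or self.max_literals_per_clause < 1:
            raise ValueError("clause/literal caps must be >= 1")
        for p in (self.inhibition_probability, self.cycle_enrichment):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0,1]")


def _node_names(config: GeneratorConfig) -> tuple[list[str], list[str]]:
    width = len(str(config.n_nodes))
    inputs = [f"IN{i:0{width}d}" for i in range(config.n_inputs)]
    core = [
        f"V{i:0{width}d}"
        for i in range(config.n_nodes - config.n_inputs)
    ]
    return inputs, core


def generate_network(config: GeneratorConfig) -> BooleanNetwork:
    """Random signed SOP network with the configured shape.

    Every non-input node is reachable from some input, rules are in SOP,
    and regeneration from the same config is deterministic.
    """
    rng = np.random.default_rng(config.seed)
    inputs, core = _node_names(config)
    nodes = inputs + core
    rules: dict[str, UpdateRule] = {}

    for j, target in enumerate(core):
        pool = inputs + core[:j]  # earlier nodes only: keeps reachability
        n_clauses = int(rng.integers(1, config.max_clauses_per_rule + 1))
        clauses: list[Clause] = []
        for _ in range(n_clauses):
            size = int(
                rng.integers(
                    1, min(config.max_literals_per_clause, len(pool)) + 1
                )
            )
            regs = rng.choice(len(pool), size=size, replace=False)
            clauses.append(tuple(
                Literal(
                    pool[int(r)],
                    negated=bool(
                        rng.random() < config.inhibition_probability
                    ),
                )
                for r in regs
            ))
        rules[target] = UpdateRule(target, tuple(clauses))

    # back-edges: extra OR clause from a *later* core node, core-only so
    # inputs never join a feedback loop
    for j, target in enumerate(core[:-1]):
        if rng.random() < config.cycle_enrichment:
            source = core[int(rng.integers(j + 1, len(core)))]
            extra = (Literal(
                source,
                negated=bool(rng.random() < config.inhibition_probability),
            ),)
            rules[target] = UpdateRule(
                target, rules[target].clauses + (extra,)
            )

    return BooleanNetwork(nodes=tuple(nodes), rules=rules)


#: Hand-written two-signal toy cascade (text SOP dialect).  Signal 1 models
#: antigen/TCR engagement, signal 2 co-stimulation.  The DAG→RAS→RAF1→
#: MAPK1→DGK⊣DAG ring is a five-node negative feedback loop: with the
#: default Hill steepness its gain exceeds the secant-condition threshold,
#: so the active network settles into a limit cycle.  LAT is the hub: both
#: signal routes converge on it and all three endpoints depend on it.
TOY_TCELL_EQUATIONS = """\
# toy two-signal activation cascade (miniature T-cell architecture)
TCR = S1
LCK = TCR
ZAP70 = LCK
PI3K = S2
ITK = PI3K
LAT = ZAP70 | ITK
PLCG1 = LAT
DAG = PLCG1 & !DGK
RAS = DAG
RAF1 = RAS
MAPK1 = RAF1
DGK = MAPK1
AP1 = MAPK1
NFAT = DAG
NFKB1 = ITK & LAT & ZAP70
"""

#: The fixture's signal inputs, TF endpoints and hub, for tests and demos.
TOY_SIGNALS = ("S1", "S2")
TOY_ENDPOINTS = ("AP1", "NFAT", "NFKB1")
TOY_HUB = "LAT"


def toy_tcell_like() -> BooleanNetwork:
    """The packaged miniature T-cell-like fixture (17 nodes, 2 inputs)."""
    return parse_boolean_equations(TOY_TCELL_EQUATIONS)
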