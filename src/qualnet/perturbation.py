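"""Clamped knockout/knockin perturbation screens.

A perturbation converts one node into an input held at a fixed Boolean
value for the whole simulation: 0 models loss of function (knockout), 1
constitutive activity (knockin/overexpression).  Each perturbed run starts
from the same resting initial condition as the wild type (non-input nodes
at 0, inputs per the signal configuration), settles into its attractor, and
is compared node-by-node against the wild-type attractor.

The impairment call for a condition is: at least one transcription-factor
endpoint (default AP1, NFAT, NFKB1) that is active in the wild-type
attractor is inactive in the perturbed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .attractors import (
    Attractor,
    AttractorComparison,
    DEFAULT_TF_NODES,
    compare_attractors,
    detect_attractor,
)
from .dynamics import SimulationParameters, integrate
from .model import BooleanNetwork, NetworkError

__all__ = [
    "PerturbationSpec",
    "ScreenRow",
    "ScreenResult",
    "run_wild_type",
    "run_perturbation",
    "run_screen",
    "score_dysregulation",
    "PID_PANEL",
]

#: Knockout/knockin panel of the 12 primary-immunodeficiency proteins of the
#: CD4+ T-cell model (PI3K overactivity is the one knockin; all others are
#: loss of function).  Meaningful for models that contain these node names.
PID_PANEL: tuple["PerturbationSpec", ...]


@dataclass(frozen=True)
class PerturbationSpec:
    """One clamp: node, state (0 knockout / 1 knockin), free-text label."""

    node: str
    clamp_state: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.clamp_state not in (0, 1):
            raise ValueError("clamp_state must be 0 or 1")
        if not self.label:
            suffix = "KO" if self.clamp_state == 0 else "KI"
            object.__setattr__(self, "label", f"{self.node}-{suffix}")


PID_PANEL = tuple(
    PerturbationSpec(node, 0)
    for node in (
        "LCK", "ZAP70", "ITK", "IKKB", "NEMO", "CARD11",
        "MALT1", "BCL10", "NFKBIA", "PTPRC", "MAP3K14",
    )
) + (PerturbationSpec("PI3K", 1),)


def _resolve_signals(
    network: BooleanNetwork, signal_config: Mapping[str, int]
) -> dict[str, int]:
    bad = [n for n in signal_config if n not in set(network.nodes)]
    if bad:
        raise NetworkError(f"signal config names unknown nodes {bad}")
    non_inputs = [n for n in signal_config if n in network.rules]
    if non_inputs:
        raise NetworkError(
            f"signal config must address input nodes only, got {non_inputs}"
        )
    signals = {n: 0 for n in network.inputs}
    signals.update({n: int(v) for n, v in signal_config.items()})
    return signals


def _initial_state(
    network: BooleanNetwork,
    signals: Mapping[str, int],
    initial: Mapping[str, float] | None,
) -> dict[str, float]:
    state = {n: 0.0 for n in network.nodes}
    if initial:
        state.update({n: float(v) for n, v in initial.items()})
    state.update({n: float(v) for n, v in signals.items()})
    return state


def run_wild_type(
    network: BooleanNetwork,
    params: SimulationParameters | None = None,
    signal_config: Mapping[str, int] | None = None,
    t_end: float = 200.0,
    initial: Mapping[str, float] | None = None,
    tf_nodes: Sequence[str] = DEFAULT_TF_NODES,
    **detect_kwargs,
) -> Attractor:
    """Attractor of the unperturbed system under the given input signals.

    ``signal_config`` assigns 0/1 to input nodes (unmentioned inputs stay
    0); non-input nodes default to 0 — a resting cell — unless ``initial``
    overrides them.
    """
    signals = _resolve_signals(network, signal_config or {})
    x0 = _initial_state(network, signals, initial)
    traj = integrate(network, params, x0, clamps=None, t_end=t_end)
    return detect_attractor(traj, **detect_kwargs)


def run_perturbation(
    network: BooleanNetwork,
    params: SimulationParameters | None = None,
    signal_config: Mapping[str, int] | None = None,
    spec: PerturbationSpec | None = None,
    reference: Attractor | None = None,
    t_end: float = 200.0,
    initial: Mapping[str, float] | None = None,
    tf_nodes: Sequence[str] = DEFAULT_TF_NODES,
    **detect_kwargs,
) -> tuple[Attractor, AttractorComparison]:
    """Clamp ``spec.node`` to ``spec.clamp_state`` and compare to wild type.

    The clamped node behaves as an input for the whole run.  Clamping a
    node that is configured as a signal is refused — vary the signal
    configuration instead.
    """
    if spec is None:
        raise ValueError("a PerturbationSpec is required")
    signal_config = signal_config or {}
    if spec.node in signal_config:
        raise NetworkError(
            f"{spec.node!r} is a configured signal; set it via "
            "signal_config rather than clamping"
        )
    if spec.node not in set(network.nodes):
        raise NetworkError(f"unknown perturbation node {spec.node!r}")
    if reference is None:
        reference = run_wild_type(
            network, params, signal_config, t_end, initial, tf_nodes,
            **detect_kwargs,
        )
    signals = _resolve_signals(network, signal_config)
    x0 = _initial_state(network, signals, initial)
    traj = integrate(
        network, params, x0,
        clamps={spec.node: spec.clamp_state}, t_end=t_end,
    )
    attractor = detect_attractor(traj, **detect_kwargs)
    comparison = compare_attractors(reference, attractor, tf_nodes)
    return attractor, comparison


@dataclass
class ScreenRow:
    """One screen condition; ``error`` is set when the run failed."""

    spec: PerturbationSpec
    attractor: Attractor | None = None
    comparison: AttractorComparison | None = None
    error: str | None = None

    @property
    def impaired(self) -> bool | None:
        """True when a wild-type-active TF endpoint went inactive."""
        if self.comparison is None:
            return None
        return bool(self.comparison.tf_lost)


@dataclass
class ScreenResult:
    """Wild-type attractor plus one row per perturbation, in spec order."""

    wild_type: Attractor
    rows: list[ScreenRow] = field(default_factory=list)
    tf_nodes: tuple[str, ...] = DEFAULT_TF_NODES

    def to_matrix(self) -> pd.DataFrame:
        """Binary attractor matrix: rows = conditions (wild type first),
        columns = nodes, cells ∈ {0,1}."""
        records = {"wild_type": self.wild_type.profile_vector()}
        for row in self.rows:
            if row.attractor is not None:
                records[row.spec.label] = row.attractor.profile_vector()
        return pd.DataFrame.from_dict(
            records, orient="index", columns=list(self.wild_type.nodes)
        )

    def to_matrix_tsv(self) -> str:
        return self.to_matrix().to_csv(sep="\t", index_label="condition")


def run_screen(
    network: BooleanNetwork,
    params: SimulationParameters | None = None,
    signal_config: Mapping[str, int] | None = None,
    specs: Iterable[PerturbationSpec] = (),
    t_end: float = 200.0,
    initial: Mapping[str, float] | None = None,
    tf_nodes: Sequence[str] = DEFAULT_TF_NODES,
    **detect_kwargs,
) -> ScreenResult:
    """Run the wild type plus every perturbation in ``specs``.

    Per-condition failures (e.g. a trajectory that does not settle) are
    isolated into their row's ``error`` field rather than aborting the
    screen.  Rows keep the order of ``specs``.
    """
    wild_type = run_wild_type(
        network, params, signal_config, t_end, initial, tf_nodes,
        **detect_kwargs,
    )
    result = ScreenResult(wild_type=wild_type, tf_nodes=tuple(tf_nodes))
    for spec in specs:
        row = ScreenRow(spec=spec)
        try:
            row.attractor, row.comparison = run_perturbation(
                network, params, signal_config, spec,
                reference=wild_type, t_end=t_end, initial=initial,
                tf_nodes=tf_nodes, **detect_kwargs,
            )
        except Exception as exc:  # isolate per-spec failures
            row.error = f"{type(exc).__name__}: {exc}"
        result.rows.append(row)
    return result


def score_dysregulation(
    screen: ScreenResult,
    affected_value: int = 0,
) -> pd.DataFrame:
    """Ranked per-perturbation summary of attractor dysregulation.

    Columns: changed-node count and one column per TF endpoint holding
    ``affected_value`` (default 0) when that endpoint's activity differs
    from wild type and ``1 - affected_value`` otherwise, plus the
    impairment call.  Sorted by descending changed count, then label.
    """
    unaffected_value = 1 - affected_value
    records = []
    for row in screen.rows:
        rec: dict = {
            "label": row.spec.label,
            "node": row.spec.node,
            "clamp_state": row.spec.clamp_state,
        }
        if row.error is not None or row.comparison is None:
            rec.update(error=row.error, n_changed=None, impaired=None)
        else:
            rec["n_changed"] = row.comparison.n_changed
            for tf in screen.tf_nodes:
                rec[f"effect_{tf}"] = (
                    affected_value
                    if row.comparison.differs.get(tf, False)
                    else unaffected_value
                )
            rec["impaired"] = row.impaired
            rec["error"] = None
        records.append(rec)
    frame = pd.DataFrame.from_records(records)
    if not frame.empty:
        frame = frame.sort_values(
            ["n_changed", "label"], ascending=[False, True]
        ).reset_index(drop=True)
    return frame
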