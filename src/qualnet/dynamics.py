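"""Discrete and continuous dynamics of Boolean network models.

Discrete mode: synchronous updates ``x_i(t+1) = B_i(x(t))``; the state space
is finite, so every trajectory enters a cycle (period 1 = fixed point).

Continuous mode: each Boolean update function is interpolated multilinearly
over the unit cube (the *BooleCube* B̄ᴵ), made sigmoidal by composing a Hill
function ``f(x) = xⁿ/(xⁿ + kⁿ)`` per regulator (*HillCube*), and normalized
by ``f(1)`` so the continuous rule agrees exactly with the Boolean rule on
every binary corner (*normalized HillCube* B̄ᴴⁿ).  The network then evolves
by

    ẋ_i = (B̄ᴴⁿ_i(x̄ regulators) − x_i) / τ_i

with per-node life time τ.  Input nodes and clamped nodes have zero
derivative: they hold the experimentally imposed value.  Defaults n=3,
k=0.5, τ=1; overrides are resolved per (influenced, influencing) edge,
falling back to node-level (source ``"*"``) and then global defaults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp

from .model import (
    BooleanNetwork,
    NetworkError,
    UpdateRule,
    rule_truth_table,
)

__all__ = [
    "SimulationParameters",
    "DuplicateOverrideWarning",
    "evaluate_boolean",
    "synchronous_step",
    "SyncResult",
    "simulate_boolean",
    "boolecube",
    "hill",
    "hillcube",
    "normalized_hillcube",
    "ContinuousModel",
    "ode_rhs",
    "Trajectory",
    "integrate",
]

DEFAULT_N = 3.0
DEFAULT_K = 0.5
DEFAULT_TAU = 1.0


class DuplicateOverrideWarning(UserWarning):
    """The same override key appears more than once; the later record wins."""


@dataclass(frozen=True)
class SimulationParameters:
    """Hill/decay parameters with edge-level overrides.

    ``hill_overrides`` maps ``(influenced, influencing)`` to ``(n, k)``; the
    influencing slot may be ``"*"`` to cover all regulators of the node.
    ``tau_overrides`` maps influenced node to its life time τ.
    """

    default_n: float = DEFAULT_N
    default_k: float = DEFAULT_K
    default_tau: float = DEFAULT_TAU
    hill_overrides: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict
    )
    tau_overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "hill_overrides", dict(self.hill_overrides))
        object.__setattr__(self, "tau_overrides", dict(self.tau_overrides))
        for n, k in [(self.default_n, self.default_k),
                     *self.hill_overrides.values()]:
            if n <= 0:
                raise ValueError(f"Hill exponent n={n} must be positive")
            if not (0.0 < k < 1.0):
                raise ValueError(f"threshold k={k} must lie in (0,1)")
        for tau in (self.default_tau, *self.tau_overrides.values()):
            if tau <= 0:
                raise ValueError(f"life time tau={tau} must be positive")

    def resolve_hill(self, target: str, source: str) -> tuple[float, float]:
        """(n, k) for the edge source → target: edge, node-level, default."""
        for key in ((target, source), (target, "*")):
            if key in self.hill_overrides:
                return self.hill_overrides[key]
        return (self.default_n, self.default_k)

    def resolve_tau(self, target: str) -> float:
        return self.tau_overrides.get(target, self.default_tau)

    @classmethod
    def from_records(
        cls,
        records: Iterable[Mapping],
        default_n: float = DEFAULT_N,
        default_k: float = DEFAULT_K,
        default_tau: float = DEFAULT_TAU,
    ) -> "SimulationParameters":
        """Build from override records ``{target, source|"*", n?, k?, tau?}``.

        Records apply in order; a repeated (target, source) key is flagged
        with :class:`DuplicateOverrideWarning` and the later record wins.
        """
        hill: dict[tuple[str, str], tuple[float, float]] = {}
        tau: dict[str, float] = {}
        seen: set[tuple[str, str]] = set()
        for rec in records:
            target = rec["target"]
            source = rec.get("source", "*") or "*"
            key = (target, source)
            if key in seen:
                warnings.warn(
                    f"duplicate parameter override for {key}; later record "
                    "wins",
                    DuplicateOverrideWarning,
                    stacklevel=2,
                )
            seen.add(key)
            if "n" in rec or "k" in rec:
                hill[key] = (
                    float(rec.get("n", default_n)),
                    float(rec.get("k", default_k)),
                )
            if "tau" in rec:
                tau[target] = float(rec["tau"])
        return cls(default_n, default_k, default_tau, hill, tau)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationParameters":
        """Parse the parameter-file format (``defaults`` + ``overrides``)."""
        doc = yaml.safe_load(text) or {}
        defaults = doc.get("defaults", {})
        return cls.from_records(
            doc.get("overrides", []) or [],
            default_n=float(defaults.get("n", DEFAULT_N)),
            default_k=float(defaults.get("k", DEFAULT_K)),
            default_tau=float(defaults.get("tau", DEFAULT_TAU)),
        )

    def to_yaml(self) -> str:
        overrides = []
        keys = sorted(
            set(self.hill_overrides) | {(t, "*") for t in self.tau_overrides}
        )
        for target, source in keys:
            rec: dict = {"target": target, "source": source}
            if (target, source) in self.hill_overrides:
                n, k = self.hill_overrides[(target, source)]
                rec.update(n=n, k=k)
            if source == "*" and target in self.tau_overrides:
                rec["tau"] = self.tau_overrides[target]
            overrides.append(rec)
        return yaml.safe_dump(
            {
                "defaults": {
                    "n": self.default_n,
                    "k": self.default_k,
                    "tau": self.default_tau,
                },
                "overrides": overrides,
            },
            sort_keys=False,
        )


# ---------------------------------------------------------------------------
# Discrete dynamics
# ---------------------------------------------------------------------------

def evaluate_boolean(rule: UpdateRule, state: Mapping[str, int]) -> int:
    """OR over clauses of AND over literals (inhibiting literals negated)."""
    for clause in rule.clauses:
        ok = True
        for lit in clause:
            try:
                v = state[lit.node]
            except KeyError:
                raise KeyError(
                    f"state lacks regulator {lit.node!r} of {rule.target!r}"
                ) from None
            if bool(v) == lit.negated:
                ok = False
                break
        if ok:
            return 1
    return 0


def synchronous_step(
    network: BooleanNetwork,
    state: Mapping[str, int],
    clamps: Mapping[str, int] | None = None,
) -> dict[str, int]:
    """One all-node simultaneous update; inputs and clamped nodes are held."""
    clamps = clamps or {}
    new = {}
    for node in network.nodes:
        if node in clamps:
            new[node] = int(clamps[node])
        elif node in network.rules:
            new[node] = evaluate_boolean(network.rules[node], state)
        else:
            new[node] = int(state[node])
    return new


@dataclass
class SyncResult:
    """Synchronous trajectory up to the first revisited state.

    ``states[cycle_start:]`` is the attractor cycle (its period is
    ``len(states) - cycle_start``; period 1 means a fixed point);
    ``states[:cycle_start]`` is the transient.
    """

    states: list[dict[str, int]]
    cycle_start: int

    @property
    def period(self) -> int:
        return len(self.states) - self.cycle_start

    @property
    def cycle(self) -> list[dict[str, int]]:
        return self.states[self.cycle_start:]


def simulate_boolean(
    network: BooleanNetwork,
    initial: Mapping[str, int],
    clamps: Mapping[str, int] | None = None,
    max_steps: int | None = None,
) -> SyncResult:
    """Iterate synchronous updates until a state repeats.

    ``max_steps`` defaults to 2^(free nodes) + 1, which guarantees a revisit
    for a finite deterministic map; exceeding a user-supplied smaller budget
    raises.
    """
    clamps = clamps or {}
    state = {n: int(initial[n]) for n in network.nodes}
    state.update({n: int(v) for n, v in clamps.items()})
    free = len(network.rules.keys() - clamps.keys())
    if max_steps is None:
        max_steps = 2**min(free, 30) + 1
    seen: dict[tuple[int, ...], int] = {}
    states: list[dict[str, int]] = []
    for step in range(max_steps + 1):
        key = tuple(state[n] for n in network.nodes)
        if key in seen:
            return SyncResult(states=states, cycle_start=seen[key])
        seen[key] = step
        states.append(state)
        state = synchronous_step(network, state, clamps)
    raise RuntimeError(
        f"no revisited state within {max_steps} steps; increase max_steps"
    )


# ---------------------------------------------------------------------------
# Continuous transforms
# ---------------------------------------------------------------------------

def _fold_truth_table(table: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Multilinear interpolation by successive reduction over variables.

    ``table`` has length 2^m (bit i of the index = value of variable i);
    ``values`` has shape (..., m).  Returns shape (...,).
    """
    m = int(values.shape[-1])
    t = np.broadcast_to(table, values.shape[:-1] + table.shape).copy()
    for i in reversed(range(m)):
        half = t.shape[-1] // 2
        lo, hi = t[..., :half], t[..., half:]
        x = values[..., i:i + 1]
        t = lo * (1.0 - x) + hi * x
    return t[..., 0]


def boolecube(rule: UpdateRule, state: Mapping[str, float]) -> float:
    """Multilinear interpolation B̄ᴵ of the rule at a continuous state.

    Exactly reproduces the discrete rule on binary corners and is affine in
    each coordinate with the others fixed.
    """
    values = np.array([state[n] for n in rule.regulators], dtype=float)
    if np.any(values < 0) or np.any(values > 1):
        raise NetworkError("BooleCube input outside [0,1]")
    return float(_fold_truth_table(rule_truth_table(rule), values))


def hill(x, n: float, k: float):
    """Hill sigmoid ``xⁿ/(xⁿ+kⁿ)``: monotone on [0,1], f(0)=0, f(k)=1/2."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise NetworkError("Hill input outside [0,1]")
    if n <= 0 or not (0 < k < 1):
        raise NetworkError(f"invalid Hill parameters n={n}, k={k}")
    xn = x**n
    out = xn / (xn + k**n)
    return float(out) if out.ndim == 0 else out


def _transformed_state(
    rule: UpdateRule,
    state: Mapping[str, float],
    params: SimulationParameters,
    normalized: bool,
) -> np.ndarray:
    vals = []
    for reg in rule.regulators:
        n, k = params.resolve_hill(rule.target, reg)
        f = hill(state[reg], n, k)
        if normalized:
            f = f / hill(1.0, n, k)
        vals.append(f)
    return np.array(vals, dtype=float)


def hillcube(
    rule: UpdateRule,
    state: Mapping[str, float],
    params: SimulationParameters | None = None,
) -> float:
    """B̄ᴴ: BooleCube composed with per-regulator Hill transforms."""
    params = params or SimulationParameters()
    vals = _transformed_state(rule, state, params, normalized=False)
    return float(_fold_truth_table(rule_truth_table(rule), vals))


def normalized_hillcube(
    rule: UpdateRule,
    state: Mapping[str, float],
    params: SimulationParameters | None = None,
) -> float:
    """B̄ᴴⁿ: Hill transforms divided by f(1), a perfect homologue of the
    Boolean rule (equal to it on every binary corner)."""
    params = params or SimulationParameters()
    vals = _transformed_state(rule, state, params, normalized=True)
    return float(_fold_truth_table(rule_truth_table(rule), vals))


# ---------------------------------------------------------------------------
# ODE system
# ---------------------------------------------------------------------------

class ContinuousModel:
    """Compiled normalized-HillCube ODE right-hand side for one network.

    Precomputes, per rule-bearing unclamped node, the truth table, regulator
    indices and normalized Hill parameters, so :meth:`rhs` is a tight numpy
    loop suitable for :func:`scipy.integrate.solve_ivp`.
    """

    def __init__(
        self,
        network: BooleanNetwork,
        params: SimulationParameters | None = None,
        clamps: Mapping[str, int] | None = None,
    ):
        params = params or SimulationParameters()
        clamps = dict(clamps or {})
        unknown = set(clamps) - set(network.nodes)
        if unknown:
            raise NetworkError(f"clamp on unknown nodes {sorted(unknown)}")
        self.network = network
        self.params = params
        self.clamps = clamps
        self.index = {n: i for i, n in enumerate(network.nodes)}
        self._compiled = []
        for node in network.nodes:
            if node in clamps or node not in network.rules:
                continue
            rule = network.rules[node]
            regs = rule.regulators
            nk = np.array(
                [params.resolve_hill(node, r) for r in regs], dtype=float
            )
            n_arr, k_arr = nk[:, 0], nk[:, 1]
            norm = 1.0 / (1.0 / (1.0 + k_arr**n_arr))  # = 1/f(1)
            self._compiled.append((
                self.index[node],
                rule_truth_table(rule),
                np.array([self.index[r] for r in regs], dtype=int),
                n_arr,
                k_arr,
                norm,
                params.resolve_tau(node),
            ))

    def drive(self, x: np.ndarray) -> np.ndarray:
        """Normalized HillCube drive B̄ᴴⁿ_i per node (held nodes: own value)."""
        x = np.clip(x, 0.0, 1.0)
        b = x.copy()  # inputs/clamped: drive equals value -> zero derivative
        for i, table, regs, n_arr, k_arr, norm, _tau in self._compiled:
            xr = x[regs]
            xn = xr**n_arr
            f = (xn / (xn + k_arr**n_arr)) * norm
            b[i] = _fold_truth_table(table, f)
        return b

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        """ẋ_i = (B̄ᴴⁿ_i − x_i)/τ_i; zero for inputs and clamped nodes."""
        dx = np.zeros_like(x)
        xc = np.clip(x, 0.0, 1.0)
        for i, table, regs, n_arr, k_arr, norm, tau in self._compiled:
            xr = xc[regs]
            xn = xr**n_arr
            f = (xn / (xn + k_arr**n_arr)) * norm
            dx[i] = (_fold_truth_table(table, f) - x[i]) / tau
        return dx

    def initial_vector(self, initial: Mapping[str, float]) -> np.ndarray:
        state = {n: float(initial[n]) for n in self.network.nodes}
        state.update({n: float(v) for n, v in self.clamps.items()})
        x0 = np.array([state[n] for n in self.network.nodes], dtype=float)
        if np.any(x0 < 0) or np.any(x0 > 1):
            raise NetworkError("initial state outside [0,1]")
        return x0


def ode_rhs(
    network: BooleanNetwork,
    params: SimulationParameters | None,
    clamps: Mapping[str, int] | None,
    state: Mapping[str, float],
) -> dict[str, float]:
    """Derivative vector at one state (dict-in/dict-out convenience)."""
    model = ContinuousModel(network, params, clamps)
    x = np.array([state[n] for n in network.nodes], dtype=float)
    dx = model.rhs(0.0, x)
    return {n: float(dx[i]) for n, i in model.index.items()}


@dataclass
class Trajectory:
    """Continuous time course: ``values[t, i]`` is node i at ``times[t]``."""

    times: np.ndarray
    values: np.ndarray
    nodes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.times), len(self.nodes)):
            raise ValueError("trajectory shape mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def column(self, node: str) -> np.ndarray:
        return self.values[:, self.nodes.index(node)]

    def state_at(self, index: int) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.nodes, self.values[index])}

    def final_state(self) -> dict[str, float]:
        return self.state_at(-1)

    def to_tsv(self) -> str:
        header = "time\t" + "\t".join(self.nodes)
        rows = [
            f"{t:.6g}\t" + "\t".join(f"{v:.6g}" for v in row)
            for t, row in zip(self.times, self.values)
        ]
        return "\n".join([header, *rows]) + "\n"


class IntegrationError(RuntimeError):
    """The ODE solver failed; carries the solver diagnostic."""


_OVERSHOOT_TOL = 1e-6


def integrate(
    network: BooleanNetwork,
    params: SimulationParameters | None = None,
    initial: Mapping[str, float] | None = None,
    clamps: Mapping[str, int] | None = None,
    t_end: float = 200.0,
    grid_dt: float = 0.25,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> Trajectory:
    """Integrate the normalized-HillCube ODE system on a dense output grid.

    Adaptive explicit Runge–Kutta (RK45), tolerances tight enough that
    the dense-output interpolant stays within 1e-6 of the unit cube.  The unit cube is forward
    invariant for the exact flow; numerical overshoot beyond
    ``1e-6`` outside [0,1] is an error, smaller overshoot is clipped.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if initial is None:
        initial = {n: 0.0 for n in network.nodes}
    model = ContinuousModel(network, params, clamps)
    x0 = model.initial_vector(initial)
    t_eval = np.arange(0.0, t_end + grid_dt / 2, grid_dt)
    sol = solve_ivp(
        model.rhs, (0.0, float(t_end)), x0,
        method="RK45", t_eval=t_eval, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"integrator failed: {sol.message}")
    values = sol.y.T
    overshoot = max(
        float(np.max(values) - 1.0), float(-np.min(values)), 0.0
    )
    if overshoot > _OVERSHOOT_TOL:
        raise IntegrationError(
            f"trajectory left [0,1] by {overshoot:.2e} (> {_OVERSHOOT_TOL})"
        )
    return Trajectory(
        times=sol.t, values=np.clip(values, 0.0, 1.0), nodes=network.nodes
    )
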