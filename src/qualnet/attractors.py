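"""Attractor detection from continuous trajectories, and comparison.

The long-run behavior of the normalized-HillCube ODE system is either a
stable fixed point or a limit cycle.  Detection works on the post-transient
part of a densely sampled trajectory (default: its last half):

* fixed point — the finite-difference derivative over the trailing window
  stays below a tolerance;
* limit cycle — the mean-centered multivariate autocorrelation of the tail
  has a dominant positive-lag peak (parabolic sub-grid refinement), and the
  tail actually recurs with that period within a recurrence tolerance.

Attractors are reported as binary activity profiles: by default a node is
"on" when its maximum over the attractor exceeds 0.5, so a node oscillating
through high values counts as biologically active; mean-over-cycle
binarization is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from scipy.interpolate import CubicSpline
from scipy.optimize import minimize_scalar

from .dynamics import Trajectory

__all__ = [
    "Attractor",
    "AttractorComparison",
    "NotSettledError",
    "detect_attractor",
    "binarize",
    "compare_attractors",
    "DEFAULT_TF_NODES",
]

DEFAULT_TF_NODES = ("AP1", "NFAT", "NFKB1")

FP_TOL = 1e-4       # max-norm finite-difference derivative, fixed points
CYCLE_TOL = 1e-3    # max-norm recurrence distance, limit cycles


class NotSettledError(RuntimeError):
    """Trajectory shows neither a fixed point nor a recurring cycle;
    the caller should extend the simulation horizon."""


@dataclass
class Attractor:
    """Terminal behavior of a trajectory.

    ``period`` is in trajectory time units and 0.0 for a fixed point.
    ``segment``/``segment_times`` hold one representative stretch of the
    attractor (a single state for a fixed point, ~one period for a cycle);
    ``binary_profile`` is the thresholded per-node activity call.
    """

    kind: str  # "fixed_point" | "limit_cycle"
    period: float
    nodes: tuple[str, ...]
    segment: np.ndarray
    segment_times: np.ndarray
    binary_profile: dict[str, int]

    @property
    def is_fixed_point(self) -> bool:
        return self.kind == "fixed_point"

    def snapshot(self) -> dict[str, float]:
        """Representative continuous state (last state of the segment)."""
        return {n: float(v) for n, v in zip(self.nodes, self.segment[-1])}

    def profile_vector(self) -> tuple[int, ...]:
        return tuple(self.binary_profile[n] for n in self.nodes)


def binarize(
    values: np.ndarray,
    nodes: Sequence[str],
    threshold: float = 0.5,
    method: str = "max",
) -> dict[str, int]:
    """Per-node activity bits over attractor states (rows = time points).

    ``method="max"`` (default) calls a node active when its maximum over the
    attractor exceeds the threshold — an oscillating node is "on".
    ``method="mean"`` uses the time average instead.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if method == "max":
        stat = values.max(axis=0)
    elif method == "mean":
        stat = values.mean(axis=0)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return {
        n: int(s > threshold) for n, s in zip(nodes, stat, strict=True)
    }


def _autocorrelation_period(
    tail: np.ndarray, dt: float
) -> float | None:
    """Dominant period of a multivariate signal via summed autocorrelation.

    Returns None when no positive-lag peak stands out (aperiodic/constant).
    Sub-grid resolution comes from parabolic interpolation around the peak.
    """
    centered = tail - tail.mean(axis=0, keepdims=True)
    t_len = centered.shape[0]
    # summed per-node autocorrelation via FFT
    size = 2 ** int(np.ceil(np.log2(2 * t_len)))
    spec = np.fft.rfft(centered, n=size, axis=0)
    ac = np.fft.irfft((spec * np.conj(spec)).real, n=size, axis=0)[:t_len]
    ac = ac.sum(axis=1)
    if ac[0] <= 0:
        return None
    ac = ac / ac[0]
    # first local maximum after the first zero-ish dip, above 0.2
    lag = 1
    while lag < t_len - 1 and not (
        ac[lag] > ac[lag - 1] and ac[lag] >= ac[lag + 1] and ac[lag] > 0.2
    ):
        lag += 1
    if lag >= t_len - 1:
        return None
    y0, y1, y2 = ac[lag - 1], ac[lag], ac[lag + 1]
    denom = y0 - 2 * y1 + y2
    offset = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    return (lag + float(np.clip(offset, -0.5, 0.5))) * dt


def detect_attractor(
    trajectory: Trajectory,
    settle_fraction: float = 0.5,
    fp_tol: float = FP_TOL,
    cycle_tol: float = CYCLE_TOL,
    threshold: float = 0.5,
    binarization: str = "max",
) -> Attractor:
    """Classify the terminal behavior of a trajectory.

    The first ``1 - settle_fraction`` of the trajectory is discarded as
    transient.  Raises :class:`NotSettledError` when the tail neither
    freezes (fixed point) nor recurs (limit cycle).
    """
    if not 0 < settle_fraction <= 1:
        raise ValueError("settle_fraction must be in (0, 1]")
    times, values = trajectory.times, trajectory.values
    if len(times) < 8:
        raise ValueError("trajectory too short for attractor detection")
    start = int(round(len(times) * (1 - settle_fraction)))
    tail_t, tail = times[start:], values[start:]
    dt = float(np.median(np.diff(tail_t)))

    # fixed point: finite-difference derivative over the trailing window
    window = max(2, len(tail) // 10)
    diffs = np.abs(np.diff(tail[-window:], axis=0)) / dt
    if diffs.size and diffs.max() < fp_tol:
        final = tail[-1:]
        return Attractor(
            kind="fixed_point",
            period=0.0,
            nodes=trajectory.nodes,
            segment=final,
            segment_times=tail_t[-1:],
            binary_profile=binarize(
                final, trajectory.nodes, threshold, binarization
            ),
        )

    period = _autocorrelation_period(tail, dt)
    if period is not None and 0 < period < (tail_t[-1] - tail_t[0]) / 2:
        # recurrence refinement: minimize the max-norm distance between the
        # tail and its period-shifted (spline-interpolated) copy, so periods
        # that are not multiples of the sampling step are handled exactly
        spline = CubicSpline(tail_t, tail, axis=0)
        t_hi = tail_t[-1]

        def recurrence(p: float) -> float:
            window = np.linspace(t_hi - p, t_hi, max(int(p / dt) + 1, 8))
            return float(np.max(np.abs(spline(window) - spline(window - p))))

        res = minimize_scalar(
            recurrence,
            bounds=(0.8 * period, min(1.2 * period, (t_hi - tail_t[0]) / 2)),
            method="bounded",
            options={"xatol": 1e-6 * period},
        )
        period = float(res.x)
        if recurrence(period) < cycle_tol:
            steps = max(int(round(period / dt)), 1)
            segment = tail[-(steps + 1):]
            return Attractor(
                kind="limit_cycle",
                period=period,
                nodes=trajectory.nodes,
                segment=segment,
                segment_times=tail_t[-(steps + 1):],
                binary_profile=binarize(
                    segment, trajectory.nodes, threshold, binarization
                ),
            )
    raise NotSettledError(
        "trajectory neither settles to a fixed point nor recurs as a limit "
        "cycle; extend t_end"
    )


@dataclass
class AttractorComparison:
    """Per-node differences between a reference and a test attractor."""

    nodes: tuple[str, ...]
    differs: dict[str, bool]
    tf_nodes: tuple[str, ...] = DEFAULT_TF_NODES
    reference_profile: dict[str, int] = field(default_factory=dict)
    test_profile: dict[str, int] = field(default_factory=dict)

    @property
    def changed_nodes(self) -> list[str]:
        return [n for n in self.nodes if self.differs[n]]

    @property
    def n_changed(self) -> int:
        return len(self.changed_nodes)

    @property
    def tf_affected(self) -> list[str]:
        """TF endpoints whose activity differs from the reference."""
        return [n for n in self.tf_nodes if self.differs.get(n, False)]

    @property
    def tf_lost(self) -> list[str]:
        """TF endpoints active in the reference but inactive in the test —
        the impairment criterion for an activation screen."""
        return [
            n for n in self.tf_nodes
            if self.reference_profile.get(n) == 1
            and self.test_profile.get(n) == 0
        ]

    @property
    def identical(self) -> bool:
        return self.n_changed == 0


def compare_attractors(
    reference: Attractor,
    test: Attractor,
    tf_nodes: Sequence[str] = DEFAULT_TF_NODES,
) -> AttractorComparison:
    """Element-wise XOR of binary profiles plus TF-endpoint summary."""
    if set(reference.nodes) != set(test.nodes):
        raise ValueError("attractors cover different node sets")
    differs = {
        n: reference.binary_profile[n] != test.binary_profile[n]
        for n in reference.nodes
    }
    return AttractorComparison(
        nodes=reference.nodes,
        differs=differs,
        tf_nodes=tuple(tf_nodes),
        reference_profile=dict(reference.binary_profile),
        test_profile=dict(test.binary_profile),
    )
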