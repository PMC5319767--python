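"""Min-max sequence optimization by annealed Nelder-Mead simplex search.

The design problem: choose the 8 free TSI parameters — inversion times t2,
t4, the second and third imaging-pulse times t3, t5, the imaging flip
angles a1, a3, a5 and the repetition time TR (the first imaging pulse is
pinned at t = 0 and inversions at 180°) — to minimize the worst-case
relative error max over a T1 range of sqrt(CRB(T1))/T1, subject to

    TR <= 6000 ms,   inter-pulse gaps >= 100 ms (EPI readout time),
    TR - t5 >= 100 ms,   imaging flips in [0, 90] deg.

Constraint violations add a prohibitive penalty of 1e3 to the cost rather
than being rejected, so the simplex can traverse infeasible territory.

The search is the classic hybrid of Nelder-Mead downhill simplex with
simulated annealing: vertex comparisons use costs perturbed by T*log(p)
(p uniform on [0,1]), which conditionally accepts uphill moves while the
temperature is high; the temperature and the simplex scale shrink
geometrically (factors 0.985 and 0.998 per outer iteration, initial
temperature 0.8, initial simplex 100 ms in times / 30 deg in angles), and
each outer iteration reseeds the simplex around the incumbent best vertex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .crb import relative_error_curve
from .sequence_model import (
    PulseEvent,
    PulseKind,
    PulseSequence,
    SequenceError,
)

__all__ = [
    "DesignVector",
    "AnnealState",
    "OptimizerConfig",
    "OptimizationResult",
    "OptimizationFailure",
    "PENALTY_DEFAULT",
    "minmax_cost",
    "anneal_step",
    "perturbed_cost",
    "optimize_sequence",
]

PENALTY_DEFAULT = 1e3
MIN_GAP_MS = 100.0
MAX_TR_MS = 6000.0

#: field order of the flattened design vector
_FIELDS = ("t2_ms", "t3_ms", "t4_ms", "t5_ms", "a1_deg", "a3_deg", "a5_deg", "tr_ms")
_TIME_LIKE = (True, True, True, True, False, False, False, True)


@dataclass(frozen=True)
class DesignVector:
    """The 8 free TSI parameters (times in ms, angles in degrees)."""

    t2_ms: float
    t3_ms: float
    t4_ms: float
    t5_ms: float
    a1_deg: float
    a3_deg: float
    a5_deg: float
    tr_ms: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in _FIELDS], dtype=float)

    @staticmethod
    def from_array(x: np.ndarray) -> "DesignVector":
        return DesignVector(**dict(zip(_FIELDS, (float(v) for v in x))))

    @staticmethod
    def from_sequence(seq: PulseSequence) -> "DesignVector":
        if len(seq.events) != 5:
            raise SequenceError("a TSI design vector describes a 5-pulse train")
        t = [ev.time_ms for ev in seq.events]
        a = [ev.flip_angle_deg for ev in seq.events]
        return DesignVector(t[1], t[2], t[3], t[4], a[0], a[2], a[4], seq.tr_ms)

    def constraint_violation(self) -> float:
        """Total feasibility violation, ms-and-degree scaled; 0 if feasible."""
        times = (0.0, self.t2_ms, self.t3_ms, self.t4_ms, self.t5_ms)
        v = max(0.0, self.tr_ms - MAX_TR_MS)
        for a, b in zip(times, times[1:]):
            v += max(0.0, MIN_GAP_MS - (b - a))
        v += max(0.0, MIN_GAP_MS - (self.tr_ms - self.t5_ms))
        for ang in (self.a1_deg, self.a3_deg, self.a5_deg):
            v += max(0.0, -ang) + max(0.0, ang - 90.0)
        return v

    def is_feasible(self) -> bool:
        return self.constraint_violation() == 0.0

    def to_sequence(self) -> PulseSequence:
        """Build the 5-pulse train; raises SequenceError if structurally invalid."""
        return PulseSequence(
            tr_ms=self.tr_ms,
            events=(
                PulseEvent(0.0, self.a1_deg, PulseKind.IMAGING),
                PulseEvent(self.t2_ms, 180.0, PulseKind.INVERSION),
                PulseEvent(self.t3_ms, self.a3_deg, PulseKind.IMAGING),
                PulseEvent(self.t4_ms, 180.0, PulseKind.INVERSION),
                PulseEvent(self.t5_ms, self.a5_deg, PulseKind.IMAGING),
            ),
        )


@dataclass(frozen=True)
class AnnealState:
    """Annealing bookkeeping: temperature, simplex scales, iteration count."""

    temperature: float
    simplex_scale_ms: float
    simplex_scale_deg: float
    outer_iteration: int = 0
    rng_seed: int = 0


def anneal_step(
    state: AnnealState, cooling_t: float = 0.985, cooling_d: float = 0.998
) -> AnnealState:
    """One cooling step: T *= cooling_t, simplex scales *= cooling_d."""
    return replace(
        state,
        temperature=state.temperature * cooling_t,
        simplex_scale_ms=state.simplex_scale_ms * cooling_d,
        simplex_scale_deg=state.simplex_scale_deg * cooling_d,
        outer_iteration=state.outer_iteration + 1,
    )


def perturbed_cost(raw_cost: float, temperature: float, rng: np.random.Generator) -> float:
    """Thermally perturbed cost ``raw + T*log(p)``, p ~ U(0,1).

    log(p) <= 0, so perturbation only lowers the apparent cost; comparing
    independently perturbed costs yields the conditional uphill acceptance
    of simulated annealing.  At T = 0 the raw cost is returned unchanged.
    """
    if temperature < 0:
        raise ValueError(f"temperature must be >= 0, got {temperature}")
    if temperature == 0.0:
        return raw_cost
    return raw_cost + temperature * math.log(rng.random())


@dataclass(frozen=True)
class OptimizerConfig:
    """Min-max design problem plus annealing schedule.

    Defaults follow the published schedule: initial temperature 0.8 cooled
    by 0.985 per outer iteration, simplex scales 100 ms / 30 deg shrunk by
    0.998, 2000 simplex iterations per temperature, 1000 temperatures.
    ``n_starts`` controls the multi-start policy (best of several
    independently seeded runs is kept).
    """

    t1_lower_ms: float = 700.0
    t1_upper_ms: float = 2000.0
    t1_grid_step_ms: float = 50.0
    snr: float = 125.0
    cooling_t: float = 0.985
    cooling_d: float = 0.998
    initial_temperature: float = 0.8
    initial_scale_ms: float = 100.0
    initial_scale_deg: float = 30.0
    inner_iterations: int = 2000
    outer_iterations: int = 1000
    penalty: float = PENALTY_DEFAULT
    n_starts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.cooling_t < 1 and 0 < self.cooling_d < 1):
            raise ValueError("cooling factors must lie in (0, 1)")
        if self.t1_lower_ms > self.t1_upper_ms or self.t1_lower_ms <= 0:
            raise ValueError("need 0 < t1_lower_ms <= t1_upper_ms")
        if self.snr <= 0:
            raise ValueError("snr must be positive")

    def t1_grid(self) -> np.ndarray:
        if self.t1_lower_ms == self.t1_upper_ms:
            return np.array([self.t1_lower_ms])
        return np.arange(
            self.t1_lower_ms,
            self.t1_upper_ms + self.t1_grid_step_ms / 2,
            self.t1_grid_step_ms,
        )


@dataclass(frozen=True)
class OptimizationResult:
    best_design: DesignVector
    best_cost: float
    worst_case_t1_ms: float
    cost_trace: np.ndarray
    restarts: int


class OptimizationFailure(RuntimeError):
    """No feasible design was found in any restart."""


def minmax_cost(design: DesignVector, config: OptimizerConfig) -> float:
    """Worst-case relative error over the T1 grid, penalized if infeasible.

    Structurally invalid geometries (non-increasing times, t5 >= TR) cannot
    be simulated; they return penalty scaled up by the violation magnitude
    so the simplex is steered back toward valid orderings.
    """
    violation = design.constraint_violation()
    try:
        seq = design.to_sequence()
    except SequenceError:
        return config.penalty * (1.0 + violation / 1000.0)
    raw = float(np.max(relative_error_curve(seq, config.t1_grid(), config.snr)))
    if not math.isfinite(raw):
        raw = config.penalty
    return raw + (config.penalty if violation > 0 else 0.0)


def _initial_design() -> DesignVector:
    """Published initialization: TR 5500 ms, evenly spread pulses, 45° flips."""
    tr = 5500.0
    times = [tr * k / 5.0 for k in range(1, 5)]
    return DesignVector(*times, 45.0, 45.0, 45.0, tr)


def _scales(config: OptimizerConfig, free_idx: np.ndarray) -> np.ndarray:
    full = np.where(_TIME_LIKE, config.initial_scale_ms, config.initial_scale_deg)
    return full[free_idx]


def _nm_iteration(S, Y, f, temp, rng):
    """One annealed Nelder-Mead update of simplex S (vertices) / Y (raw costs)."""
    n = S.shape[1]
    yp = np.array([perturbed_cost(y, temp, rng) for y in Y])
    order = np.argsort(yp, kind="stable")
    S, Y, yp = S[order], Y[order], yp[order]
    centroid = S[:-1].mean(axis=0)
    xr = centroid + (centroid - S[-1])
    yr = f(xr)
    yrp = perturbed_cost(yr, temp, rng)
    if yrp < yp[0]:
        xe = centroid + 2.0 * (centroid - S[-1])
        ye = f(xe)
        if perturbed_cost(ye, temp, rng) < yrp:
            S[-1], Y[-1] = xe, ye
        else:
            S[-1], Y[-1] = xr, yr
    elif yrp < yp[-2]:
        S[-1], Y[-1] = xr, yr
    else:
        xc = centroid + 0.5 * (S[-1] - centroid)
        yc = f(xc)
        if perturbed_cost(yc, temp, rng) < yp[-1]:
            S[-1], Y[-1] = xc, yc
        else:  # shrink toward the current best vertex
            for i in range(1, n + 1):
                S[i] = S[0] + 0.5 * (S[i] - S[0])
                Y[i] = f(S[i])
    return S, Y


def _anneal_simplex(f, x0, scales, config: OptimizerConfig, rng):
    """Annealed simplex run; returns (best_x, best_raw_cost, trace)."""
    n = len(x0)
    best_x = np.asarray(x0, dtype=float).copy()
    best_y = f(best_x)
    state = AnnealState(
        temperature=config.initial_temperature,
        simplex_scale_ms=config.initial_scale_ms,
        simplex_scale_deg=config.initial_scale_deg,
    )
    scale_frac = 1.0

    def build_simplex(center: np.ndarray, frac: float) -> tuple[np.ndarray, np.ndarray]:
        S = np.tile(center, (n + 1, 1))
        for i in range(n):
            S[i + 1, i] += scales[i] * frac
        return S, np.array([f(s) for s in S])

    # scan the initial simplex so a zero-iteration schedule still returns
    # its best vertex
    S, Y = build_simplex(best_x, scale_frac)
    i = int(np.argmin(Y))
    if Y[i] < best_y:
        best_y, best_x = Y[i], S[i].copy()
    trace = [best_y]
    for _ in range(config.outer_iterations):
        S, Y = build_simplex(best_x, scale_frac)
        i = int(np.argmin(Y))
        if Y[i] < best_y:
            best_y, best_x = Y[i], S[i].copy()
        for _ in range(config.inner_iterations):
            S, Y = _nm_iteration(S, Y, f, state.temperature, rng)
            i = int(np.argmin(Y))
            if Y[i] < best_y:
                best_y, best_x = Y[i], S[i].copy()
        state = anneal_step(state, config.cooling_t, config.cooling_d)
        scale_frac *= config.cooling_d
        trace.append(best_y)
    return best_x, best_y, np.array(trace)


def optimize_sequence(
    config: OptimizerConfig,
    initial: DesignVector | None = None,
    free: tuple[str, ...] | None = None,
) -> OptimizationResult:
    """Hybrid simplex/annealing min-max search over TSI designs.

    Parameters
    ----------
    config:
        Problem definition and annealing schedule.
    initial:
        Starting design; defaults to the published initialization (TR
        5500 ms, evenly spread pulse times, 45° imaging flips).
    free:
        Names of the design fields to optimize (default: all 8).  Fixing a
        subset enables restricted searches, e.g. a 1-D sweep over ``a1_deg``.

    The search is repeated from ``config.n_starts`` jittered initial points
    (deterministic in ``config.seed``) and the best feasible result is
    returned.  Raises :class:`OptimizationFailure` if every restart ends on
    an infeasible design.
    """
    base = (initial or _initial_design()).as_array()
    free = tuple(free) if free is not None else _FIELDS
    unknown = set(free) - set(_FIELDS)
    if unknown:
        raise ValueError(f"unknown design fields: {sorted(unknown)}")
    free_idx = np.array([_FIELDS.index(name) for name in free], dtype=int)
    scales = _scales(config, free_idx)

    def embed(xfree: np.ndarray) -> DesignVector:
        x = base.copy()
        x[free_idx] = xfree
        return DesignVector.from_array(x)

    def f(xfree: np.ndarray) -> float:
        return minmax_cost(embed(xfree), config)

    best: tuple | None = None
    for start in range(config.n_starts):
        rng = np.random.default_rng(config.seed + start)
        x0 = base[free_idx].copy()
        if start > 0:  # jitter subsequent starts by one simplex scale
            x0 = x0 + rng.uniform(-1.0, 1.0, size=x0.size) * scales
        bx, by, trace = _anneal_simplex(f, x0, scales, config, rng)
        design = embed(bx)
        if design.is_feasible() and (best is None or by < best[1]):
            best = (design, by, trace, start)
    if best is None:
        raise OptimizationFailure("no feasible design found in any restart")
    design, by, trace, _ = best
    grid = config.t1_grid()
    curve = relative_error_curve(design.to_sequence(), grid, config.snr)
    return OptimizationResult(
        best_design=design,
        best_cost=by,
        worst_case_t1_ms=float(grid[int(np.argmax(curve))]),
        cost_trace=trace,
        restarts=config.n_starts,
    )
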