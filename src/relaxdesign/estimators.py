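"""T1 (and M0) estimators for multi-pulse and SPGR acquisitions.

The workhorse is separable nonlinear least squares (variable projection):
because the signal model ``s = M0 h(T1) + w`` is linear in M0, the
two-parameter least-squares fit reduces to a 1-D search over T1 of the
projection residual

    J(T1) = s' [I - h (h'h)^-1 h'] s,

with the amplitude recovered in closed form as ``M0 = h's / h'h`` at the
minimizing T1.  The search is a coarse grid scan followed by quadratic
interpolation on the best grid triple; ties break toward the smallest T1
and boundary solutions are flagged.

`nlse_full` performs the joint (M0, T1) minimization explicitly (per-grid
least-squares amplitude) and is retained as the oracle for the variable
projection identity.  `despot1_fit` implements the DESPOT1 linearization
for SPGR data: regress ``S/sin(a)`` on ``S/tan(a)``; the slope equals
``E1 = exp(-TR/T1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .sequence_model import (
    PulseSequence,
    SequenceError,
    SPGRProtocol,
    spgr_weighting_matrix,
    weighting_matrix,
)

__all__ = [
    "T1Grid",
    "EstimationResult",
    "UnidentifiableError",
    "nlse_separable",
    "nlse_full",
    "despot1_fit",
    "nlse_separable_batch",
    "despot1_linear_batch",
]


class UnidentifiableError(ValueError):
    """The weighting vector is zero across the grid; T1 cannot be estimated."""


@dataclass(frozen=True)
class T1Grid:
    """Coarse T1 search grid (ms). Default spans 100-10000 ms in 10 ms steps.

    The grid must cover the plausible T1 range generously: at low SNR the
    objective is shallow and estimates spread far from the truth, so the
    sample mean (hence the measured bias) is sensitive to where the grid is
    truncated.
    """

    min_ms: float = 100.0
    max_ms: float = 10000.0
    coarse_step_ms: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.min_ms < self.max_ms):
            raise ValueError("need 0 < min_ms < max_ms")
        if self.coarse_step_ms <= 0:
            raise ValueError("coarse_step_ms must be positive")

    def values(self) -> np.ndarray:
        return np.arange(self.min_ms, self.max_ms + self.coarse_step_ms / 2, self.coarse_step_ms)


@dataclass(frozen=True)
class EstimationResult:
    t1_hat_ms: float
    m0_hat: float
    objective: float
    converged_on_boundary: bool


def _weighting_fn(model: PulseSequence | SPGRProtocol):
    if isinstance(model, SPGRProtocol):
        return lambda t1: spgr_weighting_matrix(model, t1)
    return lambda t1: weighting_matrix(model, t1)


def _projection_objective(S: np.ndarray, H: np.ndarray, hth: np.ndarray) -> np.ndarray:
    """J(T1) for every trial (rows of S) and grid point (rows of H)."""
    g = S @ H.T  # (trials, grid): h's per candidate
    return np.sum(S * S, axis=1)[:, None] - g * g / hth[None, :]


def nlse_separable_batch(
    signals: np.ndarray,
    model: PulseSequence | SPGRProtocol,
    grid: T1Grid | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized separable NLSE over many trials.

    Parameters
    ----------
    signals:
        Array of shape ``(n_trials, n_readouts)``.
    model:
        Pulse sequence or SPGR protocol defining h(T1).
    grid:
        T1 search grid; defaults to :class:`T1Grid` defaults.

    Returns
    -------
    (t1_hat_ms, boundary)
        Per-trial refined T1 estimates and boundary flags.
    """
    grid = grid or T1Grid()
    S = np.atleast_2d(np.asarray(signals, dtype=float))
    t1s = grid.values()
    H = _weighting_fn(model)(t1s)
    if S.shape[1] != H.shape[1]:
        raise SequenceError(
            f"signals have {S.shape[1]} readouts but the model produces {H.shape[1]}"
        )
    hth = np.sum(H * H, axis=1)
    if np.all(hth == 0):
        raise UnidentifiableError("h is zero across the whole T1 grid")
    J = _projection_objective(S, H, np.where(hth > 0, hth, np.inf))
    idx = np.argmin(J, axis=1)  # first minimum -> ties break toward small T1
    boundary = (idx == 0) | (idx == t1s.size - 1)
    t1_hat = t1s[idx].astype(float)
    # quadratic interpolation through the best grid triple (interior only)
    interior = ~boundary
    if np.any(interior):
        i = idx[interior]
        rows = np.flatnonzero(interior)
        jm, j0, jp = J[rows, i - 1], J[rows, i], J[rows, i + 1]
        curv = jm - 2.0 * j0 + jp
        ok = curv > 0
        offset = np.zeros_like(j0)
        offset[ok] = 0.5 * (jm[ok] - jp[ok]) / curv[ok] * grid.coarse_step_ms
        t1_hat[rows] = t1s[i] + np.clip(
            offset, -grid.coarse_step_ms, grid.coarse_step_ms
        )
    return t1_hat, boundary


def _finish(signals: np.ndarray, model, t1_hat: float, boundary: bool) -> EstimationResult:
    h = _weighting_fn(model)(np.array([t1_hat]))[0]
    hth = float(h @ h)
    m0_hat = float(h @ signals) / hth if hth > 0 else 0.0
    resid = signals - m0_hat * h
    return EstimationResult(
        t1_hat_ms=float(t1_hat),
        m0_hat=m0_hat,
        objective=float(resid @ resid),
        converged_on_boundary=bool(boundary),
    )


def nlse_separable(
    signals: np.ndarray,
    seq: PulseSequence | SPGRProtocol,
    grid: T1Grid | None = None,
) -> EstimationResult:
    """Separable (variable projection) NLSE for a single signal vector."""
    s = np.asarray(signals, dtype=float).ravel()
    t1_hat, boundary = nlse_separable_batch(s[None, :], seq, grid)
    return _finish(s, seq, t1_hat[0], boundary[0])


def nlse_full(
    signals: np.ndarray,
    seq: PulseSequence | SPGRProtocol,
    grid: T1Grid | None = None,
) -> EstimationResult:
    """Joint (M0, T1) least squares by explicit 2-D minimization.

    For each grid T1 the optimal amplitude is found by linear least squares
    and the full residual ``||s - M0 h||^2`` is minimized; the winning
    triple is refined by quadratic interpolation.  Equivalent to
    :func:`nlse_separable` by the variable projection identity; kept as an
    independent oracle.
    """
    grid = grid or T1Grid()
    s = np.asarray(signals, dtype=float).ravel()
    t1s = grid.values()
    H = _weighting_fn(seq)(t1s)
    if s.size != H.shape[1]:
        raise SequenceError(
            f"signals have {s.size} readouts but the model produces {H.shape[1]}"
        )
    if not np.any(np.sum(H * H, axis=1) > 0):
        raise UnidentifiableError("h is zero across the whole T1 grid")
    J = np.empty(t1s.size)
    for k in range(t1s.size):
        h = H[k]
        m0, *_ = np.linalg.lstsq(h[:, None], s, rcond=None)
        r = s - h * m0[0]
        J[k] = r @ r
    idx = int(np.argmin(J))
    boundary = idx in (0, t1s.size - 1)
    t1_hat = float(t1s[idx])
    if not boundary:
        jm, j0, jp = J[idx - 1], J[idx], J[idx + 1]
        curv = jm - 2.0 * j0 + jp
        if curv > 0:
            off = 0.5 * (jm - jp) / curv * grid.coarse_step_ms
            t1_hat += float(np.clip(off, -grid.coarse_step_ms, grid.coarse_step_ms))
    return _finish(s, seq, t1_hat, boundary)


def despot1_linear_batch(
    signals: np.ndarray,
    protocol: SPGRProtocol,
    grid: T1Grid | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized DESPOT1 linear fit over many trials.

    Regresses ``y = S/sin(a)`` on ``x = S/tan(a)`` per trial; the slope is
    ``E1`` so ``T1 = -TR / ln(slope)``.  Slopes outside (0, 1) (possible
    under noise) give non-physical T1; those trials are clipped to the grid
    bounds and flagged.
    """
    grid = grid or T1Grid()
    S = np.atleast_2d(np.asarray(signals, dtype=float))
    alpha = np.radians(np.asarray(protocol.flip_angles_deg))
    if len(set(protocol.flip_angles_deg)) < 2:
        raise SequenceError("DESPOT1 needs at least two distinct flip angles")
    if S.shape[1] != alpha.size:
        raise SequenceError(
            f"signals have {S.shape[1]} readouts but the protocol has {alpha.size} flips"
        )
    x = S / np.tan(alpha)[None, :]
    y = S / np.sin(alpha)[None, :]
    xm = x.mean(axis=1, keepdims=True)
    ym = y.mean(axis=1, keepdims=True)
    sxx = np.sum((x - xm) ** 2, axis=1)
    slope = np.sum((x - xm) * (y - ym), axis=1) / np.where(sxx > 0, sxx, np.inf)
    t1_hat = np.full(S.shape[0], grid.max_ms)
    boundary = np.ones(S.shape[0], dtype=bool)
    valid = (slope > 0) & (slope < 1)
    t1_hat[valid] = -protocol.tr_ms / np.log(slope[valid])
    boundary[valid] = False
    # slope <= 0 implies an (unphysically) instantaneous recovery
    t1_hat[slope <= 0] = grid.min_ms
    low = valid & (t1_hat < grid.min_ms)
    high = valid & (t1_hat > grid.max_ms)
    t1_hat[low], t1_hat[high] = grid.min_ms, grid.max_ms
    boundary |= low | high
    return t1_hat, boundary


def despot1_fit(
    signals: np.ndarray,
    protocol: SPGRProtocol,
    variant: str = "linear",
    grid: T1Grid | None = None,
) -> EstimationResult:
    """DESPOT1 T1 fit from SPGR signals, linear or NLSE variant.

    variant="linear": ordinary least squares on the DESPOT1 linearization;
    variant="nlse": separable NLSE with the SPGR weighting model.
    """
    grid = grid or T1Grid()
    s = np.asarray(signals, dtype=float).ravel()
    if variant == "nlse":
        return nlse_separable(s, protocol, grid)
    if variant != "linear":
        raise ValueError(f"unknown variant {variant!r}; use 'linear' or 'nlse'")
    t1_hat, boundary = despot1_linear_batch(s[None, :], protocol, grid)
    alpha = np.radians(np.asarray(protocol.flip_angles_deg))
    x = s / np.tan(alpha)
    y = s / np.sin(alpha)
    slope, intercept = np.polyfit(x, y, 1)
    e1 = math.exp(-protocol.tr_ms / t1_hat[0])
    m0_hat = float(intercept / (1.0 - e1)) if e1 < 1.0 else 0.0
    h = spgr_weighting_matrix(protocol, np.array([t1_hat[0]]))[0]
    resid = s - m0_hat * h
    return EstimationResult(
        t1_hat_ms=float(t1_hat[0]),
        m0_hat=m0_hat,
        objective=float(resid @ resid),
        converged_on_boundary=bool(boundary[0]),
    )
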