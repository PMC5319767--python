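"""Cramér-Rao bound for joint (M0, T1) estimation and its geometric split.

For the additive white-Gaussian signal model ``s_i = M0 h_i(T1) + w_i`` the
2x2 Fisher information matrix for theta = [M0, T1] has entries

    I11 = sum(h_i^2) / sigma^2
    I12 = M0 * sum(h_i * dh_i) / sigma^2
    I22 = M0^2 * sum(dh_i^2) / sigma^2

with ``dh = dh/dT1``.  The variance of any unbiased T1 estimator is bounded
below by ``CRB(T1) = [I^-1]_22``, which factors geometrically as

    CRB(T1) = ( SNR * ||dh/dT1|| * sin(phi) )^-2,       SNR = M0 / sigma,

where phi is the principal angle between the signal weighting vector h and
the sensitivity vector dh/dT1.  The three factors — SNR, sensitivity norm,
and orthogonality sin(phi) — are the only levers a sequence designer has on
T1 precision, and the design metric used throughout this package is the
relative error ``sqrt(CRB(T1)) / T1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .sequence_model import (
    PulseSequence,
    SignalWeighting,
    SPGRProtocol,
    spgr_weighting_matrix,
    weighting_matrix,
)

__all__ = [
    "FisherInfo",
    "CRBReport",
    "DegenerateModelError",
    "sensitivity_vector",
    "sensitivity_matrix",
    "fisher_information",
    "crb_t1",
    "decompose_crb",
    "relative_error_curve",
    "average_orthogonality",
    "orthogonality_curve",
]

DEFAULT_REL_STEP = 1e-4


class DegenerateModelError(ValueError):
    """The signal model carries no information about the parameter."""


@dataclass(frozen=True)
class FisherInfo:
    """Entries of the 2x2 Fisher information matrix for theta = [M0, T1].

    ``i11`` is per M0^2-scaled (units 1), ``i12`` per ms, ``i22`` per ms^2;
    ``sigma`` is the noise standard deviation in signal units.
    """

    i11: float
    i12: float
    i22: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    def as_matrix(self) -> np.ndarray:
        return np.array([[self.i11, self.i12], [self.i12, self.i22]])


@dataclass(frozen=True)
class CRBReport:
    """The CRB on T1 and its three geometric factors.

    ``crb_t1 = (snr * sensitivity_norm * orthogonality)^-2`` (ms^2);
    ``relative_error = sqrt(crb_t1) / T1`` (dimensionless, NaN when the
    report was built without a T1 value).
    """

    snr: float
    sensitivity_norm: float
    orthogonality: float
    crb_t1: float
    relative_error: float


def _weighting(model: PulseSequence | SPGRProtocol, t1: np.ndarray) -> np.ndarray:
    if isinstance(model, SPGRProtocol):
        return spgr_weighting_matrix(model, t1)
    return weighting_matrix(model, t1)


def sensitivity_matrix(
    model: PulseSequence | SPGRProtocol,
    t1_ms: np.ndarray,
    rel_step: float = DEFAULT_REL_STEP,
) -> np.ndarray:
    """dh/dT1 by central finite difference, vectorized over a T1 array.

    The step is relative (``rel_step * T1``) so accuracy is uniform across
    the orders-of-magnitude span of physiological T1 values.
    """
    if not (0 < rel_step <= 0.01):
        raise ValueError(f"rel_step must lie in (0, 0.01], got {rel_step}")
    t1 = np.atleast_1d(np.asarray(t1_ms, dtype=float))
    step = rel_step * t1
    if np.any(t1 + step == t1):
        raise FloatingPointError("finite-difference step underflows at this T1")
    return (_weighting(model, t1 + step) - _weighting(model, t1 - step)) / (
        2.0 * step[:, None]
    )


def sensitivity_vector(
    seq: PulseSequence | SPGRProtocol,
    t1_ms: float,
    rel_step: float = DEFAULT_REL_STEP,
) -> np.ndarray:
    """Sensitivity vector dh/dT1 at a single T1 value (per ms)."""
    if t1_ms <= 0:
        raise ValueError(f"t1_ms must be positive, got {t1_ms}")
    return sensitivity_matrix(seq, np.array([float(t1_ms)]), rel_step)[0]


def fisher_information(
    h: SignalWeighting | np.ndarray,
    dh: np.ndarray,
    m0: float,
    sigma: float,
) -> FisherInfo:
    """Fisher information matrix entries for joint (M0, T1) estimation."""
    hv = np.asarray(h.values if isinstance(h, SignalWeighting) else h, dtype=float)
    dhv = np.asarray(dh, dtype=float)
    if hv.shape != dhv.shape:
        raise ValueError(f"h and dh must have equal length, got {hv.shape} vs {dhv.shape}")
    inv_s2 = 1.0 / sigma**2
    return FisherInfo(
        i11=float(inv_s2 * np.sum(hv**2)),
        i12=float(inv_s2 * m0 * np.sum(hv * dhv)),
        i22=float(inv_s2 * m0**2 * np.sum(dhv**2)),
        sigma=sigma,
    )


def crb_t1(fim: FisherInfo) -> float:
    """CRB on the T1 estimate: the (2,2) entry of the inverse FIM (ms^2).

    Returns ``+inf`` when the information about T1 left after projecting
    out M0 is zero (h parallel to dh/dT1), so unidentifiable designs can be
    penalized smoothly instead of raising.
    """
    if fim.i11 <= 0:
        raise DegenerateModelError("i11 = 0: the model produces no signal")
    schur = fim.i22 - fim.i12**2 / fim.i11
    # a Schur complement at rounding level means h and dh are parallel
    if schur <= fim.i22 * 1e-12:
        return math.inf
    return 1.0 / schur


def decompose_crb(
    h: SignalWeighting | np.ndarray,
    dh: np.ndarray,
    snr: float,
    t1_ms: float | None = None,
) -> CRBReport:
    """Geometric decomposition CRB = (SNR * ||dh/dT1|| * sin phi)^-2.

    ``cos(phi)`` is clipped to [-1, 1] to guard against rounding before
    forming ``sin(phi) = sqrt(1 - cos^2 phi)``.  When ``t1_ms`` is given,
    the relative error ``sqrt(CRB)/T1`` is filled in; otherwise it is NaN.
    """
    hv = np.asarray(h.values if isinstance(h, SignalWeighting) else h, dtype=float)
    dhv = np.asarray(dh, dtype=float)
    h_norm = float(np.linalg.norm(hv))
    if h_norm == 0.0:
        raise DegenerateModelError("||h|| = 0: principal angle undefined")
    if snr <= 0:
        raise ValueError(f"snr must be positive, got {snr}")
    dh_norm = float(np.linalg.norm(dhv))
    if dh_norm == 0.0:
        sin_phi = 0.0
    else:
        cos_phi = float(np.clip(np.dot(hv, dhv) / (h_norm * dh_norm), -1.0, 1.0))
        sin_phi = math.sqrt(max(0.0, 1.0 - cos_phi**2))
    denom = snr * dh_norm * sin_phi
    crb = math.inf if denom == 0.0 else denom**-2
    if t1_ms is None:
        rel = math.nan
    else:
        rel = math.sqrt(crb) / t1_ms if math.isfinite(crb) else math.inf
    return CRBReport(
        snr=snr,
        sensitivity_norm=dh_norm,
        orthogonality=sin_phi,
        crb_t1=crb,
        relative_error=rel,
    )


def _crb_curve(
    model: PulseSequence | SPGRProtocol,
    t1: np.ndarray,
    snr: float,
    rel_step: float,
) -> np.ndarray:
    """Vectorized CRB(T1) over a grid via the closed-form Schur complement."""
    h = _weighting(model, t1)
    dh = sensitivity_matrix(model, t1, rel_step)
    sum_h2 = np.sum(h**2, axis=1)
    if np.any(sum_h2 == 0):
        raise DegenerateModelError("zero signal weighting on the T1 grid")
    schur = np.sum(dh**2, axis=1) - np.sum(h * dh, axis=1) ** 2 / sum_h2
    with np.errstate(divide="ignore"):
        return np.where(schur > 0, 1.0 / (snr**2 * np.maximum(schur, 1e-300)), np.inf)


def relative_error_curve(
    model: PulseSequence | SPGRProtocol,
    t1_grid_ms: np.ndarray,
    snr: float,
    rel_step: float = DEFAULT_REL_STEP,
) -> np.ndarray:
    """Relative error sqrt(CRB(T1))/T1 on a T1 grid (dimensionless)."""
    t1 = np.atleast_1d(np.asarray(t1_grid_ms, dtype=float))
    if t1.size == 0:
        raise ValueError("t1_grid_ms must not be empty")
    if np.any(t1 <= 0):
        raise ValueError("all T1 grid values must be positive")
    if snr <= 0:
        raise ValueError(f"snr must be positive, got {snr}")
    return np.sqrt(_crb_curve(model, t1, snr, rel_step)) / t1


def orthogonality_curve(
    model: PulseSequence | SPGRProtocol,
    t1_grid_ms: np.ndarray,
    rel_step: float = DEFAULT_REL_STEP,
) -> np.ndarray:
    """sin(phi) between h and dh/dT1 on a T1 grid."""
    t1 = np.atleast_1d(np.asarray(t1_grid_ms, dtype=float))
    h = _weighting(model, t1)
    dh = sensitivity_matrix(model, t1, rel_step)
    denom = np.linalg.norm(h, axis=1) * np.linalg.norm(dh, axis=1)
    if np.any(denom == 0):
        raise DegenerateModelError("zero-norm vector on the T1 grid")
    cos_phi = np.clip(np.sum(h * dh, axis=1) / denom, -1.0, 1.0)
    return np.sqrt(1.0 - cos_phi**2)


def average_orthogonality(
    model: PulseSequence | SPGRProtocol,
    t1_min_ms: float = 700.0,
    t1_max_ms: float = 5000.0,
    step_ms: float = 10.0,
) -> float:
    """Mean sin(phi) over a uniform T1 grid (default 700-5000 ms, 10 ms).

    This is the sequence-level orthogonality summary used to compare
    designs; report it rounded to 2 decimals.
    """
    grid = np.arange(t1_min_ms, t1_max_ms + step_ms / 2, step_ms)
    return float(np.mean(orthogonality_curve(model, grid)))
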