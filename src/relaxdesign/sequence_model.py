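"""Bloch-equation signal models for multi-pulse T1 relaxometry sequences.

This module synthesizes noise-free longitudinal-magnetization signals for
TSI-type pulse trains (imaging pulses interleaved with adiabatic inversion
pulses, repeated every TR) and for the steady-state SPGR protocol that
underlies DESPOT1.

The physical model is one-dimensional longitudinal Bloch dynamics with
perfect spoiling: between pulses the magnetization relaxes as

    Mz(t0 + dt) = M0 + (Mz(t0) - M0) * exp(-dt / T1),

an RF pulse with flip angle alpha maps ``Mz -> Mz * cos(alpha)`` and, for an
imaging pulse, emits a sample proportional to ``Mz * sin(alpha)`` at the
pulse instant.  Because every relaxation interval and every pulse is an
affine map of Mz, one full TR composes to ``Mz -> A*Mz + B`` and the
periodic steady state is the fixed point ``Mz_eq = B / (1 - A)``.  The
dimensionless per-readout signal weighting ``h_i(T1)`` is the sampled
``Mz * sin(alpha)`` divided by M0, evaluated in that steady state; the
acquired noise-free signal is ``M0 * h_i(T1)``.

Two independent implementations are provided: the closed-form fixed point
(:func:`steady_state_mz`, :func:`signal_weighting`) and a literal
period-by-period Bloch recursion (:func:`simulate_bloch_recursion`) that
serves as the numerical oracle for the closed form.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PulseKind",
    "PulseEvent",
    "PulseSequence",
    "TissueParams",
    "SignalWeighting",
    "SPGRProtocol",
    "SequenceError",
    "simulate_bloch_recursion",
    "steady_state_mz",
    "signal_weighting",
    "weighting_matrix",
    "spgr_signal",
    "spgr_weighting_matrix",
]


class SequenceError(ValueError):
    """Structural error in a pulse-sequence or protocol description."""


class PulseKind(str, enum.Enum):
    """Role of an RF pulse within the train."""

    IMAGING = "imaging"
    INVERSION = "inversion"


@dataclass(frozen=True)
class PulseEvent:
    """One RF pulse: when it happens and how far it tips the magnetization.

    Parameters
    ----------
    time_ms:
        Time of the pulse in milliseconds from the start of the TR period.
    flip_angle_deg:
        Flip angle in degrees.  Inversion pulses are ideal adiabatic 180°
        pulses (``Mz -> -Mz``); imaging pulses may take any angle in
        ``[0, 180]`` so that B1-perturbation studies can push a nominal
        angle beyond the 90° design limit.
    kind:
        Whether the pulse acquires a readout (:attr:`PulseKind.IMAGING`) or
        only prepares the magnetization (:attr:`PulseKind.INVERSION`).
    """

    time_ms: float
    flip_angle_deg: float
    kind: PulseKind

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", PulseKind(self.kind))
        if self.time_ms < 0:
            raise SequenceError(f"pulse time must be >= 0 ms, got {self.time_ms}")
        if self.kind is PulseKind.INVERSION and self.flip_angle_deg != 180.0:
            raise SequenceError(
                f"inversion pulses are fixed at 180 deg, got {self.flip_angle_deg}"
            )
        if self.kind is PulseKind.IMAGING and not (0.0 <= self.flip_angle_deg <= 180.0):
            raise SequenceError(
                f"imaging flip angle must lie in [0, 180] deg, got {self.flip_angle_deg}"
            )


@dataclass(frozen=True)
class PulseSequence:
    """An ordered pulse train repeated every ``tr_ms`` milliseconds.

    Invariants enforced at construction: the first event is an imaging pulse
    at t = 0, event times are strictly increasing, every event happens
    before the end of the TR, and at least one imaging pulse exists (so the
    sequence produces at least one readout).
    """

    tr_ms: float
    events: tuple[PulseEvent, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        if self.tr_ms <= 0:
            raise SequenceError(f"tr_ms must be positive, got {self.tr_ms}")
        if not self.events:
            raise SequenceError("a pulse sequence needs at least one pulse")
        first = self.events[0]
        if first.time_ms != 0.0 or first.kind is not PulseKind.IMAGING:
            raise SequenceError("the first pulse must be an imaging pulse at t = 0")
        times = [ev.time_ms for ev in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise SequenceError(f"pulse times must be strictly increasing, got {times}")
        if times[-1] >= self.tr_ms:
            raise SequenceError(
                f"last pulse at {times[-1]} ms must precede TR = {self.tr_ms} ms"
            )
        if not any(ev.kind is PulseKind.IMAGING for ev in self.events):
            raise SequenceError("a pulse sequence needs at least one imaging pulse")

    @property
    def n_imaging(self) -> int:
        return sum(ev.kind is PulseKind.IMAGING for ev in self.events)

    @property
    def readout_times_ms(self) -> np.ndarray:
        return np.array(
            [ev.time_ms for ev in self.events if ev.kind is PulseKind.IMAGING]
        )

    def with_scaled_imaging_flips(self, factor: float) -> "PulseSequence":
        """Scale all imaging flip angles by ``factor``; inversions stay 180°.

        Used for B1-inhomogeneity studies, where patient-induced field
        distortions perturb the imaging flip angles multiplicatively while
        adiabatic inversions remain accurate.
        """
        events = tuple(
            PulseEvent(ev.time_ms, ev.flip_angle_deg * factor, ev.kind)
            if ev.kind is PulseKind.IMAGING
            else ev
            for ev in self.events
        )
        return PulseSequence(self.tr_ms, events)


@dataclass(frozen=True)
class TissueParams:
    """Tissue voxel parameters: equilibrium magnetization and T1.

    ``m0`` is in arbitrary units and sets the overall signal scale;
    ``t1_ms`` is the longitudinal relaxation time in milliseconds.
    """

    m0: float
    t1_ms: float

    def __post_init__(self) -> None:
        if self.m0 <= 0:
            raise ValueError(f"m0 must be positive, got {self.m0}")
        if self.t1_ms <= 0:
            raise ValueError(f"t1_ms must be positive, got {self.t1_ms}")


@dataclass(frozen=True)
class SignalWeighting:
    """The dimensionless per-readout weighting vector h(T1).

    ``values[i]`` is the steady-state longitudinal magnetization (in units
    of M0) seen by readout ``i``, times ``sin(alpha_i)``; entries may be
    negative after an inversion.  The noise-free acquired signal is
    ``M0 * values``.
    """

    values: np.ndarray
    readout_times_ms: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(
            self, "readout_times_ms", np.asarray(self.readout_times_ms, dtype=float)
        )
        if self.values.shape != self.readout_times_ms.shape:
            raise ValueError("values and readout_times_ms must have matching shapes")


@dataclass(frozen=True)
class SPGRProtocol:
    """Spoiled gradient-recalled-echo protocol for DESPOT1-style T1 mapping.

    Acquires one steady-state image per flip angle at fixed ``tr_ms``.  The
    echo time, receiver bandwidth, and SENSE acceleration rate do not enter
    the signal equation; they matter only when calibrating SNR across
    sequences acquired on the same scanner.
    """

    tr_ms: float
    te_ms: float
    flip_angles_deg: tuple[float, ...]
    bandwidth_khz: float
    sense_rate: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "flip_angles_deg", tuple(float(a) for a in self.flip_angles_deg)
        )
        if self.tr_ms <= 0:
            raise SequenceError(f"tr_ms must be positive, got {self.tr_ms}")
        if not (0 <= self.te_ms < self.tr_ms):
            raise SequenceError("te_ms must satisfy 0 <= te_ms < tr_ms")
        if len(self.flip_angles_deg) < 2:
            raise SequenceError("DESPOT1 fitting needs at least 2 flip angles")
        if any(not (0.0 < a <= 90.0) for a in self.flip_angles_deg):
            raise SequenceError("SPGR flip angles must lie in (0, 90] deg")
        if self.bandwidth_khz <= 0 or self.sense_rate <= 0:
            raise SequenceError("bandwidth_khz and sense_rate must be positive")


# ---------------------------------------------------------------------------
# closed-form steady state via the per-TR affine map
# ---------------------------------------------------------------------------


def _per_tr_affine(seq: PulseSequence, t1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Compose one TR into Mz -> A*Mz + B, with Mz in units of M0.

    Relaxation over dt contributes ``(E, 1-E)`` with ``E = exp(-dt/T1)``;
    a pulse contributes ``(cos(alpha), 0)``.  Vectorized over a T1 array.
    """
    a = np.ones_like(t1)
    b = np.zeros_like(t1)
    prev = 0.0
    for ev in seq.events:
        e = np.exp(-(ev.time_ms - prev) / t1)
        a, b = e * a, e * b + (1.0 - e)
        c = math.cos(math.radians(ev.flip_angle_deg))
        a, b = c * a, c * b
        prev = ev.time_ms
    e = np.exp(-(seq.tr_ms - prev) / t1)
    return e * a, e * b + (1.0 - e)


def weighting_matrix(seq: PulseSequence, t1_ms: np.ndarray) -> np.ndarray:
    """Signal weighting vectors for an array of T1 values.

    Parameters
    ----------
    seq:
        Pulse sequence.
    t1_ms:
        1-D array of T1 values in milliseconds, all positive.

    Returns
    -------
    ndarray of shape ``(len(t1_ms), seq.n_imaging)``
        Row ``k`` is h(T1_k).
    """
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("all T1 values must be positive")
    scalar = t1.ndim == 0
    t1 = np.atleast_1d(t1)
    a, b = _per_tr_affine(seq, t1)
    if np.any(np.abs(a) >= 1.0):
        raise FloatingPointError("per-TR contraction |A| >= 1; no steady state")
    mz = b / (1.0 - a)  # start-of-TR steady state, units of M0
    prev = 0.0
    samples = []
    for ev in seq.events:
        e = np.exp(-(ev.time_ms - prev) / t1)
        mz = e * mz + (1.0 - e)
        if ev.kind is PulseKind.IMAGING:
            samples.append(mz * math.sin(math.radians(ev.flip_angle_deg)))
        mz = mz * math.cos(math.radians(ev.flip_angle_deg))
        prev = ev.time_ms
    out = np.stack(samples, axis=-1)
    return out[0] if scalar else out


def steady_state_mz(seq: PulseSequence, tissue: TissueParams) -> float:
    """Start-of-TR steady-state longitudinal magnetization.

    Solves the periodic fixed point ``Mz = A*Mz + B`` of the composed
    per-TR affine map in closed form.  Always well posed for positive TR
    and T1 (the relaxation intervals make ``|A| < 1``).
    """
    t1 = np.atleast_1d(float(tissue.t1_ms))
    a, b = _per_tr_affine(seq, t1)
    if abs(a[0]) >= 1.0:
        raise FloatingPointError("per-TR contraction |A| >= 1; no steady state")
    return float(tissue.m0 * b[0] / (1.0 - a[0]))


def signal_weighting(seq: PulseSequence, t1_ms: float) -> SignalWeighting:
    """Closed-form steady-state weighting vector h(T1) for one T1 value.

    h is independent of M0; the full noise-free signal is ``M0 * h``.
    """
    if t1_ms <= 0:
        raise ValueError(f"t1_ms must be positive, got {t1_ms}")
    values = weighting_matrix(seq, np.array([float(t1_ms)]))[0]
    return SignalWeighting(values=values, readout_times_ms=seq.readout_times_ms)


def simulate_bloch_recursion(
    seq: PulseSequence, tissue: TissueParams, n_periods: int
) -> tuple[float, SignalWeighting]:
    """Literal Bloch recursion over repeated TR periods (numerical oracle).

    Starting from thermal equilibrium ``Mz = M0``, repeats the pulse train
    ``n_periods`` times, applying relaxation between pulses, ``cos(alpha)``
    at each pulse, and collecting ``Mz * sin(alpha) / M0`` at each imaging
    pulse of the final period.

    Returns
    -------
    (mz_start_of_tr, weighting)
        The longitudinal magnetization at the start of a TR after
        ``n_periods`` repetitions, and the weighting vector collected in
        the final period.  Converges geometrically to the closed-form
        steady state of :func:`steady_state_mz` / :func:`signal_weighting`.
    """
    if n_periods < 1:
        raise ValueError(f"n_periods must be >= 1, got {n_periods}")
    t1 = tissue.t1_ms
    mz = tissue.m0
    samples: list[float] = []
    for period in range(n_periods):
        last = period == n_periods - 1
        if last:
            samples = []
        prev = 0.0
        for ev in seq.events:
            mz = tissue.m0 + (mz - tissue.m0) * math.exp(-(ev.time_ms - prev) / t1)
            if last and ev.kind is PulseKind.IMAGING:
                samples.append(
                    mz * math.sin(math.radians(ev.flip_angle_deg)) / tissue.m0
                )
            mz = mz * math.cos(math.radians(ev.flip_angle_deg))
            prev = ev.time_ms
        mz_end = tissue.m0 + (mz - tissue.m0) * math.exp(-(seq.tr_ms - prev) / t1)
        if last:
            break
        mz = mz_end
    weighting = SignalWeighting(
        values=np.array(samples), readout_times_ms=seq.readout_times_ms
    )
    return float(mz_end), weighting


# ---------------------------------------------------------------------------
# SPGR
# ---------------------------------------------------------------------------


def spgr_weighting_matrix(protocol: SPGRProtocol, t1_ms: np.ndarray) -> np.ndarray:
    """SPGR steady-state weighting h(T1) per flip angle, in units of M0.

    ``h_j = (1 - E1) sin(a_j) / (1 - E1 cos(a_j))`` with
    ``E1 = exp(-TR/T1)``; rows index T1, columns index flip angles.
    """
    t1 = np.atleast_1d(np.asarray(t1_ms, dtype=float))
    if np.any(t1 <= 0):
        raise ValueError("all T1 values must be positive")
    alpha = np.radians(np.asarray(protocol.flip_angles_deg))
    e1 = np.exp(-protocol.tr_ms / t1)[:, None]
    return (1.0 - e1) * np.sin(alpha)[None, :] / (1.0 - e1 * np.cos(alpha)[None, :])


def spgr_signal(protocol: SPGRProtocol, tissue: TissueParams) -> np.ndarray:
    """Noise-free steady-state SPGR amplitudes, one per flip angle."""
    h = spgr_weighting_matrix(protocol, np.array([tissue.t1_ms]))[0]
    return tissue.m0 * h
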