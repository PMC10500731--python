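"""Single spin-1/2 propagation under piecewise-constant shaped rf.

For one spin-1/2 without relaxation the density operator is equivalent to a
classical unit magnetization vector, so the engine composes exact axis-angle
rotations in the rotating frame: slice k rotates the state about the field

    ( s * amp_k * cos(phase_k),  s * amp_k * sin(phase_k),  offset + s * track_k )

(in Hz) by ``2*pi*|field|*dt``, where ``s`` is the dimensionless rf
inhomogeneity factor.  Because the waveform is piecewise constant, the
propagation is exact per slice; subdividing slices (``substeps``) must not
change the result and serves only as a consistency oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._rotations import propagate_fields
from .shapes import ShapedPulse

__all__ = [
    "PropagationParams",
    "MagnetizationState",
    "propagate",
    "propagate_batch",
    "nutation_signal",
]


@dataclass(frozen=True)
class MagnetizationState:
    """Expectation values (<Ix>, <Iy>, <Iz>) scaled to unit norm."""

    mx: float
    my: float
    mz: float

    def as_array(self) -> np.ndarray:
        return np.array([self.mx, self.my, self.mz])

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.as_array()))


@dataclass(frozen=True)
class PropagationParams:
    """Conditions for a propagation run.

    rf_scale:
        Dimensionless inhomogeneity factor s = nu1_actual / nu1_nominal;
        multiplies the programmed rf amplitude and offset track.
    offset_hz:
        Resonance offset (omega0 - omega_rf)/2pi in Hz.
    initial_state:
        Unit magnetization vector; defaults to spin-locked x.
    substeps:
        Per-point subdivision (>= 1).  Exactness oracle only.
    """

    rf_scale: float = 1.0
    offset_hz: float = 0.0
    initial_state: Sequence[float] = (1.0, 0.0, 0.0)
    substeps: int = 1

    def __post_init__(self):
        if self.rf_scale < 0:
            raise ValueError("rf_scale must be non-negative")
        if self.substeps < 1:
            raise ValueError("substeps must be >= 1")
        v = np.asarray(self.initial_state, float)
        if v.shape != (3,) or abs(np.linalg.norm(v) - 1.0) > 1e-12:
            raise ValueError("initial_state must be a unit 3-vector")


def _field_table(pulse: ShapedPulse, rf_scales: np.ndarray, offsets: np.ndarray, substeps: int = 1):
    """(T, B) Cartesian field tables for a batch of (rf_scale, offset) pairs."""
    x, y = pulse.cartesian()
    track = pulse.offset_track if pulse.offset_track is not None else np.zeros(pulse.n_points)
    if substeps > 1:
        x = np.repeat(x, substeps)
        y = np.repeat(y, substeps)
        track = np.repeat(track, substeps)
    wx = np.outer(x, rf_scales)
    wy = np.outer(y, rf_scales)
    wz = np.outer(track, rf_scales) + offsets[None, :]
    return wx, wy, wz, pulse.dt / substeps


def propagate(pulse: ShapedPulse, params: Optional[PropagationParams] = None) -> MagnetizationState:
    """Propagate a single spin through a shaped pulse; returns the final state.

    A zero-length pulse returns the initial state unchanged; NaNs in the
    waveform raise.
    """
    params = params or PropagationParams()
    m0 = np.asarray(params.initial_state, float)
    if pulse.n_points == 0:
        return MagnetizationState(*m0)
    wx, wy, wz, dt = _field_table(
        pulse, np.array([params.rf_scale]), np.array([params.offset_hz]), params.substeps
    )
    M = propagate_fields(wx, wy, wz, dt, m0)
    return MagnetizationState(*M[0])


def propagate_batch(
    pulse: ShapedPulse,
    rf_scales: np.ndarray,
    offset_hz: float = 0.0,
    initial_state: Sequence[float] = (1.0, 0.0, 0.0),
) -> np.ndarray:
    """Propagate one pulse for many rf scales at once; returns (B, 3) states."""
    scales = np.asarray(rf_scales, float)
    wx, wy, wz, dt = _field_table(pulse, scales, np.full(scales.shape, float(offset_hz)))
    return propagate_fields(wx, wy, wz, dt, np.asarray(initial_state, float))


def nutation_signal(nu1_hz: float, t1_points: int, dwell_s: float, axis: str = "y") -> np.ndarray:
    """<Ix>(k * dwell) during nutation of x magnetization about a y rf field.

    Computed by propagation (one exact rotation per dwell), not by formula,
    so the result doubles as an engine check: it must equal
    ``cos(2*pi*nu1*k*dwell)``.
    """
    if nu1_hz < 0:
        raise ValueError("nu1 must be non-negative")
    if axis != "y":
        raise ValueError("nutation axis must be 'y'")
    if t1_points < 1:
        raise ValueError("t1_points must be >= 1")
    T = t1_points - 1
    wx = np.zeros((T, 1))
    wy = np.full((T, 1), float(nu1_hz))
    wz = np.zeros((T, 1))
    traj = propagate_fields(wx, wy, wz, dwell_s, np.array([1.0, 0.0, 0.0]), record_stride=1)
    return traj[:, 0, 0]
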