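"""Shaped-pulse containers and the spin-lock-frame B1-selective construction.

A B1-selective pulse is built from two Cartesian rf components in the usual
rotating frame: a constant spin-lock field ``nu_sl`` along x, and a resonant
selective component along y,

    y(t) = 2 * nu2 * B(t / tau_p) * cos(2*pi*nu_mod*t),

whose co-rotating part acts in the frame rotating about x at ``nu_mod`` as a
band-selective pulse of amplitude ``nu2 * B``.  Spins whose nutation
frequency (local rf amplitude) falls within roughly ``4-6 / tau_p`` of
``nu_mod`` are inverted; all others are returned to the spin-lock axis.  The
factor 2 compensates for splitting the linear-polarized y field into co- and
counter-rotating halves.

With circular polarization the counter-rotating half is never generated: the
y component carries ``nu2 * B * cos`` and a synchronous resonance-offset
track carries ``nu2 * B * sin`` (an Iz term in the rotating frame is
indistinguishable from a resonance offset), realizing the co-rotating field
exactly and avoiding Bloch-Siegert shifts when ``nu2`` is not much smaller
than ``nu_sl``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .envelopes import BaseEnvelope

__all__ = [
    "ShapedPulse",
    "SelectivePulseSpec",
    "cartesian_to_amp_phase",
    "selective_field_at",
    "make_b1_selective_pulse",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ShapedPulse:
    """Time-discretized rf waveform: per-point amplitude (Hz) and phase (deg).

    Each point is held constant for one dwell ``dt`` (hardware semantics).
    ``offset_track`` optionally carries a per-point resonance-offset in Hz
    (used for circular-polarized selective pulses; phase-ramp shapes encode
    their effective offset in the phase itself and leave this unset).
    """

    dt: float
    amplitude: np.ndarray
    phase_deg: np.ndarray
    offset_track: Optional[np.ndarray] = None

    def __post_init__(self):
        amp = np.atleast_1d(np.asarray(self.amplitude, float))
        ph = np.atleast_1d(np.asarray(self.phase_deg, float))
        object.__setattr__(self, "amplitude", amp)
        object.__setattr__(self, "phase_deg", ph)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if amp.shape != ph.shape or amp.ndim != 1:
            raise ValueError("amplitude and phase must be 1-D arrays of equal length")
        if np.any(amp < 0):
            raise ValueError("amplitude must be non-negative")
        if np.any(ph < 0) or np.any(ph >= 360.0):
            raise ValueError("phase must lie in [0, 360)")
        if self.offset_track is not None:
            ot = np.atleast_1d(np.asarray(self.offset_track, float))
            if ot.shape != amp.shape:
                raise ValueError("offset_track must match the number of points")
            object.__setattr__(self, "offset_track", ot)

    @property
    def n_points(self) -> int:
        return int(self.amplitude.size)

    @property
    def duration(self) -> float:
        return self.n_points * self.dt

    def cartesian(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-point (x, y) rf components in Hz."""
        ph = np.radians(self.phase_deg)
        return self.amplitude * np.cos(ph), self.amplitude * np.sin(ph)

    def reversed_negated(self) -> "ShapedPulse":
        """Time-reversed pulse with the rf field (and offset track) negated.

        Playing this immediately after the original pulse undoes it exactly:
        each slice's rotation is inverted and the order reversed.
        """
        return ShapedPulse(
            dt=self.dt,
            amplitude=self.amplitude[::-1].copy(),
            phase_deg=np.mod(self.phase_deg[::-1] + 180.0, 360.0),
            offset_track=None if self.offset_track is None else -self.offset_track[::-1],
        )


def cartesian_to_amp_phase(x, y):
    """(x, y) rf components [Hz] -> (amplitude [Hz], phase [deg, 0-360)).

    (0, 0) maps to amplitude 0, phase 0 by convention.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    amp = np.hypot(x, y)
    phase = np.degrees(np.arctan2(y, x))
    phase = np.where(amp == 0.0, 0.0, np.mod(phase, 360.0))
    # arctan2(-0., x>0) can wrap to 360 - eps after mod; fold exactly
    phase = np.where(phase >= 360.0, 0.0, phase)
    if amp.ndim == 0:
        return float(amp), float(phase)
    return amp, phase


@dataclass(frozen=True)
class SelectivePulseSpec:
    """Parameters of the spin-lock-frame B1-selective pulse.

    nu_sl:
        Spin-lock amplitude in Hz (nominal rf amplitude along x).
    nu_mod:
        Modulation frequency in Hz; sets the center of the inversion band in
        nutation-frequency space.
    tau_p:
        Pulse length in seconds; the inversion bandwidth shrinks as 1/tau_p.
    dt:
        Dwell in seconds; tau_p/dt must be an integer number of points.
    nu2_scale:
        Selective-pulse amplitude parameter in Hz.  The envelope norm is such
        that nu2_scale = 1/tau_p gives an on-resonance flip angle of pi.
        ``None`` defaults to 1/tau_p.
    polarization:
        "linear" (y only, factor-2 convention) or "circular" (exact
        co-rotating field via a synchronous offset track).
    envelope:
        The dimensionless base envelope B(s).
    """

    nu_sl: float
    nu_mod: float
    tau_p: float
    dt: float
    envelope: BaseEnvelope
    nu2_scale: Optional[float] = None
    polarization: str = "linear"

    def __post_init__(self):
        if self.tau_p <= 0 or self.dt <= 0:
            raise ValueError("tau_p and dt must be positive")
        if self.nu_sl <= 0 or self.nu_mod <= 0:
            raise ValueError("nu_sl and nu_mod must be positive")
        ratio = self.tau_p / self.dt
        if abs(ratio - round(ratio)) > 1e-9 * ratio:
            raise ValueError("tau_p must be an integer multiple of dt")
        if self.polarization not in ("linear", "circular"):
            raise ValueError(f"unknown polarization {self.polarization!r}")
        if self.nu2_scale is None:
            object.__setattr__(self, "nu2_scale", 1.0 / self.tau_p)

    @property
    def n_points(self) -> int:
        return int(round(self.tau_p / self.dt))


def selective_field_at(spec: SelectivePulseSpec, t):
    """Continuous-time Cartesian field (x, y, offset) of the selective pulse, Hz.

    Pure function of t; `make_b1_selective_pulse` samples it at the midpoint
    of each dwell interval, so waveforms built at different dwell times are
    samplings of one and the same underlying field.
    """
    t = np.asarray(t, float)
    b = spec.envelope(t / spec.tau_p)
    mod = np.cos(2.0 * np.pi * spec.nu_mod * t)
    x = np.full_like(t, spec.nu_sl)
    if spec.polarization == "linear":
        y = 2.0 * spec.nu2_scale * b * mod
        off = np.zeros_like(t)
    else:
        y = spec.nu2_scale * b * mod
        off = spec.nu2_scale * b * np.sin(2.0 * np.pi * spec.nu_mod * t)
    return x, y, off


def make_b1_selective_pulse(spec: SelectivePulseSpec) -> ShapedPulse:
    """Build the B1-selective shaped pulse from its spec.

    Point k covers [k*dt, (k+1)*dt) and is evaluated at the interval
    midpoint (midpoint sampling halves the first-order discretization bias
    of piecewise-constant waveforms).
    """
    if spec.nu_mod * spec.dt > 0.25:
        log.warning(
            "dt = %.3g s gives fewer than 4 points per modulation period at "
            "nu_mod = %.3g Hz; the co-rotating decomposition degrades",
            spec.dt,
            spec.nu_mod,
        )
    tm = (np.arange(spec.n_points) + 0.5) * spec.dt
    x, y, off = selective_field_at(spec, tm)
    amp, phase = cartesian_to_amp_phase(x, y)
    track = off if spec.polarization == "circular" else None
    return ShapedPulse(dt=spec.dt, amplitude=amp, phase_deg=phase, offset_track=track)


def constant_pulse(amplitude_hz: float, phase_deg: float, duration: float, dt: float) -> ShapedPulse:
    """Constant-amplitude, constant-phase pulse (e.g. a plain spin lock)."""
    n = int(round(duration / dt))
    if not math.isclose(n * dt, duration, rel_tol=1e-9):
        raise ValueError("duration must be an integer multiple of dt")
    return ShapedPulse(
        dt=dt,
        amplitude=np.full(n, float(amplitude_hz)),
        phase_deg=np.full(n, float(phase_deg) % 360.0),
    )
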