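"""Inversion profiles of B1-selective pulses versus rf-field amplitude.

Sweeping the actual rf amplitude nu1 while keeping the programmed waveform
fixed emulates a nutation-frequency scan across the rf-inhomogeneity
distribution.  Two sweep modes are provided:

``scaled``
    The entire programmed waveform (spin lock and selective component alike)
    is multiplied by s = nu1 / nu_sl, as happens physically when a sample
    region experiences a different B1: the selective amplitude becomes
    ``nu2 * nu1 / nu_mod`` and acquires a flip-angle error away from the
    band center.
``ideal``
    Only the spin-lock component scales with s while the selective component
    is held at its nominal amplitude, emulating a hypothetical perfectly
    calibrated inversion pulse at every nu1.  The difference between the two
    modes measures how well the envelope compensates rf amplitude missetting
    (small for I-BURP-2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._rotations import propagate_fields
from .shapes import SelectivePulseSpec, make_b1_selective_pulse

__all__ = ["InversionProfile", "BandMetrics", "inversion_profile", "band_metrics"]


@dataclass(frozen=True)
class InversionProfile:
    """Final <Ix> of spin-locked magnetization over a grid of rf amplitudes."""

    nu1_grid: np.ndarray
    ix_final: np.ndarray
    mode: str
    spec: SelectivePulseSpec

    def __post_init__(self):
        g = np.asarray(self.nu1_grid, float)
        v = np.asarray(self.ix_final, float)
        if g.ndim != 1 or g.shape != v.shape:
            raise ValueError("grid and values must be 1-D and of equal length")
        if g.size > 1 and np.any(np.diff(g) <= 0):
            raise ValueError("nu1 grid must be strictly ascending")
        if v.size and (v.min() < -1 - 1e-9 or v.max() > 1 + 1e-9):
            raise ValueError("<Ix> outside [-1, 1]")
        object.__setattr__(self, "nu1_grid", g)
        object.__setattr__(self, "ix_final", v)

    def to_text(self, path) -> None:
        """Two-column export: nu1 [Hz], <Ix>."""
        np.savetxt(path, np.column_stack([self.nu1_grid, self.ix_final]),
                   fmt="%.6f", header="nu1_Hz Ix")


@dataclass(frozen=True)
class BandMetrics:
    """Zero-crossing metrics of the inversion region.

    ``center`` is the midpoint between the zero crossings bounding the
    contiguous <Ix> < 0 run that contains the global minimum; ``width`` the
    distance between those crossings; ``depth`` the global minimum;
    ``max_artefact`` the largest deviation |1 - <Ix>| outside the band
    widened by one bandwidth on each side.  A profile with no inverted
    points reports width 0 and a NaN center (``inverted`` False).
    """

    center: float
    width: float
    depth: float
    max_artefact: float
    inverted: bool = True


def inversion_profile(
    spec: SelectivePulseSpec,
    nu1_min: float = 10e3,
    nu1_max: float = 150e3,
    step: float = 100.0,
    mode: str = "scaled",
    initial_state=(1.0, 0.0, 0.0),
) -> InversionProfile:
    """Sweep rf amplitude and record the final <Ix> after the selective pulse."""
    if mode not in ("scaled", "ideal"):
        raise ValueError(f"unknown sweep mode {mode!r}")
    if not (nu1_min < nu1_max):
        raise ValueError("nu1_min must be < nu1_max")
    if step <= 0:
        raise ValueError("step must be positive")
    grid = np.arange(nu1_min, nu1_max + step / 2.0, step)
    pulse = make_b1_selective_pulse(spec)
    x, y = pulse.cartesian()
    track = pulse.offset_track if pulse.offset_track is not None else np.zeros(pulse.n_points)
    s = grid / spec.nu_sl
    wx = np.outer(x, s)
    if mode == "scaled":
        wy = np.outer(y, s)
        wz = np.outer(track, s)
    else:
        wy = np.broadcast_to(y[:, None], wx.shape)
        wz = np.broadcast_to(track[:, None], wx.shape)
    M = propagate_fields(wx, wy, wz, pulse.dt, np.asarray(initial_state, float))
    return InversionProfile(nu1_grid=grid, ix_final=M[:, 0], mode=mode, spec=spec)


def band_metrics(profile: InversionProfile) -> BandMetrics:
    """Locate the inversion band and measure its center, width and artefacts."""
    nu1 = profile.nu1_grid
    ix = profile.ix_final
    if nu1.size == 0:
        raise ValueError("empty profile")
    imin = int(np.argmin(ix))
    if ix[imin] >= 0:
        return BandMetrics(
            center=float("nan"), width=0.0, depth=float(ix[imin]),
            max_artefact=float(np.max(np.abs(1.0 - ix))), inverted=False,
        )
    lo = imin
    while lo > 0 and ix[lo - 1] < 0:
        lo -= 1
    hi = imin
    while hi < ix.size - 1 and ix[hi + 1] < 0:
        hi += 1

    def crossing(i, j):
        return nu1[i] + (0.0 - ix[i]) * (nu1[j] - nu1[i]) / (ix[j] - ix[i])

    left = crossing(lo - 1, lo) if lo > 0 else nu1[0]
    right = crossing(hi, hi + 1) if hi < ix.size - 1 else nu1[-1]
    center = 0.5 * (left + right)
    width = right - left
    outside = (nu1 < center - width) | (nu1 > center + width)
    max_art = float(np.max(np.abs(1.0 - ix[outside]))) if outside.any() else 0.0
    return BandMetrics(
        center=float(center), width=float(width), depth=float(ix[imin]),
        max_artefact=max_art, inverted=True,
    )
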