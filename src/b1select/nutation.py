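"""Nutation experiments over a synthetic rf-field-amplitude distribution.

The 2D nutation experiment measures the rf-inhomogeneity profile of a probe:
after an optional B1-selective inversion in the spin-lock frame, the
magnetization nutates about the rf field during t1 and a z-filter selects
the cosine component, so the detected signal is a weighted superposition of
cosines at the nutation frequencies nu1 present in the sample,

    S(k * dwell) = sum_nu1  p(nu1) * w(nu1) * cos(2*pi*nu1*k*dwell).

Acquisition modes differ only in the selection weights w(nu1):

plain        w = 1                        (no selective pulse)
selected     w = <Ix> after the pulse     (inverted band carries w ~ -1)
difference   w = 1 - <Ix>                 (two scans, receiver inverted on
                                           the second; a fully inverted
                                           slice carries weight 2, an
                                           untouched slice 0)

By linearity, plain = selected + difference, signal-wise and spectrum-wise.

Sample regions off the rotor axis additionally see a periodic amplitude and
phase modulation of the rf field under magic-angle spinning; the optional
``MasModulation`` propagates that fraction of the distribution explicitly
through the spin engine and produces modulation bands at multiples of the
rotor frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import stats

from ._rotations import propagate_fields
from .shapes import SelectivePulseSpec, make_b1_selective_pulse
from .engine import propagate_batch

__all__ = [
    "MasModulation",
    "RfDistribution",
    "NutationResult",
    "make_rf_distribution",
    "selection_weights",
    "simulate_nutation",
    "process_spectrum",
    "cosine_squared_window",
    "nutation_spectral_width",
    "pi_pulse_rf_field",
]


@dataclass(frozen=True)
class MasModulation:
    """Rotor-synchronous rf amplitude/phase modulation parameters.

    rotor_freq_hz:
        Spinning frequency; modulation bands appear at its multiples.
    amp_mod_depth:
        Relative amplitude-modulation depth in [0, 1).
    phase_mod_rad:
        Peak rf phase excursion in radians.
    fraction_modulated:
        Fraction of the distribution's weight that experiences the
        modulation, in [0, 1].
    """

    rotor_freq_hz: float
    amp_mod_depth: float = 0.1
    phase_mod_rad: float = 0.0
    fraction_modulated: float = 1.0

    def __post_init__(self):
        if self.rotor_freq_hz <= 0:
            raise ValueError("rotor frequency must be positive")
        if not (0 <= self.amp_mod_depth < 1):
            raise ValueError("amp_mod_depth must be in [0, 1)")
        if not (0 <= self.fraction_modulated <= 1):
            raise ValueError("fraction_modulated must be in [0, 1]")


@dataclass(frozen=True)
class RfDistribution:
    """Probability weights over a grid of rf amplitudes nu1.

    ``gain_offset_hz`` rigidly shifts the whole distribution and emulates a
    slow drift of the rf-amplifier gain between scans; it defaults to 0 and
    is not part of any shipped fixture.
    """

    kind: str
    grid: np.ndarray
    weights: np.ndarray
    mode_hz: float
    mas_modulation: Optional[MasModulation] = None
    gain_offset_hz: float = 0.0

    def __post_init__(self):
        g = np.asarray(self.grid, float)
        w = np.asarray(self.weights, float)
        if g.size == 0:
            raise ValueError("empty nu1 grid")
        if g.ndim != 1 or g.shape != w.shape:
            raise ValueError("grid and weights must be 1-D and of equal length")
        if g.size > 1 and np.any(np.diff(g) <= 0):
            raise ValueError("nu1 grid must be strictly ascending")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "weights", w)

    def with_modulation(self, mod: MasModulation) -> "RfDistribution":
        return replace(self, mas_modulation=mod)

    @property
    def effective_grid(self) -> np.ndarray:
        return self.grid + self.gain_offset_hz


def make_rf_distribution(
    kind: str,
    mode_hz: float,
    width_hz: float = 8e3,
    skew: float = 0.0,
    grid: Optional[np.ndarray] = None,
) -> RfDistribution:
    """Build a synthetic rf-amplitude distribution on a nu1 grid.

    ``parametric`` evaluates a skew-normal weight function whose mode (most
    probable nu1) is placed at ``mode_hz``; negative ``skew`` produces the
    low-field tail typical of solenoid-coil B1 maps.  ``delta`` puts all
    weight on the grid point nearest ``mode_hz``.
    """
    if grid is None:
        grid = np.arange(10e3, 150e3 + 1.0, 1e3)
    grid = np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("empty nu1 grid")
    if kind == "delta":
        w = np.zeros(grid.size)
        w[int(np.argmin(np.abs(grid - mode_hz)))] = 1.0
    elif kind == "parametric":
        if width_hz <= 0:
            raise ValueError("width_hz must be positive")
        # place the skew-normal mode (not its loc) at mode_hz
        z = np.linspace(-4, 4, 8001)
        m0 = z[np.argmax(stats.skewnorm.pdf(z, skew))]
        w = stats.skewnorm.pdf((grid - mode_hz) / width_hz + m0, skew)
        tot = w.sum()
        if tot <= 0:
            raise ValueError("distribution has no support on the grid")
        w = w / tot
    else:
        raise ValueError(f"unknown distribution kind {kind!r}")
    return RfDistribution(kind=kind, grid=grid, weights=w, mode_hz=float(mode_hz))


def histogram_distribution(grid, weights, mode_hz: Optional[float] = None) -> RfDistribution:
    """Wrap externally obtained (e.g. measured or seeded) weights."""
    w = np.asarray(weights, float)
    w = w / w.sum()
    g = np.asarray(grid, float)
    if mode_hz is None:
        mode_hz = float(g[np.argmax(w)])
    return RfDistribution(kind="histogram", grid=g, weights=w, mode_hz=mode_hz)


def selection_weights(
    spec: SelectivePulseSpec, dist: RfDistribution, mode: str = "difference"
) -> np.ndarray:
    """Per-nu1 acquisition weights for the chosen mode.

    The selective pulse is propagated at scaled amplitude (the whole
    waveform multiplied by nu1/nu_sl) for every grid point of the
    distribution, exactly as rf inhomogeneity scales it in the probe.
    """
    if mode == "plain":
        return np.ones(dist.grid.size)
    if mode not in ("selected", "difference"):
        raise ValueError(f"unknown acquisition mode {mode!r}")
    pulse = make_b1_selective_pulse(spec)
    scales = dist.effective_grid / spec.nu_sl
    ix = propagate_batch(pulse, scales)[:, 0]
    return ix if mode == "selected" else 1.0 - ix


def _modulated_nutation(dist: RfDistribution, t1_points: int, dwell: float) -> np.ndarray:
    """<Ix>(k) per grid nu1 under rotor-modulated rf, shape (t1_points, B)."""
    mod = dist.mas_modulation
    assert mod is not None
    sub = max(1, int(np.ceil(dwell * mod.rotor_freq_hz * 16)))
    dt = dwell / sub
    T = (t1_points - 1) * sub
    t = (np.arange(T) + 0.5) * dt
    nu1 = dist.effective_grid[None, :]
    amp = nu1 * (1.0 + mod.amp_mod_depth * np.cos(2.0 * np.pi * mod.rotor_freq_hz * t))[:, None]
    psi = mod.phase_mod_rad * np.cos(2.0 * np.pi * mod.rotor_freq_hz * t)[:, None]
    # rf nominally along y; phase modulation tilts it in the xy plane
    wx = -amp * np.sin(psi) * np.ones_like(nu1)
    wy = amp * np.cos(psi) * np.ones_like(nu1)
    wz = np.zeros_like(wx)
    traj = propagate_fields(wx, wy, wz, dt, np.array([1.0, 0.0, 0.0]), record_stride=sub)
    return traj[:, :, 0]


@dataclass(frozen=True)
class NutationResult:
    """t1 signal and processed one-sided spectrum of a nutation run."""

    t1_signal: np.ndarray
    dwell: float
    freq_hz: np.ndarray
    spectrum: np.ndarray
    acquisition_mode: str


def simulate_nutation(
    dist: RfDistribution,
    weights: np.ndarray,
    t1_points: int = 512,
    dwell: float = 3.5e-6,
    acquisition_mode: str = "plain",
    zero_fill_to: Optional[int] = None,
    apodization: str = "cosine_squared",
) -> NutationResult:
    """Simulate the t1 nutation signal and process it into a spectrum.

    The z-filter of the experiment is modelled as exact selection of the
    cosine component, so the unmodulated part of the signal is the weighted
    cosine sum over the distribution grid (deterministic quadrature, no
    sampling).  Any rotor-modulated fraction is propagated explicitly.
    """
    if t1_points < 2:
        raise ValueError("t1_points must be >= 2")
    w = np.asarray(weights, float)
    if w.shape != dist.grid.shape:
        raise ValueError("weights must align with the distribution grid")
    k = np.arange(t1_points)
    plain = np.cos(2.0 * np.pi * np.outer(k * dwell, dist.effective_grid))  # (T, B)
    p = dist.weights * w
    mod = dist.mas_modulation
    if mod is not None and mod.fraction_modulated > 0:
        mod_ix = _modulated_nutation(dist, t1_points, dwell)
        sig = (1.0 - mod.fraction_modulated) * plain @ p + mod.fraction_modulated * mod_ix @ p
    else:
        sig = plain @ p
    freq, spec = process_spectrum(sig, dwell, zero_fill_to=zero_fill_to, apodization=apodization)
    return NutationResult(
        t1_signal=sig, dwell=dwell, freq_hz=freq, spectrum=spec, acquisition_mode=acquisition_mode
    )


def cosine_squared_window(n: int) -> np.ndarray:
    """cos^2(pi*k / (2*(n-1))) apodization window, 1 at k=0 to 0 at k=n-1."""
    if n < 2:
        return np.ones(n)
    k = np.arange(n)
    return np.cos(np.pi * k / (2.0 * (n - 1))) ** 2


def process_spectrum(
    signal: np.ndarray,
    dwell: float,
    zero_fill_to: Optional[int] = None,
    apodization: str = "cosine_squared",
    return_complex: bool = False,
):
    """Window, zero-fill and Fourier transform a real t1 signal.

    Returns a one-sided frequency axis [0, 1/(2*dwell)] and the real
    (absorptive) part of the transform; the acquisition is a pure cosine
    series, so the cosine-component spectrum is real.  The first point is
    halved before the transform (standard first-point scaling: the t=0
    sample is shared between the positive- and negative-time halves of the
    cosine series) to avoid a constant baseline offset.  Set
    ``return_complex`` to obtain the full complex transform instead.
    """
    sig = np.array(signal, float)
    n = sig.size
    if zero_fill_to is None:
        zero_fill_to = max(4096, n)
    if zero_fill_to < n:
        raise ValueError("zero_fill_to must be >= signal length")
    if apodization == "cosine_squared":
        sig = sig * cosine_squared_window(n)
    elif apodization != "none":
        raise ValueError(f"unknown apodization {apodization!r}")
    if n:
        sig[0] = 0.5 * sig[0]
    padded = np.zeros(zero_fill_to)
    padded[:n] = sig
    spec = np.fft.rfft(padded)
    freq = np.fft.rfftfreq(zero_fill_to, dwell)
    return (freq, spec) if return_complex else (freq, spec.real)


def nutation_spectral_width(dwell_s: float) -> float:
    """Spectral width (Hz) of a nutation acquisition with the given dwell."""
    if dwell_s <= 0:
        raise ValueError("dwell must be positive")
    return 1.0 / dwell_s


def pi_pulse_rf_field(tau_pi_s: float) -> float:
    """rf amplitude (Hz) indicated by the zero crossing of a pi pulse of given length."""
    if tau_pi_s <= 0:
        raise ValueError("pulse length must be positive")
    return 1.0 / (2.0 * tau_pi_s)
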