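"""Deterministic generators of synthetic test inputs.

Every fixture is a pure function of (name, seed, parameters); the registry
maps names to builders.  The shipped distributions emulate qualitative
features of measured probe B1 maps (a skewed single-mode amplitude
distribution peaking above the nominal calibration, rotor-synchronous
modulation of off-axis sample regions) without reproducing any particular
hardware.
"""

from __future__ import annotations

import numpy as np

from .envelopes import BaseEnvelope, iburp2_envelope
from .nutation import MasModulation, RfDistribution, histogram_distribution, make_rf_distribution

__all__ = ["fixture", "fixture_names"]


def _delta_100k(seed: int, params: dict) -> RfDistribution:
    grid = params.get("grid", np.arange(10e3, 150e3 + 1.0, 1e3))
    return make_rf_distribution("delta", params.get("mode_hz", 100e3), grid=grid)


def _probe_1p9mm_like(seed: int, params: dict) -> RfDistribution:
    """Skewed single-mode distribution peaking at 109 kHz, low-field tail."""
    return make_rf_distribution(
        "parametric",
        mode_hz=params.get("mode_hz", 109e3),
        width_hz=params.get("width_hz", 8e3),
        skew=params.get("skew", -4.0),
        grid=params.get("grid", np.arange(60e3, 150e3 + 1.0, 500.0)),
    )


def _mas_modulated_30k(seed: int, params: dict) -> RfDistribution:
    base = _delta_100k(seed, params)
    return base.with_modulation(
        MasModulation(
            rotor_freq_hz=params.get("rotor_freq_hz", 30e3),
            amp_mod_depth=params.get("amp_mod_depth", 0.1),
            phase_mod_rad=params.get("phase_mod_rad", 0.0),
            fraction_modulated=params.get("fraction_modulated", 1.0),
        )
    )


def _histogram_noisy(seed: int, params: dict) -> RfDistribution:
    """Seeded jittered histogram; exercises reproducibility of seeded fixtures."""
    rng = np.random.default_rng(seed)
    grid = params.get("grid", np.arange(80e3, 120e3 + 1.0, 1e3))
    base = np.exp(-0.5 * ((grid - params.get("mode_hz", 100e3)) / params.get("width_hz", 6e3)) ** 2)
    noisy = base * rng.uniform(0.8, 1.2, grid.size)
    return histogram_distribution(grid, noisy)


def _iburp2(seed: int, params: dict) -> BaseEnvelope:
    return iburp2_envelope()


_REGISTRY = {
    "delta_100k": _delta_100k,
    "probe_1p9mm_like": _probe_1p9mm_like,
    "mas_modulated_30k": _mas_modulated_30k,
    "histogram_noisy": _histogram_noisy,
    "iburp2": _iburp2,
}


def fixture_names() -> list[str]:
    return sorted(_REGISTRY)


def fixture(name: str, seed: int = 0, params: dict | None = None):
    """Materialize the named fixture; unknown names raise with the registry listing."""
    if name not in _REGISTRY:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(fixture_names())}")
    return _REGISTRY[name](seed, params or {})
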