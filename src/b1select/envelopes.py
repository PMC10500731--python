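"""Dimensionless band-selective inversion envelopes.

An envelope ``B(s)`` on the unit interval is given by a truncated Fourier
series.  Scaled to an rf amplitude ``nu2`` and played over a duration
``tau_p``, it becomes the time-dependent amplitude ``nu2 * B(t / tau_p)`` of
a frequency-band-selective inversion pulse.  The shipped I-BURP-2 table is
normalized so that the on-resonance flip angle of the pulse is
``2*pi*nu2*tau_p * mean(B) = pi`` when ``nu2 = 1/tau_p`` (mean(B) = 1/2).

Any coefficient table with that normalization can be substituted (REBURP,
hyperbolic-secant expansions, ...); only I-BURP-2 ships with the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "BaseEnvelope",
    "iburp2_envelope",
    "load_envelope",
    "zero_envelope",
    "EnvelopeValidation",
    "validate_inversion_envelope",
]


@dataclass(frozen=True)
class BaseEnvelope:
    """Fourier-series envelope B(s), s in [0, 1).

    Parameters
    ----------
    name:
        Identifier of the shape family (e.g. ``"iburp2"``).
    fourier_a:
        Cosine coefficients; index 0 is the constant term a0.
    fourier_b:
        Sine coefficients; index 0 is b1 (there is no constant sine term).
    """

    name: str
    fourier_a: tuple = field(default=(0.0,))
    fourier_b: tuple = field(default=())

    def __post_init__(self):
        if len(self.fourier_a) == 0:
            raise ValueError(f"envelope {self.name!r}: coefficient table is empty")
        object.__setattr__(self, "fourier_a", tuple(float(v) for v in self.fourier_a))
        object.__setattr__(self, "fourier_b", tuple(float(v) for v in self.fourier_b))
        if not all(np.isfinite(self.fourier_a)) or not all(np.isfinite(self.fourier_b)):
            raise ValueError(f"envelope {self.name!r}: non-finite coefficient")

    def __call__(self, s):
        """Evaluate B at fractional position(s) ``s`` (pure function of s)."""
        s = np.asarray(s, dtype=float)
        out = np.full_like(s, self.fourier_a[0])
        for n in range(1, len(self.fourier_a)):
            out = out + self.fourier_a[n] * np.cos(2.0 * np.pi * n * s)
        for n, b in enumerate(self.fourier_b, start=1):
            out = out + b * np.sin(2.0 * np.pi * n * s)
        return out

    def samples(self, n: int) -> np.ndarray:
        """n-point uniform sampling of B on s = k/n, k = 0..n-1."""
        if n <= 0:
            raise ValueError("n must be positive")
        return self(np.arange(n) / n)


def zero_envelope() -> BaseEnvelope:
    """The identically-zero envelope (useful as a negative control)."""
    return BaseEnvelope(name="zero", fourier_a=(0.0,), fourier_b=())


def load_envelope(path) -> BaseEnvelope:
    """Load an envelope from a plain-text key-value file.

    Format: comment lines start with ``#``; ``name <identifier>``,
    ``a a0 a1 ...`` and ``b b1 b2 ...`` records.
    """
    name = None
    a: list | None = None
    b: list = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, *vals = line.split()
        if key == "name":
            name = vals[0] if vals else None
        elif key == "a":
            a = [float(v) for v in vals]
        elif key == "b":
            b = [float(v) for v in vals]
        else:
            raise ValueError(f"{path}: unknown record {key!r}")
    if name is None or not a:
        raise ValueError(f"{path}: missing 'name' or 'a' record")
    return BaseEnvelope(name=name, fourier_a=tuple(a), fourier_b=tuple(b))


def iburp2_envelope() -> BaseEnvelope:
    """The I-BURP-2 inversion envelope shipped with the package."""
    ref = resources.files("b1select").joinpath("data/iburp2.env")
    with resources.as_file(ref) as path:
        if not path.exists():
            raise FileNotFoundError("packaged I-BURP-2 coefficient table is missing")
        return load_envelope(path)


@dataclass(frozen=True)
class EnvelopeValidation:
    """Result of the simulation gate run by `validate_inversion_envelope`."""

    passed: bool
    ix_final: float
    threshold: float
    tau_p: float


def validate_inversion_envelope(
    env: BaseEnvelope,
    tau_p: float,
    nu_sl: float = 100e3,
    nu_mod: float = 100e3,
    dt: float = 1e-6,
    threshold: float = -0.98,
) -> EnvelopeValidation:
    """Simulation gate: does the envelope invert across the band interior?

    Builds the selective pulse at ``nu2 = 1/tau_p`` and propagates
    spin-locked magnetization (1, 0, 0) at rf amplitudes nu_mod and
    nu_mod +- 1/tau_p (band interior; the whole waveform scales with the
    amplitude, as in a real probe).  Passes iff <Ix> <= ``threshold`` at
    all three.  The on-resonance point alone cannot catch coefficient
    transcription errors -- the on-resonance flip angle depends only on the
    envelope mean -- whereas the band-interior points collapse for corrupted
    tables.
    """
    from .engine import propagate_batch
    from .shapes import SelectivePulseSpec, make_b1_selective_pulse

    if tau_p <= 0:
        raise ValueError("tau_p must be positive")
    spec = SelectivePulseSpec(
        nu_sl=nu_sl, nu_mod=nu_mod, tau_p=tau_p, dt=dt, nu2_scale=1.0 / tau_p, envelope=env
    )
    pulse = make_b1_selective_pulse(spec)
    probes = np.array([nu_mod - 1.0 / tau_p, nu_mod, nu_mod + 1.0 / tau_p])
    ix = propagate_batch(pulse, probes / nu_sl)[:, 0]
    return EnvelopeValidation(
        passed=bool(np.all(ix <= threshold)), ix_final=float(ix[1]), threshold=threshold, tau_p=tau_p
    )
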