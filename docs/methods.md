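# Methods

## Physical model

All simulations treat a single spin-1/2 without relaxation, for which the
density operator is equivalent to a classical unit magnetization vector
**M**.  Shaped rf is piecewise constant: during shape point *k* the
rotating-frame Hamiltonian is the static field

&nbsp;&nbsp;&nbsp;&nbsp;**w**_k = 2π ( s·a_k cos φ_k, s·a_k sin φ_k, Δν + s·o_k )

with amplitude a_k (Hz), phase φ_k, resonance offset Δν, optional per-point
offset track o_k, and dimensionless rf-inhomogeneity scale
s = ν1,actual / ν1,nominal.  Each point applies the exact axis–angle
(Rodrigues) rotation by 2π|**w**_k|dt; rotations are composed in order.
Because the waveform is exactly piecewise constant, this propagation is
exact — subdividing a point is a no-op, which the test suite exploits as a
consistency oracle, and the norm of **M** is conserved to <1e-9 over 1e5
slices.

## B1-selective pulses in the spin-lock frame

A band-selective inversion envelope B(s), s ∈ [0, 1), defined by a Fourier
series (shipped: I-BURP-2, transcribed coefficient table in
`data/iburp2.env`), is played along y on top of a constant spin-lock field
ν_SL along x:

&nbsp;&nbsp;&nbsp;&nbsp;x(t) = ν_SL,&nbsp;&nbsp; y(t) = 2 ν₂ B(t/τ_p) cos(2π ν_mod t).

In the frame rotating about x at ν_mod, the co-rotating half of the y field
is a band-selective pulse of amplitude ν₂B acting on an effective offset
ν₁ − ν_mod: spins are inverted when their nutation frequency ν₁ (i.e. their
local B1) lies within the envelope's bandwidth of ν_mod.  The factor 2
compensates the co-/counter-rotating split of the linear-polarized field;
with `polarization="circular"` the counter-rotating half is never produced
(y carries ν₂B cos, a synchronous resonance-offset track carries ν₂B sin),
which avoids Bloch–Siegert shifts when ν₂ is not ≪ ν_SL.

Conventions: the modulation is a cosine with phase zero at the pulse start
(the choice only rotates the selective pulse's axis in the interaction
frame, not the magnitude of the inversion profile); the envelope is
normalized so that mean(B) = 1/2, making the on-resonance flip angle π at
ν₂ = 1/τ_p; shape point *k* covers [k·dt, (k+1)·dt) and is evaluated at the
interval midpoint, which halves the first-order discretization bias of
piecewise-constant waveforms.  `samples(n)` of an envelope, by contrast,
uses the left-edge grid k/n so that resampling at 2n and decimating
reproduces it exactly.

The coefficient table is guarded by a simulation gate
(`validate_inversion_envelope`): the pulse must invert (⟨Ix⟩ ≤ −0.98) at
rf amplitudes ν_mod and ν_mod ± 1/τ_p.  The band interior matters: the
on-resonance flip angle depends only on the envelope mean, so a center-only
check cannot detect sign errors in individual harmonics, whereas the
band-interior points collapse for every corruption of a dominant
coefficient.

## Inversion profiles and band metrics

`inversion_profile` sweeps the actual rf amplitude (default 10–150 kHz in
100 Hz steps) and propagates spin-locked magnetization through the pulse.
In `scaled` mode the whole waveform is multiplied by s (physical
rf-inhomogeneity semantics, effective ν₂ = (1/τ_p)(ν₁/ν_mod)); in `ideal`
mode only the spin-lock component scales while the selective component is
pinned at its nominal amplitude.  The two differ by at most ~0.02 in ⟨Ix⟩
for the 1 ms pulse — the rf-amplitude error compensation built into
I-BURP-2.

`band_metrics` defines the inversion region as the contiguous ⟨Ix⟩ < 0 run
containing the global minimum; the width is the distance between the
linearly interpolated zero crossings bounding that run, the center their
midpoint, and the artefact level the largest |1 − ⟨Ix⟩| outside the band
widened by one width on each side.  Measured time–bandwidth product of the
zero-crossing span for the shipped I-BURP-2 table: width·τ_p ≈ 5.8,
constant to <5% across τ_p from 200 µs to 2 ms (5.80 kHz at 1 ms, 11.63 kHz
at 500 µs, 29.53 kHz at 200 µs).  The widely quoted ~4/τ_p bandwidth of
I-BURP-2 refers to the deeply inverted core of the band (the ≥90%-inversion
region spans ≈4.8–5.0/τ_p here); the zero-crossing span necessarily
includes the transition wings and is systematically larger.  Both numbers
are honest readings of the same profile; this package reports the
zero-crossing span because it is grid-robust and threshold-free.

## Nutation pipeline

The 2D nutation experiment is modelled as exact selection of the cosine
component after t1 (the z-filter of the sequence; exact for a relaxation-
free single spin), so the unmodulated signal is the deterministic
quadrature S(k·dwell) = Σ p(ν₁) w(ν₁) cos(2π ν₁ k·dwell) over the
distribution grid — no Monte-Carlo anywhere.  Acquisition weights:
plain w = 1; selected w = ⟨Ix⟩ after the scaled selective pulse;
difference w = 1 − ⟨Ix⟩ (two scans, receiver inverted on the second, so a
fully inverted slice carries weight 2).  By linearity,
plain = selected + difference holds exactly, signal- and spectrum-wise.

Synthetic rf distributions are parametric skew-normal weight functions with
the mode placed at the requested ν₁ (defaults: mode 109 kHz, width 8 kHz,
skew −4 for the "1.9 mm probe-like" fixture — a single-mode distribution
peaking ~9% above the nominal 100 kHz calibration with a low-field tail,
the qualitative signature of solenoid-coil B1 maps).  They emulate the
shape of real probe distributions but none of their spatial structure,
temperature dependence, or amplifier-gain drift (a constant
`gain_offset_hz` lets users emulate the latter's 1–2 kHz shifts).  Passing
tests therefore validate the selection physics, not any particular
hardware.

Rotor-synchronous modulation of off-axis sample regions is modelled as
ν₁(t) = ν₁(1 + depth·cos(2π ν_r t + φ)) with an optional rf phase
excursion, propagated explicitly (16 sub-slices per rotor period); it
produces modulation bands at multiples of ν_r.  The experimental
disappearance of these bands from difference sub-spectra is *not* modelled
(its mechanism is an open question); in this model they persist unless the
modulated fraction is zeroed for selected scans.

Processing: cosine-squared apodization cos²(πk/(2(N−1))), first point
halved (standard first-point scaling — the t = 0 sample is shared between
the positive- and negative-time halves of the cosine series; omitting it
leaves a flat baseline offset), zero filling (default 4096), real FFT,
one-sided axis [0, 1/(2·dwell)].

## FSLG shapes and lineshapes

The FSLG cycle is a constant-amplitude phase-ramp shape: amplitude
ν₁ = ν_eff sin θ_m, ramp slope ±360·Δ deg/s with Δ = ν_eff cos θ_m,
θ_m = arccos(1/√3).  Defaults follow the 320-point, 50 ns, 16 µs cycle
(ν_eff = 125 kHz).  The second half ramps down starting at the accumulated
phase of the first half plus 180°.  This phase continuity is load-bearing:
it makes the two half-cycle propagators exact inverses at zero chemical-
shift offset (the cycle closes to machine precision for *any* rf
amplitude), and it makes the first-order chemical-shift rotations of the
two halves add along the tilted axis, giving the scaling factor
cos θ_m = 0.5773.  Restarting the second ramp at an absolute 180° instead
leaves a residual per-cycle rotation and collapses the simulated scaling
factor to ≈0.35 — a convention error that simulation detects immediately.
In the carrier frame each half propagator is a pure z rotation by the
residual ramp phase (207.85° for the default cycle); only the full cycle is
the identity.

`fslg_scaling` propagates transverse magnetization through repeated cycles,
strobes once per cycle, and fits the unwrapped phase in the plane
perpendicular to the cycle rotation axis (sign referred to the axis' z
component).  Projecting on the axis-perpendicular plane rather than the
laboratory xy plane matters: the static component along the tilted axis
dominates Mx + iMy and its elliptical projection biases a raw transverse
phase fit by tens of percent over the <1 precession period that desk-scale
runs cover.  At ±2 kHz offsets and 64 cycles the fitted slope is 0.5773
(cos θ_m + 3e-4); at rf amplitude missed by 10% (phase ramp unchanged — a
phase is immune to rf-amplitude scaling) it moves to 0.6201, the mechanism
behind scaling-factor dispersion in inhomogeneous B1.

`fslg_lineshape` sums stroboscopic single-spin evolutions over an rf
distribution, each slice at rf scale ν₁/ν_nominal with the chemical-shift
offset added.  The initial state is prepared perpendicular to the
nominal-amplitude cycle axis and the component along that preparation axis
is detected (magic-angle preparation plus phase-sensitive acquisition,
yielding pure-absorption spectra): the nominal slice is a pure cosine at
cos θ_m·δ with no carrier-frequency component (<1e-4 of the peak), while
slices with mis-set rf keep a static component along their own tilted axis
and feed the zero-frequency artefact in proportion to the admitted rf
inhomogeneity.  Difference-mode selection weights (from the nutation
pipeline) suppress off-nominal slices; in simulation this reduces both the
carrier artefact and the second moment of the scaled peak, monotonically
with selection-pulse length through {200 µs, 400 µs, 800 µs, 2 ms}.
Dipolar couplings, FSLG supercycles and absolute experimental linewidths
are out of scope — the single-spin-per-ν₁ ensemble captures exactly the two
mechanisms the selection acts on (scaling-factor dispersion and the
carrier artefact), nothing more.

## Numerical choices

- Exact axis–angle rotations everywhere; no small-angle or average-
  Hamiltonian approximations.  Degenerate zero fields rotate about z by a
  zero angle.
- All ν₁ quadratures use the distribution's fixed grid; everything is
  deterministic given fixture seeds.
- Default sweeps: 10–150 kHz in 100 Hz steps (1401 propagations, batched;
  ~0.2 s for the 1 ms pulse).  Lineshape simulations default to 512 t1
  cycles (8.2 ms acquisition, 122 Hz resolution) on a 500 Hz ν₁ grid —
  within the increment counts used on spectrometers and fine enough that
  the apodization-limited linewidth does not mask the dispersion being
  measured.
- Shape files store amplitudes as percent-of-maximum with 6 decimals and
  phases rounded to 6 decimals folded into [0, 360); the absolute maximum
  (Hz) and dwell are kept in comment records, guaranteeing self-round-trip
  to 1e-6 (relative / circular degrees).

## Known limitations

- Single spin-1/2 only: no dipolar or J couplings, no relaxation, no MAS
  dipolar dynamics; experimental linewidths are not predicted.
- Synthetic B1 distributions are stand-ins, not measured maps.
- The MAS-modulation model keeps modulation bands in difference spectra
  (see above).
- The zero-crossing bandwidth of the shipped I-BURP-2 table is ≈5.8/τ_p;
  users planning selections against the ~4/τ_p rule of thumb should expect
  the wider value for the full inversion span and ≈5/τ_p for the deeply
  inverted core.
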