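# Methods

## The measurement model

The assay estimates the apparent permeability *P* of a microvessel wall
from an endpoint pair of images: the tracer-positive ("red") area at the
start of the time-lapse is taken as the lumen footprint `A_diffusion`, and
the area gained by the final frame, converted to moles through the lumen
concentration `C0` and an optical section thickness `h`, gives the molar
flux `J = Δn / (A_diffusion · t)`; Fick's first law with the transmural
gradient approximated by `C0` then yields `P = J / C0`. Algebraically the
estimate collapses to

    P = ΔA · h / (A_init · t)      [µm/min],

so neither `C0` nor the per-pixel area affects it; the implementation
computes this cancelled form (and derives `J`, `Δn` from it) so the
invariance is exact in floating point. `P` is converted to cm/s as
`×10⁻⁴/60`.

**The role of `h`.** A molar quantity cannot be formed from an area and a
concentration alone; the estimator therefore carries an explicit optical
section thickness `h` (default 1 µm) that converts red *area* into sampled
*volume*. The same `h` appears in the generator's front-position identity
(below), so generator and estimator are dimensionally consistent; doubling
`h` doubles the estimate.

**Red rule.** A pixel is tracer-laden iff its red channel strictly exceeds
the threshold *and* strictly exceeds green and blue ("exceeds"/"higher
than" read as strict; ties excluded). A negative area change (bleaching,
drift) yields a negative `P` carried with a `negative_growth` flag rather
than being clamped: it is evidence, not noise.

## Generative physics of the synthetic assay

A straight capillary of diameter `d` held at constant lumen concentration
`C0` leaks through its wall at rate `P_true (C0 − C_wall)` (membrane /
Robin condition) into a quiescent hydrogel with diffusivity `D`. A straight
vessel is translation-invariant along its axis, so the field reduces to the
wall-normal half-space problem

    ∂C/∂t = D ∂²C/∂x²,  −D ∂C/∂x|₀ = P (C0 − C(0,t)),  C(∞,t) = 0.

Two closed forms anchor the tests:

* **constant-flux solution** (flux `J0 = P·C0`):
  `C_cf(x,t) = (J0/D)[√(4Dt/π)·e^(−x²/4Dt) − x·erfc(x/√4Dt)]`, an upper
  bound on the membrane solution, nearly equal to it in the wall-limited
  regime;
* **exact membrane solution** (Carslaw & Jaeger):
  `C_R(x,t)/C0 = erfc(ξ) − e^(κx+κ²Dt)·erfc(ξ+κ√(Dt))`, `ξ = x/√(4Dt)`,
  `κ = P/D`, evaluated through `erfcx` so the exponential never overflows.

The dimensionless group `P√(t/(πD))` measures wall depletion
(`C_wall/C0 = 2P√(t/(πD))` for constant flux); the generator warns when it
exceeds 0.1, because the calibration below assumes membrane-limited
release. At the reference conditions it is 0.0068.

### Numerical scheme

Conservative finite volumes on nodes `x_i = i·dx` (half-width cell at the
wall; membrane flux enters cell 0; far node Dirichlet 0), Crank–Nicolson in
time (`dt = 0.05` min default; unconditionally stable — an explicit scheme
at `dx = 1 µm` would need ~10⁶ steps). The far boundary sits at three
diffusion lengths `3√(4DT)` unless a truncated domain is explicitly
accepted. The mass ledger `M(t) = influx − outflux` (trapezoidal flux
integrals, including the far-sink leak) closes to ~10⁻¹¹ relative because
the scheme is conservative by construction; the solver refuses negative
concentrations and misaligned `dt`. Against the exact membrane closed form
the solution agrees to ~10⁻⁴ relative at `dx = 1 µm`; halving `dx` moves
the final wall concentration by far less than 1%.

A small 2D Crank–Nicolson solver (same wall scheme in x, reflecting ends
along the vessel, ≤ 200×200 nodes) is retained purely as an independent
oracle. Cross-checks run both solvers on the *same* truncated domain
(600 µm, far sink flagged): at 180 min the reference diffusion length
(~2100 µm) dwarfs any such domain, so comparing like-for-like is the only
way the comparison isolates the 2D machinery rather than the truncation.
Agreement is ~0.2% (tolerance 5%).

### Rendering

Profiles are rasterized by each pixel centre's distance to the axis (lumen
within `d/2` gets `C0`; gel pixels interpolate the profile at their wall
distance) and rendered as `red = rint(k·C + bg_mean + N(0, bg_sd))`,
green/blue background-only, clipped to the bit depth. The sensor defaults
(k = 2000 counts/mM, bg 100 ± 5, 16-bit) are plausible confocal-scale
stand-ins, not claims about any instrument. Identical seeds give
bit-identical stacks; the JSON sidecar records FOV, timestamps, the full
scenario (including the planted `P_true`) and the seed, so every stack is
self-describing for tests.

### Reference configuration

One capillary of `d = 7 µm` through the FOV centre, horizontal;
`C0 = 10 mM`; planted `P = 1.154×10⁻⁷ cm/s = 0.069240 µm/min`;
`D = 6000 µm²/min` (≈10⁻⁶ cm²/s, free-solution order for a 10 kDa dextran —
the hydrogel value is not known, and `D` only shapes the synthetic
stand-in, configurable for hindered matrices); `h = 1 µm`; FOV
244.03 × 193.99 µm at 1385 × 1101 px; frames every 5 min for 180 min.

### Threshold calibration

The endpoint estimator is exact when the final red/not-red front sits at

    x* = P·d·t_end / (2h)

from the wall (the band grows on both sides, so
`P_est = 2x*·h/(d·t_end)`). The calibration routine therefore places the
threshold at the rendered intensity of the *exact membrane* profile there:
`min_red = round(bg_mean + k·C_R(x*, t_end))` → 358 counts at reference
conditions (x* = 43.62 µm). The constant-flux form was considered and
rejected for this role: it overshoots `C_R` by `~P√(πt/D)/2` (≈1% here),
and because the profile near `x*` is nearly flat (~0.22 counts/µm), that
1% displaces the front by ~13 µm and biases recovery low by ~30%. With the
exact form, recovered medians sit within 3% of the planted value.

### What the generator does and does not emulate

It reproduces the geometry, physics, sampling and count statistics that the
estimator actually consumes: a wall-limited leak, the pixel grid, frame
cadence, additive sensor noise and quantization. It deliberately omits
confocal optics (PSF, z-extent), photobleaching, vessel curvature and
branching, advection in the gel, autofluorescence structure, and drift.
Passing recovery tests therefore certifies the *estimator pipeline* under
ideal-but-noisy imaging of the stated physics; it does not certify
robustness to the omitted effects, which real data will add.

### Known estimator biases (measured on synthetic data)

* **Noise-flat-profile bias.** Threshold classification under Gaussian
  noise is unbiased only where the mean profile crosses the threshold
  linearly and symmetrically. At low planted `P` (0.5×10⁻⁷ cm/s) the
  profile is so flat that the noise-crossing zone (±σ/|slope| ≈ ±50 µm)
  is truncated by the lumen on one side but extends freely on the other,
  inflating the red count: the recovery grid shows ~+40% there, ~−3% at
  1×10⁻⁷ and ~−2% at 2×10⁻⁷. Monotonicity across planted values is
  unaffected.
* **Count quantization.** One count spans `1/(k·|∂C/∂x|)` of front
  position; at short durations or low gain this dominates (the desk-scale
  unit test raises `k` to 5×10⁴ for exactly this reason).

## Capillary eligibility filter

Components are labelled with 8-connectivity (conventional for thin
structures). Diameter is `2 × median(EDT)` sampled on the morphological
skeleton, scaled by pixel size — robust to end tapering; exact for
even-pixel band widths and biased +1 px for odd widths (the EDT of a
w-pixel band peaks at `⌈(w+1)/2⌉`), an inherent ±1-pixel quantization.
Separation is edge-to-edge: the minimum EDT of the other components'
background sampled on this component, minus one pixel so touching
components read 0. Selection keeps `5 ≤ d ≤ 10 µm` (inclusive bounds) with
separation ≥ 50 µm; a component alone in the mask trivially passes the
separation criterion. Whether a published "diameter" means lumen or outer
wall is assay-dependent; the filter measures the mask it is given.

## Pulse-wave synthesis

Per period (`t_pulse + t_between`): half-cosine upstroke `Q_base → Q_sys`
over `t_rise`, half-cosine decay back over `t_pulse − t_rise`, and a
raised-cosine dip of fractional depth `notch_depth` and width `t_notch_dur`
centred at `t_notch_onset + t_notch_dur/2` multiplied into the decay
envelope — the dicrotic notch; the diastolic gap is flat. This functional
form is this package's own minimal realization of the standard pump knobs
(direction, rise time, pulse duration, gap, notch timing/duration/depth);
defaults follow a 60 beats/min cardiac rhythm (1 s period: 0.15 s rise,
0.6 s pulse, 0.4 s gap, notch at 0.35 s for 0.1 s, depth 0.4, 100 Hz
sampling), reading a "60 Hz cardiac cycle" convention as 60 cycles/min —
a 60 Hz heart rate is not physiological.

A genuine second crest exists only when the notch releases faster than the
decay envelope falls, roughly `notch_depth · π/t_notch_dur >
|amp′|/amp` at the notch — depth ≳ 0.3 with the default timing. Shallower
notches produce a shoulder, not a maximum; no continuous subtractive-dip
waveform can produce two maxima for arbitrarily small depth.

The step scheduler integrates |flow| exactly per sample and emits whole
steps as the accumulated volume crosses multiples of `ul_per_step`,
carrying the remainder; the commanded volume never lags the requested
volume by more than one step volume (the worked example — 60 µL/min for
one minute at 0.5 µL/step — gives exactly 120 steps). Direction is handled
by the sign of the waveform, not the magnitude channel, mirroring
step/direction motor drivers.

## Problem sizes and determinism

Validation runs use the full reference frames (1385 × 1101 px, 37 frames);
recovery suites use 8 replicate seeds (and 3 planted values × 5 seeds for
the monotone grid), about two minutes of compute; unit tests run on a
60 × 50 µm, 5-frame configuration in seconds. Every stochastic step
(rendering noise, random test frames) flows from an explicit seed, and the
pipeline echoes its resolved configuration and seeds beside its outputs so
any result is reproducible from the echo alone.
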