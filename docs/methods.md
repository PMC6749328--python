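# Methods

## Background and scope

Electro-oculography (EOG) measures the standing potential of the eye's
corneo-retinal dipole with skin electrodes around the orbit; rotating the
eyeball changes the potential, so a saccade from one fixation point to
another appears as a step in the raw (DC) signal. Because the DC baseline
drifts with electrode-skin conditions and body movement, practical systems
band-pass the signal ("AC-EOG"): each saccade step then becomes a biphasic
transient that returns to zero, and the amount of eye movement is read off
the integral of the transient. Two channels carry the horizontal (Ch1) and
vertical (Ch2) components; with cross-shaped electrode placements the
recovered 2-D feature cloud is translated, sheared, rotated and
anisotropically scaled relative to the on-screen gaze targets, and a
calibration step must undo that distortion.

`eogcal` implements this pipeline in simulation: a synthetic AC-EOG signal
chain, the threshold-gated integral feature, a nine-parameter
"virtual-origin" affine calibration fitted to 24 gaze-target points
simultaneously, the conventional per-quadrant baseline it is compared
against, and the simulation experiment that contrasts the two. Hardware
drivers, electrode guidance, blink rejection and real-subject data
acquisition are out of scope.

## Signal layer

**DC generator.** A saccade is modeled as a logistic step
`amp * expit(4 (t - onset) / rise_time)` per channel: smooth, two
parameters, and adequate to produce the familiar biphasic AC transient
after band-passing. Blink-like events can be injected as Gaussian
transients of the same width; they contribute to the integral like any
other supra-threshold activity — no rejection is attempted, matching the
measurement convention the feature is defined with. Measurement noise is
zero-mean Gaussian per sample. Defaults: 1 kHz sampling, 20 ms rise time.
A fixed seed makes the generator bit-reproducible; with `noise_sd=0` it is
deterministic regardless of seed.

**Band-pass.** A Butterworth band-pass of order 2 with cut-offs
1.06–4.97 Hz, applied causally (forward only, `sosfilt`), because the
physical chain is an analog causal circuit; zero-phase filtering would be
unfaithful to hardware. The filter blocks DC to well below 1e-3 of the
input level in steady state.

**Threshold-gated integral.** The raw gaze feature of a channel is
`|∫ x dt over {x > th+}| + |∫ x dt over {x < th-}|` with a left-endpoint
Riemann sum at spacing 1/fs (the simplest convention consistent with
sampled hardware integration). The sign is that of the lobe with larger
absolute area, with ties broken by the earlier threshold crossing. Two
numerical consequences are worth noting:

- a signal that never leaves `(th-, th+)` integrates to *exactly* zero (no
  floating-point residue), which is the point of the gating: residual
  noise cannot accumulate;
- a band-pass has zero DC gain, so the positive and negative lobe areas of
  a step response cancel exactly at zero threshold. The gated integral
  therefore only tracks saccade direction when the thresholds sit above
  the bulk of the rebound lobe; with thresholds deep inside both lobes the
  two gated areas nearly tie and the recovered *sign* is fragile, while
  the magnitude remains monotone in the saccade amplitude. Default
  thresholds are noise-referenced, `±3 σ̂` with `σ̂` estimated from a
  designated baseline window (the method's sources state no numeric
  threshold values); explicit values are accepted everywhere.

The mapping from volt·seconds to screen-pixel-like units is a free gain;
the affine calibration absorbs any residual scale, so the gain's value is
immaterial to the final estimate.

## The virtual-origin calibration

The correction applied to a raw feature point `p` is

    u  = R(θ) · Sh(m1, m2) · (p - (Tx, Ty))
    x' = s3·u_x  if u_x ≥ 0,  else  s4·u_x
    y' = s1·u_y  if u_y ≥ 0,  else  s2·u_y

i.e. translation of the virtual origin (an imaginary 25th point estimated
from the data) to the screen center, a shear that restores the
perpendicularity of the measured gaze axes, a rotation onto the screen
axes, and one dilatation factor per semi-axis (+y, −y, +x, −x). Nine
scalars in total; in homogeneous coordinates the composition with a common
(sx, sy) dilatation is the single 3×3 matrix
`[Dilatation][Rotation][Shear][Translation]` that `homogeneous_matrix`
returns in closed form. Boundary points (`u` coordinate exactly 0) take
the positive branch. The dilatation factors are positive, so the piecewise
map is a bijection and has an exact closed-form inverse
(`inverse_proposed`).

### Gauge freedom and the canonical representative

The nine-parameter family is overparametrized by exactly one degree of
freedom: for a positive diagonal `D0` such that `D0^-1 · R·Sh` is again of
rotation-shear form, replacing `R·Sh` by `D0^-1·R'·Sh'` and multiplying
(s3, s4) by `D0_xx` and (s1, s2) by `D0_yy` leaves the piecewise map
pointwise unchanged (dilatations are positive, so branch selection is
also unchanged). Only the gauge orbit of a parameter vector is
identifiable from data — two different-looking parameter sets can encode
the identical calibration.

The gauge-invariant content of (θ, m1, m2) is the pair of raw-space
directions that map onto the +x and +y screen semi-axes. A shear aligns
those directions iff it makes them perpendicular; the
perpendicularity-restoring shears form a conic in the (m1, m2) plane, and
the orientation-preserving branch is exactly `m1·m2 < 1` (the sheared
cross product is `(1 - m1 m2)` times the raw one). The canonical
representative used throughout the package takes

- the *minimal-norm* shear on that conic (the smallest shear that restores
  perpendicular axes), found by Lagrange stationarity, which reduces to
  the real roots of a quartic;
- the rotation that carries the sheared +x direction onto the +x axis;
- the dilatations that absorb the compensating scales.

`canonicalize` maps any parameter vector to this representative without
changing the transformation (verified to machine precision), and
`fit_proposed` reports its result in canonical gauge. Parameter-recovery
statements are made, and tested, in this gauge.

### Fitting

The estimator is a closed-form geometric initialization followed by joint
refinement:

1. **Virtual origin.** The raw images of the x-axis targets are collinear,
   as are those of the y-axis targets, and both lines pass through the
   virtual origin; (Tx, Ty) is the intersection of the two total-least-
   squares lines. (The centroid of all 24 raw points is *not* used: with
   unequal semi-axis dilatations the raw centroid is provably displaced
   from the true origin even on noiseless data.)
2. **Axis directions.** Unit directions toward the +x and +y semi-axes
   from the same on-axis points, oriented by the positive semi-axis
   centroids.
3. **θ, m1, m2** from the canonical minimal-shear alignment of those two
   directions.
4. **Scales** as the per-semi-axis ratio of mean target coordinate to mean
   pre-dilatation coordinate.
5. **Joint refinement** of all nine parameters by Levenberg–Marquardt on
   the 48 pixel residuals, with the four scales log-parametrized to stay
   positive (`xtol=ftol=gtol=1e-15`), followed by canonical gauge
   normalization (the residual surface is flat along the gauge direction,
   so the optimizer may drift along it).

On noiseless data generated by the exact inverse model, the fit reproduces
the generating transformation and (canonical) parameters to ~1e-12. The
fit requires exactly 24 points, a target set symmetric about (0, 0), and
at least two labeled points per semi-axis; near-parallel axis estimates or
degenerate shear geometry raise `CalibrationError`.

## The quadrant baseline

The conventional method splits the 24 points into the four sign-quadrants
of the *raw* coordinates (boundary points go to the positive side) and
fits an independent 7-parameter transform — translation (2), shear (2),
rotation (1), dilatation (2) — per quadrant, 28 parameters in total. The
7-parameter form `D·R·Sh·T` covers the orientation-preserving 2-D affine
family with one spare degree of freedom, so the baseline is fitted as an
unconstrained per-quadrant linear least-squares affine (the exact optimum)
and then decomposed, exactly, into the seven named parameters using the
same minimal-shear convention as above. Two robustness choices:

- the fit solves for the *deviation from the identity map* and truncates
  noise-level singular values (`rcond=1e-10`), so a quadrant whose points
  are collinear (a single target ray) stays at neutral parameters instead
  of blowing up;
- an *empty* quadrant raises `CalibrationError`; a quadrant with one or
  two points is fitted (underdetermined directions stay neutral), because
  under large rotations borderline points routinely change sign-quadrant —
  that polarity disruption is precisely the failure mode the comparison
  experiment measures, and the baseline should degrade there, not abort.

Note that with a symmetric radial grid and a rotation of exactly 45°, each
raw quadrant can happen to mix dilatation branches in only one axis, in
which case the baseline is genuinely exact in the other axis; its error
then shows up on one axis only. Randomized distortions break this
symmetry.

## Simulation experiment and metrics

**Target grid.** 24 points as 8 equally spaced directions (including the
four semi-axes) × 3 eccentricities, 100/200/300 px by default, centered on
(0, 0). This is the only symmetric 24-point radial family that populates
every semi-axis (needed by the dilatation fit) and every quadrant; the
layout is configurable (`n_directions` divisible by 4,
`n_directions × len(eccentricities) = 24`).

**Distortion patterns.** Raw data are produced by pushing the targets
through the exact *inverse* of the piecewise model plus optional isotropic
Gaussian noise, so the proposed fit has a zero-error optimum by
construction and any error it shows is estimation error. Four patterns of
increasing complexity are enforced by validation: (a) dilatation +
rotation, (b) + translation, (c) + shear instead, (d) all four.

**Metrics.** Pixel-distance error is the per-axis absolute error |Δx|,
|Δy| with mean and SD over the 24 points (population SD by default,
`ddof` configurable) — per-axis rather than Euclidean because results are
reported separately per axis. Gaze-angle error converts each axis
coordinate to a visual angle with the exact form
`atan(coordinate · pixel_pitch / distance)` before differencing; defaults
are 35 cm viewing distance and 0.25 mm/px pitch (the pitch is not fixed by
the method's sources and is explicit and overridable).

**Study conditions.** Noiseless-pattern checks draw distortions from
θ ∈ [−60°, 60°], |m1|, |m2| ≤ 0.5, scales ∈ [0.5, 2], |Tx|, |Ty| ≤ 100
(with each pattern's excluded components zeroed). The 45°-rotation
comparison fixes θ = 45° and draws scales ∈ [0.7, 1.4], shear ∈
[−0.2, 0.2], translation ∈ [−50, 50] px over 20 replicates — magnitudes
representative of cross-shaped-electrode distortions. The noise-robustness
check uses raw-space noise of 1, 2 and 5 px over 100 replicates each and
verifies that the mean fitted residual grows at most linearly in the noise
level. These problem sizes run the whole suite in seconds.

## What the synthetic data does and does not show

The generator emulates the geometry of the calibration problem (affine +
piecewise-dilatation distortion, additive feature noise) and the shape of
the signal chain (steps → band-passed transients → gated integrals). It
does not emulate electrode drift, amplitude nonlinearity across
eccentricity, blink statistics, head motion, or inter-subject variability
— so passing tests demonstrate the correctness and the comparative
behavior of the *algorithms* (exact correction where the model family
contains the truth; graceful, at-most-linear degradation under feature
noise; quadrant-method breakdown under rotation), not end-to-end accuracy
on human recordings. Subject-level gaze-angle accuracies can only be
measured with real EOG data, which this package does not ship.

## Known limitations

- The quadrant baseline reconstructs the conventional method from its
  stated parameter count (2+2+1+2 per quadrant) and failure mode; the
  original implementation's exact estimator and step order are not
  published, so absolute baseline error magnitudes depend on these
  choices. The comparative ordering does not.
- The piecewise dilatation makes the model discontinuous in its parameters
  at branch boundaries; points mapped near `u = 0` can in principle switch
  branches during refinement. The on-axis points of a symmetric grid sit
  exactly on branch boundaries and take the positive branch by convention.
- Calibration assumes one feature point per target (a completed
  fixation-saccade cycle); online recalibration, head-movement
  compensation and nonlinear calibration models are out of scope.
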