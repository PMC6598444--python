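# Model and methods

## Overview

`mtpattern` simulates a two-stage rate model of motion processing.  A
stimulus movie (grayscale frames on a white background) drives three V1
populations — direction-selective complex cells, end-stopped cells, and
orientation-selective cells with suppressive extra-classical receptive
fields (ECRF) — whose outputs feed a recurrent MT network of integration and
segmentation units.  The claim the model embodies: whether an MT unit ends up
pattern- or component-selective is set by the relative strength of two of its
V1 inputs, not by a hierarchy within MT.  Unambiguous motion signals exist
only at terminators (line endings and crossings); the network's job is to
let those signals win over the aperture-ambiguous edge signals and spread.

## Units and geometry

Time is a single abstract unit; all rate constants, the Euler step
(dt = 0.01) and the inhibition delay (T_ig = 0.1, i.e. 10 steps) are
expressed in it.  Space is the V1 lattice (one unit per lattice step, one MT
unit per V1 column).  Parameters printed in degrees of visual angle are
converted at `pixels_per_degree = 4`.  This calibration was chosen so that
the canonical bar width (3 steps = 0.75°) exceeds the ECRF centre width: in
that regime the nearly mass-balanced difference-of-Gaussians (centre mass
π·A_C·σ_xc·σ_yc ≈ 0.44, surround π·A_S·σ_xs·σ_ys ≈ 0.45) responds positively
to a single bar but is driven negative where a second bar doubles the local
dark area — which is exactly the suppression at crossings the ECRF population
must exhibit.  At finer calibrations (≥ 8 steps/degree) the same σ values
produce the opposite ordering, so the model's behaviour fixes the scale.

## Stimuli

The generator renders rigidly translating dark bars with hard edges
(positions rounded to the lattice per frame).  The canonical conditions, used
by every experiment and frozen once:

- 64×64 lattice; bar width 3, length 40 (crossing preset) or 60 (occluded
  preset); contrast 1 (dark on white).
- Orientations 135° and 45° from the +x axis, moving right and left at speed
  15 lattice steps per time unit (0.15 steps/frame); their intersection — the
  extrinsic terminator — translates straight upward.
- 30 frames at dt_frame = dt = 0.01.

The speed sits where the junction's upward motion-energy signal clears the
complex-cell threshold c_cx while the trail left by the causal temporal
filters stays short.  Overlaps take the darker luminance (a saturated
plaid); with unequal contrasts the lighter bar is drawn in front.

The occluded-terminator ("pattern") stimulus crops the long-bar movie to a
36×36 window that contains the crossing and excludes all bar endpoints.
Because the frame edge now cuts the bars, a 6-step border margin is treated
as occluded: V1 drive inside it is masked while lateral inhibition still
pools the unmasked field, so the cut ends are hidden rather than seen as new
line endings.  For the same reason all spatial convolutions use replicate
("nearest") boundaries: zero padding would make every frame edge look like a
luminance boundary.

What the generator does not emulate: real plaids (additive gratings),
sub-pixel motion, luminance noise, multiple speeds.  Passing tests show the
network mechanism works on clean, single-speed bar stimuli; they say nothing
about robustness to noise or natural movies.

## V1 front end

**Complex cells.**  Classical opponent motion energy: per contour
orientation a quadrature Gabor pair (carrier along the motion axis,
frequency f = 1.1 cyc/deg, envelope σ = 0.5°), times two biphasic temporal
kernels g_n (n = 6 fast, n = 9 slow, τ_g = 0.01) sampled at the frame
interval.  The four space-time filters combine into energies for the two
opposed directions; opponent subtraction and rectification leave one
non-negative map per direction.  Responses are normalised by the peak
response to a full-contrast calibration bar drifting at the canonical speed,
so complex activity is a bounded quantity in [0, 1] comparable across
stimuli and contrasts.

**End-stopped cells.**  Shunting excitation from the co-located complex cell
minus threshold-gated lateral inhibition.  The inhibition weights form a
discretised Gaussian over a ±12 patch (σ = 6, peak 1/σ) with the inner ±4
gate region excluded.  Two properties matter: the summed weight grows
linearly with patch size, so an extended contour accumulates inhibition
several times the direct drive while remaining bounded; and the central
exclusion keeps a compact terminator blob from inhibiting itself.  The gate
opens wherever same-direction complex activity within ±4 exceeds c_cx = 0.12.
Radii are configurable (`es_inhib_radius`, `es_gate_radius`).

**ECRF cells.**  Memoryless: each frame's reversed intensity is convolved
with the four oriented difference-of-Gaussians kernels and saturated.  Their
output gates the complex signal: κ for direction θ passes only where the
form cell of the orthogonal orientation is active (strict positivity with a
1e-6 tolerance).  κ therefore vanishes at extrinsic terminators.

## MT stage

Both populations are rate units on the V1 lattice, stepped with forward
Euler.  The published equations put the decay term inside the saturation,
`dv/dt = h(...)` with h in [0, 1]; taken literally this makes activity
monotone non-decreasing — inhibition stalls growth rather than erasing it —
and turns regime selection into a race.  The package adopts that literal
reading.

The V1 drives (v_cx, v_es, κ) are pooled over the MT centre RF before
entering the equations: MT receptive fields span 7 V1 lattice steps (the
surround annulus 10), so an MT unit is driven by the Gaussian-weighted V1
population within its centre.  Pooling is what lets terminator signals reach
MT units several steps away.

Lateral terms (all thresholded at c_ig / c_sg):

| term | form |
|------|------|
| λ | same-direction integration activity, centre Gaussian (unit mass × `lambda_mass` = 1.0, self excluded) |
| γ | inter-directional inhibition at the same location, delayed by T_ig; uniform weights normalised over the 7 non-preferred directions (a cosine profile is available via `gamma_weighting`) |
| ζ | long-range same-direction inhibition, surround annulus, delayed; kernel mass `zeta_mass` = 0.1 |
| η | direction-averaged integration activity pooled over the centre (drive onto segmentation) |
| χ_e / χ_i | surround segmentation activity in the same / opposite direction (unit-mass annulus) |

One additional coupling scale, `mt_cx_gain = 0.25`, multiplies the raw
complex-cell drive into the integration units.  It implements the model's
premise directly: the broadly tuned, aperture-ambiguous complex input must
not be able to win the integration race on its own, or terminator signals
could never come to dominate and no gain setting would yield pattern
selectivity.  The form-gated pathway κ is *not* scaled — its strength is the
experimental variable G_igcs.

These kernel scales, together with the uniform γ profile, were calibrated
once against the model's described behaviours (pattern and component regime
maps, monotone gain dependence of the pattern index, contrast dependence,
delayed pattern dominance) and then frozen; they are exposed in the
configuration for sensitivity analyses.

## Simulation protocol

`simulate()` computes the V1 populations per frame (one Euler step per
frame) and, after the movie ends, holds the final V1 fields fixed for
`n_settle = 800` further steps while the end-stopped and MT dynamics
continue.  The movie is short (0.3 time units) relative to the integration
race (several time units); the settle phase is where propagation from the
terminators plays out.  Final maps are the mean over the last 10% of steps.
Runs are deterministic given (movie, config).

## Pattern-index analysis

Desired-activity templates are built from the generating bar geometry at the
final frame: the pattern template is unit activity over the full stimulus
footprint in the upward direction; each component template is unit activity
over one bar's footprint in that bar's aperture direction (up-right for the
135° bar moving right, up-left for the 45° bar moving left).  Footprints are
dilated by the MT centre-RF radius (4 steps): templates describe the MT
population, whose RF smears any idealised map, and without the dilation the
narrow wedges at the crossing would count legitimate junction responses as
off-stimulus.

For each run, deviations are summed absolute differences over the whole
lattice (off-footprint activity counts against a run).  Within one sweep
ensemble the deviations are min-max normalised, giving selectivity levels
S_P and S_C in [0, 1] and the pattern index P_I = S_P − S_C.  The scores are
therefore *relative to the ensemble*: a single run has no meaningful P_I,
and a degenerate ensemble (all deviations equal) is scored S = 1 by
convention and logged.

## Numerical choices

- Forward Euler everywhere, dt = 0.01; states clipped to [0, 1] after each
  step as a safeguard (the shunting/saturated forms already bound them).
- Delay buffer of round(T_ig/dt) = 10 past integration fields, zeros at t=0.
- Replicate boundaries for all spatial convolutions; causal temporal
  filtering with zero history.
- Non-finite activity anywhere aborts the run naming the offending term.

## Limitations

- The time axis is abstract; no claim is made about physiological
  milliseconds (the delayed pattern crossing is ~3 time units under the
  default conditions, but only its existence and ordering are meaningful).
- Monotone (ratchet) dynamics: the literal equations cannot decrease
  activity, so "suppression" always means prevented growth; final maps
  depend on the run length, which is part of the frozen protocol.
- Single speed tuning, four orientations / eight directions, and one
  stimulus family (crossing bars); no integration/segmentation mode
  switching, no MST feedback, no attention.
- The pattern index is ensemble-relative by construction; comparisons are
  valid only within sweeps run under identical conditions.
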