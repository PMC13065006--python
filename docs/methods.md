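# Methods

This note documents the models, conventions and numerical choices behind
`mechwork`, and what the synthetic validation does and does not show.

## Coordinate frame and units

Right-handed court frame: x along the baseline, y forward toward the net
(the sprint axis, origin at the baseline centre), z vertical up.  All
positions in metres, time in seconds, angular velocities in rad/s.  All
energies and work are mass-normalised (J/kg); absolute Joules follow by
multiplying by subject mass.  Gravity is fixed at g = 9.81 m/s².

## Body model

A 14-segment model: merged head+trunk, pelvis, and bilateral
thigh/shank/foot and upper-arm/forearm/hand.  Mass, longitudinal CoM and
principal radius-of-gyration fractions follow the de Leva adjustments of
the Zatsiorsky data, shipped as sex-specific CSV tables
(`mechwork/data/deleva_{male,female}.csv`).  The head and upper/mid trunk
are merged into one segment (their published fractions summed); the lower
trunk is kept as the pelvis.  Products of inertia are neglected — only
principal radii are published — so segment rotational energy is
`½ωᵀIω` with diagonal `I` in the segment principal frame.  The female
fractions as published sum to 0.9999 (rounding); the loader renormalises
every table to sum exactly to 1.  Racket mass is not modelled anywhere,
consistent with the bounding boxes excluding the racket.

## Signal processing

Kinematic streams are smoothed with a zero-lag (forward–backward)
Butterworth low-pass filter, default cutoff 6 Hz.  The quoted "4th order"
is interpreted as the *effective* order after the bidirectional pass
(design order 2 per direction); the alternative reading is available via
`convention="per-pass"`.  Edges are handled by even reflection of up to
one second of signal.  Cutoff selection by residual analysis fits a line
to the RMS residuals of the noise-dominated upper half of the candidate
range, extrapolates it to 0 Hz as the noise estimate, and selects the
smallest candidate whose residual does not exceed it.  Note that with a
noise-free band-limited signal the residual at low cutoffs is dominated
by passband droop (a 1 Hz sinusoid retains ~4% residual at a 2 Hz
cutoff), so the procedure selects a cutoff comfortably above the signal
band rather than the smallest candidate — an inherent property of real
Butterworth responses.

Differentiation uses central differences with second-order one-sided end
stencils (`np.gradient`, `edge_order=2`), exact for quadratics, so
ballistic trajectories conserve energy to machine precision.  Extrema
detection returns strict interior minima/maxima with topographic
prominences; plateaus resolve to their first sample and prominence ties
to the earliest index.

## Work bookkeeping

Positive (negative) work over a section is the sum of increments
(decrements) of the *total* energy series between consecutive samples —
KE and PE are summed before increments are taken, so within-series energy
exchange is not double-counted.  The telescoping identity
`w_pos + w_neg = E_end − E_start` holds to floating-point precision.
Within-limb segment energies are summed **before** increments, then limb
works are summed — within-limb energy transfer is therefore allowed,
between-limb transfer is not.  Work is invariant to horizontal
translation of the origin and to the height datum.

Each captured trial covers one set plus the sprint; per-cycle work is
3 × groundstroke-section work + sprint-section work, assuming the three
sets of a cycle are equivalent.  Set-to-set variability within a cycle is
consequently not represented.

## Event detection

- Serve start: second local minimum of vertical CoM position counting
  strictly backwards from the most prominent peak (top of the serve).
  Minima/maxima with prominence below 0.01 m are ignored so that
  noise-scale wiggles cannot masquerade as countermovement minima.
- Transition into the sprint: last local minimum of resultant CoM speed
  (prominence ≥ 0.3 m/s) before the sprint's peak speed.
- Sprint end: first sample with the CoM ≥ 8.5 m forward of the baseline
  (no interpolation; work integration ends at that sample).

The two prominence floors are the only detection tunables; they sit an
order of magnitude above filtered noise and an order below genuine
protocol features.

## Proxy reconstruction

Ideal pinhole cameras (no lens distortion).  The bounding-box pseudo-CoM
back-projects each camera's box centre as a unit ray from the camera
centre and solves the 3×3 normal equations minimising the summed squared
perpendicular distances.  One outlier pass: rays whose residual exceeds
both the threshold (default 0.15 m) and twice the median residual are
dropped and the solve repeated once — the median guard prevents a single
gross outlier, which biases the first solve, from dragging inliers over
the plain threshold.  Frames seen by fewer than two cameras raise rather
than interpolate.  Proxy trajectories are filtered identically to the CoM
and their potential energy uses the proxy's own height.

## Statistics

Per-player Pearson r relates peak sprint velocity (% of the player's
overall maximum, baseline included) to cumulative positive work of a
variant.  Pooling is a random-effects meta-analysis on the Fisher-z
scale: sampling variance `1/(n−3)`, between-player variance τ² by the
DerSimonian–Laird moment estimator truncated at zero, weights
`1/(1/(n−3)+τ²)`, normal 95% interval back-transformed through tanh.
Players need at least 4 cycles to enter the pool (three cycles still give
a valid per-player r).  Magnitude labels apply strictly-above thresholds
0.5/0.7/0.9 on |r|; boundary values fall to the smaller class.
Negative-work correlations mirror the positive-work results and are
omitted from default reports.

Repeated-measures Bland–Altman: differences (proxy − reference) per trial
are decomposed by one-way random-effects ANOVA into within- and
between-subject components (unbalanced designs use the average-group-size
correction), with limits of agreement `bias ± 1.96·√(sd_w² + sd_b²)` —
the variance-components route is appropriate because the true work
genuinely differs between cycles.  The minimal-detectable-correlation
utility solves `atanh(r)·√(n−3) = z_{1−α/2} + z_power`; for n = 15,
α = 0.05, power = 0.8 this gives r ≈ 0.669.  This is the standard
two-sided Fisher-z solution; other power tools may use different
approximations, and no other value is targeted.

## Synthetic motion generator

Trajectory construction is kinematic (smooth envelopes plus sinusoids),
not dynamic: no ground-reaction forces or muscle model, which suffices
because every downstream computation consumes kinematics only.  Defaults
represent the study conditions: 200 Hz, 30-s trials; feed cadence 2.0 s
(male) / 2.5 s (female); eight alternating groundstrokes as ±2 m lateral
shuttles; a serve modelled as a 0.45 m vertical Gaussian peak over a
2.5 Hz, 2 cm bounce (providing the countermovement minima); a sprint with
a 1.5 s parabolic velocity ramp to the target peak, crossing 8.5 m.
Baseline peak velocity is drawn from N(6.0, 0.5²) m/s (clipped to
4.8–7.2); target cycle counts from N(6.3, 2.2²) clipped to 4–12, from
which each player's fatigue slope follows.

Fatigue is linear: target peak velocity = baseline − slope × cumulative
true total work *including* the current cycle (the sprint follows the
cycle's own sets).  Because the sprint's work depends on its own peak
velocity, the generator solves this with a three-step fixed-point
iteration (contraction rate slope·dW/dv ≈ 6×10⁻³), making velocity
exactly linear in cumulative total work before Gaussian trial noise
(default 0.12 m/s) is added.  Players stop after the first cycle (from
the 4th onward) whose peak falls below 80% of baseline — the
sub-threshold cycle is completed and kept.  In the fully noise-free limit
the measured total-work correlations equal −1 up to discretisation
(<10⁻⁶); the external and proxy variants reach −1 only to ~10⁻³–10⁻⁴
because their work is not exactly proportional to the total work that
drives the fatigue.

Limb segments oscillate relative to the CoM with per-limb common phase
(antiphase across sides) and deterministic amplitudes scaled by a single
calibration constant (`LIMB_AMPLITUDE_SCALE = 0.5`), chosen once so the
internal-work share of total work sits near one third (realised
0.28–0.35 across sexes and fatigue states); limb tempo scales with the
feed cadence.  The mass-weighted mean of all segment offsets is
subtracted every sample, so the segment cloud is exactly consistent with
the prescribed whole-body CoM.  The pelvis proxy adds a slow sway plus a
4.3 Hz, 4–6 mm wobble (below the 6 Hz cutoff, so it survives filtering);
bounding boxes are the image-plane extrema of the projected body
keypoints in an 8-camera rig around the half court, with 1 px observation
noise.  Position noise is 2 mm white, angular-velocity noise 0.05 rad/s.

What passing tests show — and don't.  The generator reproduces the
*structure* the analysis assumes (event morphology, work shares, fatigue
trend, direction of proxy bias); it does not reproduce pose-estimation
artefacts, occlusion, soft-tissue motion, stroke biomechanics, or the
absolute magnitude of the bounding-box inflation (real boxes deform far
more with limb extension than this keypoint cloud does, so the ~+50–80
J/kg per-cycle proxy biases seen here are direction-correct but smaller
than on real data).  Conclusions about estimator correctness,
bookkeeping identities, detection tolerance and statistical calibration
transfer to real data; absolute work magnitudes do so only approximately.

## Problem sizes and determinism

Default analyses use 15-player cohorts (~100 trials); validation suites
use 4–6 players or 30–100 single trials, sizes chosen to exercise every
code path at interactive runtimes.  All randomness flows from one cohort
seed through spawned per-player/per-trial substreams; reports, CSVs and
the manifest are byte-identical across runs with the same seed (floats
are written at fixed precision, JSON keys sorted, trial CSVs at full
precision for lossless round-trips).  Trials failing segmentation are
excluded with a logged reason; a run aborts if more than 20% of trials
are excluded.

## Known limitations

- No lens distortion or camera calibration; the rig is ideal.
- No joint-level work or power, no energy-recovery metrics, no metabolic
  estimation; no stroke classification within the groundstroke block.
- The ×3 set multiplication reproduces the protocol's accounting but
  hides within-cycle variability.
- The linear fatigue model is a deliberate simplification; an exponential
  alternative would change per-player r only marginally at these noise
  levels and is not currently implemented.
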