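# Methods

## The physical loop

A larva at height `h` (mm) above a grating translating at `s` (mm/s) while
swimming at `v(t)` (mm/s) experiences whole-field translational optic flow

    ω(t) = (s − v(t)) / h        [rad/s]

positive when the fish is slower than the stimulus.  Height and stimulus
speed are fixed within a trial, so the feedback gain of the loop is
`dω/dv = −1/h`.  Inertia is neglected relative to viscous friction: the
commanded motor signal is identified with the realized swim speed, with all
proportionality constants absorbed into the intensity gain `k_i`.  The
simulated fish swims in an unbounded channel; the 300 mm walls exist only in
the synthetic-data renderer, where position clips at the channel ends.

Two stimulus procedures are built in.  The *regulation* grid crosses the
three heights (8, 32, 56 mm) with a common speed set, by default
{4, 6, 8, 10, 12} mm/s — the printed design gives only the bounds (4 mm/s
engages the response reliably; above ~12 mm/s a different, faster bout class
appears), so the 2 mm/s spacing between them is this package's choice and is
configurable.  The *constant-baseline-flow* grid holds the at-rest flow
`s/h` at {0.1 … 0.5} rad/s by scaling `s` with height (15 cells, speeds
0.8–28.0 mm/s), which unconfounds baseline flow from feedback gain.

## Perceived spatial frequency under refraction

The grating's nominal frequency (0.0156 cycles/degree at the channel centre)
ignores refraction.  Treating the channel bottom as a flat air/water
interface, a half-period on the screen subtending `θ/2` in air is seen along
an in-water ray `θ_w` satisfying

    half_period = (H − d)·tan θ_a + d·tan θ_w,   sin θ_a = n · sin θ_w

with eye height `H`, water depth below the eye `d` and index `n = 1.33`.
`θ_w` is found by bisection on `(0, asin(1/n))` (the residual is monotone
there) to 1e-10 rad; the perceived frequency is `1/(2·θ_w°)`.  `d` defaults
to 4 mm — the fish at mid-depth of the 8 mm water column — because the
experiments fix the channel, not the fish's vertical position; the acrylic
wall itself is ignored.  This gives 0.0187 cpd at the low and 0.0210 cpd at
the high height: refraction compresses the apparent grid period more the
closer the screen.

## Controller

State updates run at `Δt = 10 ms`.  The sensed flow is the true flow delayed
220 ms (22 steps; the delay buffer is pre-filled with the baseline flow
`s/h`, since the fish has been resting in the moving stimulus before t = 0 —
the 10 s warm-up makes this choice immaterial to analyzed output) and
rectified into non-negative forward and backward components
`y_f = max(ω, 0)`, `y_b = max(−ω, 0)`.

Flow integration is leaky Euler integration of `u = k_f·y_f − k_b·y_b`:

    Y[t] = Y[t−1] + Δt·(u[t] − Y[t−1]/τ_f)

relaxing to `u·τ_f` for constant input.  A pass-through mode (`τ_f = None`)
represents "no integration" explicitly rather than as `τ_f → 0`, avoiding a
degenerate Euler step.  `Δt ≥ τ` is rejected as an unstable discretization.

Bout initiation is an inhomogeneous Bernoulli approximation of a Poisson
process: on each step a bout starts with probability

    p[t] = min(max(Δt·(k_r·drive[t] − k_m·M[t]), 0), 1)

where `drive` is `Y` for the single-factor model and `y_f` for the
dual-factor models, and `M` is the leaky integral (time constant `τ_m`) of
the motor output — motor inhibition, which delays the next bout after strong
swimming.  Initiation is suppressed for 25 steps after an onset (the 250 ms
refractory period, fixed from data, with gaps of exactly 250 ms permitted).
Under constant `p` the long-run rate is `1/(t_ref + Δt/p − Δt)`, matching
the renewal approximation `1/(t_ref + Δt/p)` closely for small `p` and
saturating near 4 Hz.

Bouts are ballistic.  An onset at `t0` latches a magnitude `k_i·Y[t0]`, and
the speed thereafter is `v[t] = max(k_i·Y[t0]·g[t−t0], 0)`: the fixed
relative profile `g` scaled by the latched magnitude, with a new bout
*replacing* the previous one.  The rectification is kept although `g ≥ 0`
makes it redundant.

Variants: `single` — one signal (`Y` of the overall flow `y_f − y_b`) drives
both rate and intensity, no motor inhibition; `A` — `k_f = k_b = 1`;
`B` — `k_f, k_b` free, `k_i = 1`; `C` — forward flow only
(`k_b = 0, k_i = 1`), the final model.  The published fitted parameter sets
ship as JSON presets:

| preset | τ_f | k_i | k_r | k_m | τ_m | k_f | k_b |
|---|---|---|---|---|---|---|---|
| single_speed | 0.071 | 250.46 | 50092 | — | — | 1 | 1 |
| single_bout | pass-through | 22.36 | 39.76 | — | — | 1 | 1 |
| dual_A | 0.0238 | 1055.42 | 772.934 | 0.034 | 0.345 | 1 | 1 |
| dual_B | 0.152 | 1 | 274.831 | 0.021 | 0.792 | 291.204 | 0.400 |
| dual_C | 0.152 | 1 | 274.831 | 0.021 | 0.792 | 291.204 | 0 |

(An additional `bout_generator.json` table records the enhanced bout
generator fitted to bout rate alone, with intensity pinned per condition; it
is a reference fixture, not a runnable preset.)

## Canonical bout-speed profile

The empirical relative speed profile is characterized by landmarks, not a
formula: ≈ 0 at onset, a single peak of ≈ 6.75× the mean bout speed at
≈ 80 ms, a fall back through the mean at ≈ 200 ms, then a slow decline
(post-bout coasting), with unit mean over the first second by construction.
The canonical profile realizes these landmarks piecewise:

* quarter-sine rise from 0 to the peak over 0–80 ms.  The quarter-sine puts
  the *maximum acceleration at bout onset*, which keeps the
  acceleration-maximum onset detector unbiased; a rise with an inflection
  (e.g. half-cosine) would systematically shift detected onsets ~40 ms late;
* exponential decay from the peak, with rate `ln(6.75)/0.12 s⁻¹` fixed by
  requiring the curve to cross the mean exactly at 200 ms;
* a second, slower exponential tail after 200 ms whose rate is *solved*
  (Brent's method) so that the discrete mean over the first second is
  exactly the reciprocal of the peak — after the final renormalization to
  unit mean, the peak is then exactly 6.75 and the crossing exactly 1.0.

Note the three landmarks plus unit mean leave essentially no freedom in the
tail's total mass (≈ 0.37× the mean over 0.2–1 s); only its shape within
that budget is conventional.  A single-rate decay cannot satisfy peak,
crossing and unit mean simultaneously, which is why the tail rate is a
solved second stage.  The profile shape is a pluggable component
(`SpeedProfile`): any non-negative unit-mean single-peak curve can be
substituted.

## Simulation

Sessions are 3000 steps (30 s); the first 1000 are warm-up and excluded
from summaries.  Per step, in order: the flow generated by the current speed
enters the delay line; the delayed flow is sensed and rectified; `Y` is
updated; `M` integrates the motor signal of the bout active *before* any new
onset; `p` is computed; the initiation event is drawn; the speed is emitted
(an onset contributes `g[0] = 0` on its own step).  Each fish has an
independent random stream derived from `(master seed, condition index, fish
index)`, so grids are reproducible and order-independent; a vectorized
implementation advances all fish of a condition simultaneously and is
verified step-for-step against the scalar single-fish path on identical
streams.

Per-condition summaries use the same definitions as the analysis pipeline:
mean swim speed is the time average of `v` over the analyzed 20 s, OMR ratio
divides it by the stimulus speed, bout rate counts analyzed-window onsets,
and initial bout speed averages `v` over each bout's first 100 ms (per fish,
then across fish).

## Trace analysis

* **Resampling** — raw samples to a uniform 10 ms grid; gaps ≤ 120 ms are
  linearly interpolated, longer gaps become missing values.
* **Frame convention** — positions are mapped into the stimulus-direction
  frame (`x_s = direction · x`) so forward and backward traverses share one
  code path; the traverse is truncated at the first arrival 50 mm before the
  channel end.
* **OMR trajectories** — the difference between a fast (α = 0.05) and a slow
  (α = 0.002) finite-history exponential moving average of position marks
  with-stimulus movement; the same computation on the time-reversed series
  trims segment end points (a sample counts as moving only if both passes
  agree).  Maximal agreeing runs are split at missing samples and must last
  ≥ 1 s at a mean speed ≥ 0.5 mm/s.  Traverses with < 2 s of total
  trajectory time are discarded; a session needs at least one valid
  traverse, and its speed is the *unweighted* mean of its traverses' speeds.
  Note the slow EMA carries ~5 s of memory, so an isolated full reversal of
  swimming direction is located with an intrinsic lag of roughly half that
  memory; the two-pass trimming compensates at segment boundaries.
* **Bout detection** — position is zero-phase filtered (forward-backward FIR,
  20-tap Kaiser window, β = 5, cutoff 0.02 of Nyquist; β and the
  Nyquist-relative reading of the cutoff are conventions, both exposed in
  `AnalysisConfig`), differentiated twice, and onsets taken at local maxima
  of acceleration with a 100 mm/s² prominence guard and 150 ms minimum
  separation (the guard suppresses noise peaks; the validity rules do most
  rejection).  Candidates must exceed 50 ms active duration and 0.5 mm
  displacement.
* **Bout measures** — initial speed (mean over the first 100 ms), peak
  speed, displacement to the next onset, and active duration: the time
  until the 50 ms-windowed speed first drops below 5 mm/s after having
  reached it (bouts that never reach it are flagged degenerate).
* **Profiles** — instantaneous speeds from *unsmoothed* first differences,
  averaged per offset over 0–1 s across bouts, counting only timesteps that
  still belong to the bout (offsets past the next onset are excluded —
  without this the tail of the window is contaminated by the following bout
  at physiological bout rates and the normalized peak collapses), then
  divided by the curve's own mean.  Quartile profiles split bouts by initial
  speed.

## Fitting

The cost for an outcome variable is the RMSE of per-condition prediction
errors divided by the observed grand mean (dimensionless, unit-invariant);
multiple outcomes average with equal weight.  The optimizer evaluates a
3-per-dimension multiplicative grid, recentres while a strictly better
off-centre point exists, and square-roots every pitch factor once centred,
stopping when all pitches ≤ 1.05 (gains and time constants span orders of
magnitude, hence the log layout; shrink and stop factors are stated
defaults automating what was originally a contour-map-guided manual
schedule).  Evaluations are cached and use common random numbers — fixed
per-condition seeds — so the stochastic cost surface is deterministic and
repeated fits are bit-identical.  The pass-through integrator is a discrete
arm: fit with and without integration and keep the cheaper.

A practical identifiability note: with the motor signal identified with swim
speed in mm/s, the published final-model scales make `k_m·M` at most ~1% of
`k_r·y_f` everywhere on the standard grids, so the cost surface is
essentially flat in `k_m` and self-consistency refits recover `k_r` but not
`k_m`.  The backward gain `k_b` is likewise recoverable only as "small":
freeing it on forward-only data drives its flow contribution below a few
percent of the forward one without pinning an exact value.

## Synthetic data

The generator emulates the recordings: 100 frames/s, 300 mm channel, two
60 s traverses (stimulus forward then backward), position clipped at the
walls, Gaussian measurement noise (default sd 0.05 mm) and dropped frames
(default probability 0.01, emitted as absent rows).  Noise and drop defaults
are conventions for a well-behaved tracker, not measurements.  Script-driven
mode draws inter-onset intervals as refractory-shifted exponentials
(default rate 1 Hz) and bout magnitudes as a truncated normal (mean 8, sd 3,
floor 2 — roughly a four-fold intensity range), the minimal structure the
pipeline assumes; model-driven mode takes bout trains from the closed-loop
controller.  Ground truth records onsets, magnitudes, displacement and —
because behavior beyond the 50 mm end margin is pruned and beyond the wall
unobservable — the windowed mean speed and bout rate up to margin arrival,
which are the quantities recovery checks compare against.

What passing recovery tests shows, and what it does not: the synthetic data
share the real recordings' sampling, noise floor, gaps, channel limits and
bout intermittency, so they validate the pipeline's segmentation, detection
and normalization logic; they do not contain tracking-candidate ambiguity,
body-posture artefacts, fast bouts, turning, or any deviation of real bouts
from the fixed-profile assumption, so they cannot certify performance on
those.

## Problem sizes

Simulated reproduction runs use the study's own scale (30 fish × 30 s per
condition).  Pipeline-recovery checks use six synthetic fish (twelve 60 s
traverses, ~700 bouts); profile extraction uses ≥ 200 bouts;
self-consistency refits evaluate a 9-condition grid with 15 fish per cost
evaluation against observations generated at 30.

## Known limitations

* The bout-speed profile tail between 200 ms and 1 s is landmark-constrained
  in mass but conventional in shape; simulated mean speeds at the medium and
  high heights run ~10–15% below the published overall OMR ratios, which is
  within the stochastic-reproduction tolerance but plausibly traceable to
  the tail shape of the original empirical profile.
* Onset detection from filtered acceleration is ~10–20 ms late on average,
  shifting the extracted profile peak slightly earlier than 80 ms.
* No modelling of fast bouts, turning, rotational OMR, inter-fish
  interaction, lateral-line input, or adaptation across sessions.
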