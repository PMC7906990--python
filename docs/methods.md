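# Methods

## Scope and architecture

`vretsim` reproduces, headlessly, a closed-loop biofeedback system for
virtual-reality exposure therapy: an EDA-driven controller, the spider
arena it steers, a synthetic participant that supplies the physiology, and
the session-metric/statistics layer used to compare the adaptive protocol
with a pre-recorded static one.  Hardware acquisition, rendering, occluder
geometry, and clinician UI are out of scope; the clinician's override is
modeled as an abort flag only (`SessionConfig.abort_at`), which truncates
the crash-safe, line-buffered session log at the abort tick.

## Signal layer

Raw EDA is a positive, arbitrary-unit voltage-response difference sampled
at 100 Hz.  No artifact filtering is applied, and no tonic/phasic
decomposition is performed — the protocol analyses the normalized raw
signal.  The Relaxed EDA value is the arithmetic mean of the first
stimulus-free minute and is frozen for the whole session (a one-time
initialization).  Session start additionally requires the signal to sit
within ±8% of that mean; because the criterion is stated for "measurements"
without a dwell time, we require `hold = 100` consecutive in-band samples
(one full second at 100 Hz) so that a single noise spike cannot trigger
convergence.  The convergence instant is the time the hold run completes,
so a perfectly clean signal converges at 61 s.  Samples between the end of
the baseline window and convergence belong to no phase and enter no metric;
if the signal has not settled within `baseline_max_wait` (default 60 s) the
session aborts with a diagnostic rather than guessing a fallback baseline.
Normalization is plain division by the relaxed value and is deliberately
not clipped: values slightly above 1 (calmer than baseline) are meaningful
and preserved.

## Controller

States are fixed bands of normalized EDA (Rest 0.92–1.0, Low 0.7–0.8, High
0.4–0.5) whose representative value is the band's lower edge.  The
correction c = representative − normalized is recomputed at every 100 Hz
sample from the latest sample only; the five parameter mappings are pure
functions of c (see README for the closed forms).  Numerical choices:

- **Jumping force.** The printed closed form of this mapping is
  typographically unrecoverable in the source material.  We use the linear
  reconstruction SJF(c) = 0.035 − 0.14c, the unique line through both
  published anchor values (0.035 N at c = 0, 0.049 N at c = −0.1), monotone
  in the required direction.  The coefficients are config keys
  (`sjf_intercept`, `sjf_slope`) should a better reading emerge.
- **Clamps.** SGF goes negative for c ≥ 0.1 (Low) / c ≥ ~0.27 (High) and
  SPU exceeds 1 for c < −0.6, so SGF and SJF are floored at 0, SPU clamped
  to [0, 1], and SV floored at 1e−4.  These floors are not part of the
  published equations; they enforce physical ranges outside the on-target
  regime.
- **SGF units.** SGF is treated as rate-like (larger ⇒ more frequent
  spawning), the reading consistent with the published statement that
  less-anxious participants received SGF above 240; the conversion to
  spawns per second lives in the arena layer (below).
- The published correction ranges (−0.4..0.6 in Low, −0.7..0.3 in High) are
  algebraically inconsistent with normalized EDA ∈ (0, ~1.1] and are not
  enforced; excursions simply appear in the log.

The **static (control) schedule** is only described qualitatively in the
source (Low: smaller, slower, fewer spiders; High: bigger, faster, more).
It is realized as the adaptive bundle frozen at on-target corrections,
c = 0 for Low and c = −0.1 for High, which makes the static High state
strictly stronger than static Low in every parameter.  In static mode the
EDA stream is recorded but never reaches the arena.

## Arena

Geometry is not prescribed by the protocol — only the route topology
matters — so the room is a 5 m × 5 m floor with generation points at wall
midpoints, exits at corners, destination-assignment points 0.5 m in front
of each generation point, gathering points 0.5 m inside each exit, and the
user at the center.  Spiders move in straight lines between waypoints
(generation → destination assignment → [user, with probability SPU] →
gathering → exit); the waypoint scheme is what prevents collisions, so no
collision handling is simulated.  Jumping is an attribute annotation (only
detouring spiders jump), not ballistic motion.  A spider's parameters are
fixed at its spawn instant.

Spawning uses a deterministic fractional accumulator: each frame adds
SGF/(divisor · frame_rate), spawning on unit crossings, so the expected
rate is SGF/divisor spiders per second (divisor 100: SGF 120 ⇒ 1.2
spawns/s) and inter-spawn intervals are fully determined by the SGF
history.  On a phase transition into Rest all active spiders are removed
immediately (and counted as exited, preserving spawned = exited + active):
the rest state is stimulus-free by definition, and letting spiders linger
into it would contaminate the recovery metric.

The scalar stimulus intensity is additive over active spiders: each
contributes w_presence + w_size·size + w_vel·(v/0.006) +
w_jump·(force/0.049) + w_prox·max(0, 1 − d_user/diag) with default weights
(0.2, 0.3, 0.15, 0.15, 0.2).  The weights set the *relative* composition of
a spider's salience; the overall scale is calibrated (below).

## Participant model

Latent arousal a ≥ 0 integrates the latency-delayed intensity,
da/dt = (g·I(t − L) − a)/τ, with τ = tau_rise (2 s) during onset and
tau_recover (8 s) during recovery — recovery slower than onset, matching
the observation that stronger stimuli take longer to recover from.
Normalized output is y = exp(−a): positive, exactly 1 at rest, and able to
fall far below 0.5 without crossing zero (a linear link could not).  Raw
output is relaxed_eda · y · (1 + ε) with i.i.d. Gaussian multiplicative
noise (default SD 2%, a typical measurement-noise level for a finger
electrode on a motionless participant).  Latency L defaults inside the
physiological 1.6–5.5 s reaction band.  Habituation (linear gain decay) is
available but off by default: the scope is a single 5-minute session.
Constant intensity I settles at a* = g·I, i.e. y* = exp(−g·I), the closed
form used as a test oracle.

Cohorts draw sensitivity log-normally (median 1.0, log-SD 0.4, giving a
90th/10th-percentile gain ratio of ~2.8 — the hard- and easy-to-stimulate
heterogeneity the static protocol cannot absorb), latency uniformly on
1.6–5.5 s, and baseline EDA uniformly on 2–8 arbitrary units.

### What the generator emulates, and what it does not

The synthetic participant reproduces the *mechanistic* features the loop
needs: baseline individuality, reaction latency, asymmetric
onset/recovery, monotone stimulus–arousal link, sensitivity heterogeneity,
and measurement noise.  It does not reproduce human tonic drift,
spontaneous fluctuations, habituation within the minute, movement
artifacts, or any cognitive appraisal.  Passing tests therefore show that
the *system* behaves as designed around a plausible physiological stand-in;
they do not certify the human percentages of the original study, whose raw
traces were never published.

## Calibration of the simulator's free scales

Two quantities of the headless loop are not fixed by the published design
and were set by analysis, not by simulation output:

- **Intensity normalization.** Only the product of stimulus intensity and
  participant gain is observable, so one overall scale is free.
  `calibrate_intensity_scale` chooses it in closed form so that at the
  on-target correction (c = −0.05, the middle of the published on-target
  band) the steady-state arousal of a median participant equals the
  band-center arousal: steady intensity = spawn rate × mean route residence
  time × mean per-spider contribution, everything computed from the room
  geometry, the weights, and the mappings; the final scale is the geometric
  mean of the Low and High solutions (≈ 0.054 with defaults).  Without this
  normalization a single spider saturates the participant and both
  protocols pin the signal to the floor.
- **Spider speed.** The published velocity parameter (~0.005) is defined
  per frame but printed as m/s; at face value either reading gives
  implausible room-crossing times (17 s or 17 min).  The behaviorally
  meaningful quantity is the crossing time — on-target spiders should
  traverse the room in a few seconds — so `velocity_scale = 5` converts the
  parameter to simulated meters per frame, giving ~3.5 s crossings at
  60 fps.  Long residence also acts as actuator lag that makes the
  proportional controller limit-cycle through the band, which is an
  artifact of the literal unit reading, not of the published control law.

## Session metrics

Each active-state minute is scored per sample against its band:
maintenance (inside), less-anxious (above), more-anxious (below) — the
three partition the window exactly.  Entrance time is the first in-band
sample regardless of approach direction (so less-anxious duration includes
it).  Recovery duration is measured from the start of the following rest
minute to the first sample at or above the rest band's lower edge (0.92);
an exact return to 1.0 is a measure-zero event under noise, so re-entry
into the rest band is the operational definition.  Group summaries use the
population (divisor-n) SD because that convention reproduces the published
summary rows of the reference tables; ANOVA and Pearson are standard
(scipy) and are cross-checked against hand-written textbook formulas in the
tests.

The packaged reference tables transcribe the published per-participant
metrics of both 18-person study arms, checksummed.  They are shipped
*exactly as printed*, including three State-1 rows whose three durations do
not sum to 60 s (sums 59.01, 59.70, 61.00 s) — an internal inconsistency of
the source data that the test suite documents rather than repairs, and the
reason the window-partition check fails on 3 of the 72 printed windows.

## Experiment design

`run_cohort` uses a *paired* design: each synthetic profile runs under both
protocols with identical seeds, which is strictly more informative than the
original two-independent-groups design (two independent cohorts remain
available by drawing two cohorts with different seeds).  The headline
structural result, computed by the acceptance test at n = 18 with five seed
replicates, is that mean in-band occupancy is higher under feedback control
than under the static schedule in both active states, with the larger gap
in the high-intensity state — the same ordering and asymmetry as the
published human comparison (74.25/45.91% Low, 67.46/27.68% High), though
the absolute human percentages are not reproducible from synthetic
physiology and are not targets.  Problem sizes (300-s sessions at 100 Hz,
60 fps arena, n = 18, 5 seeds) were chosen to match the protocol's own
dimensions while keeping a full paired comparison around a minute of
compute.

## Known limitations

- The arousal model is first-order; real electrodermal responses summate
  phasic peaks over a tonic drift, so transient shapes differ.
- Correction-range bookkeeping, the jumping-force reconstruction, and the
  static schedule's numeric values are documented interpretations of an
  under-specified source, each overridable via the YAML config.
- Intensity is a hand-designed salience sum, not a fitted perceptual model;
  only its calibrated scale, not its functional form, is validated.
- Single-session scope: no habituation by default, no cross-session
  treatment planning, no alternative state orderings.
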