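# Methods

This note documents the models and conventions behind `vgskit`: what the
pipeline computes, what the synthetic data emulate, which defaults were
chosen where the design was open, and what the tests do and do not show.

## Display geometry

Eccentricity is the angle between the gaze ray through a screen point and
the ray through the screen center: `θ = atan(r·s / D)`, with `r` the
radial pixel offset, `s` the pixel pitch and `D` the viewing distance.
Pixels are assumed square; `s` is derived from the diagonal, aspect ratio
and horizontal resolution (23 in, 16:9, 1920×1080 → 0.02652 cm/px).  At
`D = 65 cm` this puts 100 px at 2.34°.  The flat-screen approximation is
exact for the angle *from center* and a very good approximation for
angular distances between arbitrary points at the eccentricities used
here (≤ 18°).  General angular distances are computed between the 3-D
gaze vectors, not as scaled Euclidean pixel distances.

Coordinates are screen pixels, origin top-left, y growing downward; an
upward target therefore has amplitude −8° in the screen-y convention.
Timestamps are milliseconds; intervals are half-open `[start, end)`.

## Event detection (I-VT chain)

Stages run in a fixed order:

1. **Blink detection** on the *raw* validity codes: maximal runs in which
   both eyes are invalid, lasting 50–500 ms, are blinks.  The bounds are
   the physiological blink-duration range; shorter runs are treated as
   data loss, longer ones as tracking loss.  Validity semantics: code 0 =
   tracked with high confidence, any nonzero code = invalid (the
   simulator writes 4).
2. **Eye averaging**: midpoint when both eyes are valid, the single valid
   eye otherwise, missing when neither is.
3. **Blink excision before interpolation**, so gap-fill never synthesizes
   gaze through a blink.
4. **Gap fill**: missing runs with valid flanks and flank-to-flank
   interval ≤ 75 ms are linearly interpolated.
5. **Velocity**: at sample *i*, the angular distance between the samples
   at the ends of a 20 ms window centered on *i*, divided by their time
   separation.  At 250 Hz the endpoints sit 2 samples (16 ms) apart.  At
   recording edges the window shrinks symmetrically; the velocity is
   absent where an endpoint is missing.
6. **Classification**: saccade iff `v ≥ 30 °/s` (inclusive), fixation
   below, missing where the velocity is absent.
7. **Event assembly with boundary refinement** (below), blinks taking
   precedence over the per-sample labels.
8. **Fixation merging**: adjacent fixations (no blink and no other
   fixation between them) separated by ≤ 75 ms with centroids ≤ 0.5°
   apart are combined; whatever lay between them is absorbed.  Applied to
   a fixpoint; this is also the mechanism that removes most
   noise-induced micro-events.
9. **Sub-resolution saccade removal**: a candidate saccade whose
   start-to-end displacement is below `min_saccade_amplitude_deg`
   (default 1.0°) is fixational noise, not a saccade, and is reabsorbed
   by a second merge pass.  The task's smallest target eccentricity is
   8°; microsaccade detection is explicitly out of scope.
10. **Minimum fixation duration**: fixations shorter than 60 ms
    (exclusive) become gaps.  Merging runs before the duration filter.

All threshold comparisons are inclusive.  Velocities are °/s throughout;
output tables print the unit.

### Boundary refinement

The first sample whose 20 ms windowed velocity crosses 30 °/s lies
systematically 1–5 ms *after* true movement onset (the window must
accumulate ~0.5° of displacement).  Saccade onsets and offsets are
therefore refined with a dual-threshold walk, standard practice in
oculomotor event detection: from each supra-threshold run, the boundary
moves outward over at most `refine_max_samples` (default 1) neighboring
samples while the velocity stays above a low onset threshold (default
5 °/s, floored at 1.5× the median of the velocity trace so the walk never
descends into the noise floor of a noisy recording) and decreases
monotonically away from the run.  On noiseless 250 Hz data this recovers
grid-aligned onsets exactly; under the default noise it leaves a mean
latency bias below 1%.

The windowed estimator attenuates peak velocity by the window average of
the raised-cosine profile — about 11% for ~45 ms (≈ 9–10°) saccades and
5% for ~65 ms (≈ 16–18°) ones.  This is a property of the prescribed
filter, not a bug; the recovered peak velocities average ~7% below truth
over the near/far mix and the tests assert exactly that attenuation band.

## Trial analysis

The gap protocol presents, per trial: central dot 1500 ms, gap 200 ms,
eccentric target 1500 ms (3200 ms total).  Horizontal sessions use
±10°/±18° (classes *near*/*far*), vertical sessions ±8° (*up*/*down*),
40 presentations per task in seeded random order (for the vertical task:
20 per amplitude, honoring the 40-per-task protocol; configurable).

Validity checks run in a fixed order and record the first failure:

- (a) no saccade or blink overlapping the 60 ms before central-dot
  offset;
- (b) gaze within 100 px (≈ 2.3°) of the screen center *at central-dot
  offset* (the criterion refers to the starting point, which exists
  before the target appears — hence this instant);
- (c) the first saccade leaving the 100 px start radius after target
  onset must begin within [100, 1500) ms of target onset.  Earlier
  launches are anticipatory (pre-planned); the upper bound equals the
  target-presentation time, since a movement begun after target offset
  cannot be stimulus-driven.

Metrics of the selected saccade: latency (onset − target onset),
duration, amplitude (full 2-D angular displacement between gaze at start
and end — not the axis projection; configurable), mean and peak of the
velocity trace over the saccade span, and gain = amplitude / |target
amplitude|.  Aggregates use sample SDs (n−1).  Subjects need ≥ 6 valid
trials *per task* (inclusive) to be included; blink rate is blinks per
minute over the task span.

## Synthetic data

The simulator generates what the analysis consumes: 250 Hz binocular
gap-paradigm sessions plus a per-trial ground-truth sidecar.

- **Kinematics**: peak velocity from the saturating main sequence
  `V_p = V_max (1 − e^{−A/a_0})` with `V_max = 600 °/s`, `a_0 = 8°`
  (mid-range literature values for healthy adults); raised-cosine
  velocity profiles with `D = 2A/V_p`, which integrate exactly to the
  amplitude and have time-mean velocity `V_p/2`.
- **Latency**: shifted gamma, 130 + Γ(4, 25) ms (mean 230 ms, SD 50 ms,
  typical of gap-paradigm saccades in older adults), truncated at
  1300 ms.  With probability 0.05 a trial is anticipatory: latency
  uniform below 100 ms, toward the correct target.  Onsets are aligned
  to the 4 ms sample clock — the simulation is discrete-time.
- **Gain**: Normal(0.9, 0.08) truncated to [0.5, 1.3], the physiological
  hypometria range; gains far below that would produce return saccades
  slower than the 30 °/s threshold, which no velocity-threshold filter
  can see.
- **Behavior**: the subject re-fixates the central dot 100–300 ms into
  each trial's central period (a *return saccade*, recorded in the
  ground truth so that detected-saccade counts are well defined) and
  holds fixation otherwise.
- **Blinks**: Poisson at 12/min, durations uniform 100–300 ms, realized
  as both-eyes-invalid runs.  Blinks are drawn to avoid saccade
  intervals (±12 ms), modelling saccadic blink suppression.
- **Noise and loss**: white Gaussian angular noise, SD 0.15° per axis
  per sample; independent per-eye sample loss at 0.2%; a fixed 0.3°
  interocular offset so the eye-averaging branches are exercised.

What the simulator does **not** emulate: pink/drift-like noise spectra,
calibration bias, head movement, square-wave jerks, ocular tremor,
direction errors of anticipatory saccades, corrective/multi-step
saccades, pupil dynamics.  Passing recovery tests therefore show the
chain is correct for clean saccadic kinematics under white noise; they
do not certify performance on pathological recordings.

The synthetic cohort draws a clinical table (62 subjects, 37:25
male:female, age ~ N(60.4, 9.0), Hoehn & Yahr stages concentrated at 2,
MMSE for 42, CANTAB for 22, nested by default) and per-subject metric
means as `baseline + Σ slope·(covariate − mean) + Normal(0, σ_resid)`.
All slopes default to zero (the null cohort); the calibration suites set
e.g. a +2 ms/yr age–latency slope against a 20 ms residual SD.  The fast
path emits the metric means directly — sufficient for correlation
calibration at hundreds of replicates; full gaze synthesis per subject is
available behind `simulate_gaze=True` and is exercised end-to-end at
small n.

## Statistics

Spearman's ρ uses average ranks for ties.  For n ≤ 10 the two-sided
p-value is exact: all n! pairings are enumerated (vectorized, cached per
n) and compared on |ρ|.  For larger n the usual t approximation
`t = ρ√((n−2)/(1−ρ²))` is used; at n = 10 the two agree within 0.02.
Pearson's r carries the standard two-sided t test.  Grids use pairwise
deletion (the clinical subsets with MMSE/CANTAB scores are analyzed as
available, not listwise) and apply **no multiple-testing correction** —
the report prints the number of tests and an explicit caveat instead.
Ordinal covariates (Hoehn & Yahr stage) default to Spearman.  Effect-size
adjectives use |ρ| bands 0.1/0.3/0.5 (weak/moderate/high), configurable
because usage in the clinical literature is inconsistent.

## Numerical conventions and problem sizes

- Degenerate inputs: fewer than 3 complete pairs → flagged
  `insufficient_data` result (no ρ); zero-variance input → `undefined`.
- Recovery suites run 20 seeded sessions of 40 trials (≈ 2.6 M samples
  total); calibration uses 500 null and 100 alternative cohort
  replicates of 62 subjects.  These sizes put Monte-Carlo error well
  inside the asserted bands while keeping the whole suite fast.
- All randomness flows from explicit integer seeds; identical seeds give
  byte-identical gaze exports.

## Known limitations

- The exact-permutation Spearman p is limited to n ≤ 10 (10! ≈ 3.6 M
  permutations); beyond that only the t approximation is offered.
- The I-VT velocity window biases peak velocity low by a known,
  amplitude-dependent factor (see above); comparisons should be within
  one pipeline, not across window settings.
- Off-axis (oblique) saccades are supported by the geometry but not
  generated by the simulator, whose targets lie on the display axes.
- The blink detector cannot separate a true blink from a both-eyes
  tracking loss of similar duration; the 50–500 ms gate is the only
  discriminator.
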