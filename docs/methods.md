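# Methods

## The MAD statistic and epoching

The mean amplitude deviation of an epoch is the mean absolute deviation
of the resultant acceleration about the epoch mean, in milligravity
units. It is shift-invariant (gravity and any constant offset cancel),
scale-equivariant, and zero exactly on constant epochs. For a resultant
`c + A·sin(ωt)` sampled over whole periods it converges to `2A/π`.

Epoch lengths are powers of two: `choose_epoch_spec` returns the `n =
2^k` minimising `|n − rate·target|` with ties broken toward the smaller
`n` (target 5 s by default), giving 512 samples at 100 Hz and 128 at
30 Hz. Epochs are non-overlapping, anchored at the first sample, and a
trailing remainder is discarded; these choices are the simplest
deterministic grid and do not affect steady-activity MADs.

Per activity bout three epochs are extracted: starting 5 s after the
bout begins, centred on the bout midpoint, and ending 5 s before the
bout ends. Sub-sample boundaries snap to the nearest sample index. The
middle epoch may overlap the others in bouts shorter than ~20 s; the
default 2-min protocol never triggers this. Missing or non-finite
samples are rejected at read time, not imputed — protocol recordings
are continuous. No filtering or auto-calibration precedes the resultant;
the statistic is computed on the raw signal.

## Synthetic protocol generator

The generator emulates a supervised protocol: ten 2-min activities
(five sedentary postures, slow/normal walking, brisk walking, jogging,
running) separated by 15 s quiet transitions, recorded simultaneously by
a 100 Hz/±16 000 mg device and a 30 Hz/±3000 mg device. A master
specific-force process is synthesised at 400 Hz; each device observes it
by nearest-sample decimation (no anti-alias filter — a documented
simplification), adds white sensor noise (default SD 1.5 mg/axis), and
saturates each axis at its dynamic range.

Signal model, per bout:

- **Sedentary postures** — gravity (1000 mg on the vertical axis) plus
  white postural tremor (SD 3.6–18 mg by activity), producing epoch MADs
  of roughly 3–15 mg (the MAD of N(0, σ) noise is σ·√(2/π)).
- **Walking gaits** — a sinusoid at the step frequency (1.4–2.2 Hz)
  along a fixed, mostly vertical body direction, superposed on gravity.
- **Jogging/running** — alternation between a flight phase (near free
  fall: the sensed resultant drops toward ~100 mg) and a ground-contact
  impact of fixed magnitude along a near-vertical direction, blended by
  a smoothed square-wave envelope at the step frequency. This shape was
  chosen because a non-negative resultant bounds MAD at half the peak:
  reaching running's ~1600 mg MAD with a vertical sinusoid would demand
  ~6.5 g peaks whose clipping at ±3000 mg collapses the narrow device's
  running MAD below jogging's. Flight–contact alternation reaches the
  same MAD with ~3.4 g vertical peaks, so the ±3000 mg device clips
  running noticeably (≈1600 → ≈1470 mg) yet preserves the activity
  ordering — matching the observed regime in which devices agree below
  700 mg and diverge above it.

Amplitudes are solved numerically on the noiseless waveform so the
unclipped 100 Hz epoch MADs hit per-activity targets of 75 / 150 / 450 /
1050 / 1600 mg (slow walk → running); the closed form 2A/π holds only
for small vertical sinusoids because larger ones are rectified by the
norm. These targets are calibration anchors spanning the class ranges
(sedentary ≈ 2–20, light ≈ 40–200, moderate ≈ 350–550, vigorous ≈
650–1800 mg), not ground truth about any population.

Per-participant random effects: a log-normal pace multiplier (σ = 0.10)
scaling all movement amplitudes, and a normal heart-rate intercept
(σ = 6 bpm). Heart rate is linear in the bout's true (unclipped) MAD,
with the line solved from two anchors — slow walking 92 bpm and running
180 bpm — which places the remaining activities near their protocol
means (99/118/155 bpm). The 1-min and 2-min readings scatter about this
prediction with per-activity SDs of 8–19 bpm; the start reading sits
8 bpm below steady state. Sedentary bouts receive an optional
"excitement" elevation (default 10 bpm) emulating measurement-related
arousal; because the validity analysis excludes sedentary bouts, this
offset must not — and verifiably does not — change any correlation.

Everything is a pure function of configuration and seed (numpy
`SeedSequence` spawning per participant), so cohorts are bit-reproducible.

What the generator does **not** emulate: biomechanical gait variability
(stride-to-stride timing, asymmetry), soft-tissue attenuation, device
placement offsets, non-ambulatory activities, and autocorrelated HR
dynamics. Passing tests therefore demonstrate the correctness of the
analysis chain under the stated signal model, not the field behaviour of
any physical device.

## Device agreement

Bland–Altman in its conventional form: bias = mean(differences), limits
of agreement = bias ± 1.96·SD (sample SD, n−1; no t-correction). Pairs
default to bout level (the mean of the three epoch MADs) with an
epoch-level option, since either aggregation is defensible for
activity-wise comparison. The threshold-stratified bias splits pairs at
a 700 mg pair-mean, isolating the saturation regime. Unmatched pairing
keys are reported, never silently dropped; an empty stratum yields NaN
rather than an error.

## Heart-rate validity

Bout heart rate is the mean of the 1-min and 2-min readings (the start
reading reflects the previous activity). Per subject, Pearson r between
bout MAD (three-epoch mean) and bout heart rate is computed over the
non-sedentary bouts; with only five ambulatory activities per subject, r
is refused (not imputed) below three usable points, and zero variance
raises an explicit error. Subject coefficients are pooled on the Fisher
z scale; coefficients of exactly ±1 are clamped to ±(1−10⁻¹²) with a
warning. Each device is analysed independently. A flag-level choice —
bout means (5 points) rather than individual epochs (15 points) — keeps
one point per activity.

## Cut-point model

"Generalized" ordinal logistic regression is implemented as three
cumulative binary models (class ≥ light/moderate/vigorous), each with
its own intercept and slope (non-proportional odds), estimated by GEE
(statsmodels) with an exchangeable working correlation over subject
clusters — the compound-symmetry assumption that all within-subject
pairs share one correlation. Each of the three epoch MADs per bout is
one observation. The cut-point is the 0.5-probability crossing
`−α_k/β_k`; a usable fit requires every slope positive and the three
cuts strictly increasing, otherwise the fit is rejected outright.

Complete separation (an empty MAD gap between the classes at a
threshold) leaves the logistic likelihood without a finite optimum; the
estimator then takes the gap midpoint and warns prominently. On the
default synthetic cohort the classes are cleanly separated, so fitted
cuts come from this fallback; the regression path is exercised by a
dedicated recovery study (`simulate_ordinal_mad`) drawing classes from
known cumulative-logit curves — boundaries (100, 400, 800) mg, slopes
(0.08, 0.03, 0.02)/mg, log-uniform MAD over 5–2000 mg, subject
intercept SD 0.5 — whose marginal 0.5-crossings are exactly the
boundaries (the subject intercept is symmetric, so attenuation moves
the slope but not the crossing). Twenty seeded replicates of 20×30
observations recover each boundary with median relative error ~3 %.

Classification uses lower-closed intervals (MAD equal to a cut belongs
to the higher class — an arbitrary but fixed tie-break). Reports give
the 4×4 confusion matrix, the misclassification percentage over MAD
values, and per-threshold sensitivity/specificity/accuracy from the
collapsed binary split. Because "values" and "activities" denominators
differ, the pipeline also reports an activity-level count using the
majority vote of each bout's three epoch classes (the median vote when
all three differ); neither is privileged. The regression predictor is
raw MAD in mg; fits are per device, since device-specific cut-points
are the object of interest.

## Numerical and scale choices

All internal units are mg and seconds; session time starts at 0 with
0-based sample indexing and half-open `[start, end)` intervals. The
test suite and demonstration runs use a 20-participant cohort (~13 M
master samples), generating in a few seconds; the GEE recovery study
uses 20 replicates of 600 observations. The pipeline writes only
derived tables by default; full raw CSVs (~130 k rows per device per
participant) are opt-in via `madaccel simulate --write-raw`.

## Known limitations

- The separation fallback returns the gap midpoint, which is any valid
  boundary but not a likelihood-based estimate; with narrowly separated
  real data a penalised (Firth-type) logistic fit would be preferable.
- GEE standard errors are computed but not surfaced as cut-point
  confidence intervals (the delta method on −α/β would be needed).
- The 30 Hz device inherits aliasing from nearest-sample decimation, as
  real resampling firmware may not; its epoch MADs consequently wobble
  a few percent around the 100 Hz device's on sharp-impact signals even
  without clipping.
- Sex-stratified cut-points and energy-expenditure (MET) calibration are
  out of scope.
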