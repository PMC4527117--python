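# madaccel

Intensity classification of physical activity from **raw tri-axial
accelerometer data** via the **mean amplitude deviation (MAD)**, for
researchers comparing accelerometer brands or deriving intensity
cut-points in lab protocols.

Activity counts are vendor-specific, which makes studies using different
devices hard to compare. MAD is computed directly from the physical
acceleration signal: within each analysis epoch of *n* samples, with
resultant acceleration *r_i* = √(a_x² + a_y² + a_z²),

```
MAD = (1/n) Σ |r_i − r̄|        [mg, 1000 mg = 1 g]
```

Because gravity contributes a near-constant offset to the resultant, the
mean-subtraction cancels it: a motionless sensor yields MAD = 0 in any
orientation. Epoch lengths are powers of two approximating 5 s — 512
samples at 100 Hz (5.12 s), 128 at 30 Hz (4.27 s).

The package implements the full analysis chain of a two-device lab
protocol (ten 2-min activities from lying to running, 15 s transitions):

- **signal_core** — resultant, epoch segmentation, MAD, three-epoch bout
  summaries (5 s after bout start, bout middle, 5 s before bout end),
  minute-by-minute series;
- **synthetic** — a seeded generator emulating the 20-participant
  protocol on two virtual devices (100 Hz/±16 000 mg and 30 Hz/±3000 mg),
  including axis saturation and heart rate linear in intensity;
- **agreement** — Bland–Altman bias and 95 % limits of agreement between
  paired device MADs, with a 700 mg threshold-stratified bias;
- **hr_validity** — within-subject Pearson correlation of bout heart
  rate vs MAD (sedentary bouts excluded), pooled by Fisher
  z-transformation: `pooled_r = tanh(mean(arctanh(r_j)))`;
- **cutpoints** — generalized (non-proportional-odds) ordinal logistic
  regression of cumulative intensity on MAD, fitted per threshold by GEE
  with an exchangeable within-subject correlation; cut-point *k* is the
  MAD where P(class ≥ k) = 0.5, i.e. `−α_k/β_k`. The universal adult
  cut-points (17, 331, 599 mg) are built in;
- **pipeline / cli** — file formats (plain CSV), the end-to-end run and
  a `madaccel` command with `simulate`, `mad`, `agree`, `validate-hr`,
  `cutpoints`, `classify` and `run` subcommands.

## Worked example

```bash
madaccel run --seed 42 --n-participants 20 --out demo_out
```

simulates the full 20-participant cohort (200 bouts) on both virtual
devices and runs every stage. Excerpts of the printed summary:

```
"agreement": {
    "bias_mg": -13.27,
    "loa_lower_mg": -118.51, "loa_upper_mg": 91.98,
    "threshold_mg": 700.0,
    "bias_below_mg": -0.14,  "bias_above_mg": -65.80 },
"hr_validity": {
    "narrow_30hz": {"pooled_r": 0.965},
    "wide_100hz":  {"pooled_r": 0.971} },
"cutpoints": {
    "wide_100hz":  {"cut1_mg": 38.8, "cut2_mg": 285.4, "cut3_mg": 681.6},
    "narrow_30hz": {"cut1_mg": 38.8, "cut2_mg": 285.2, "cut3_mg": 683.0} }
```

Reading the numbers: the two devices agree almost perfectly below
700 mg (bias −0.14 mg) while above 700 mg the narrow-range device
under-reads by ~66 mg on average — its ±3000 mg axes clip the impact
peaks of running. Heart rate correlates with MAD at r ≈ 0.97 within
subjects across the ambulatory activities, supporting the pattern-based
intensity ordering. The fitted sedentary/light, light/moderate and
moderate/vigorous cut-points are nearly identical between devices; on
this cleanly separated synthetic cohort they come from the documented
gap-midpoint fallback (`SeparationWarning`), and classification against
both the fitted and the adult universal cut-points is error-free
(`misclassification_pct` 0.0). Output files (MAD table, agreement pairs,
correlation table, cut-point JSON, classification report, run manifest)
land in `demo_out/`.

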