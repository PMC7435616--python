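# Methods

This note documents the models, parameter choices and numerical decisions
behind `posturekit`, and what the synthetic-data tests do and do not show
about real recordings.

## The posture model

A thigh-worn triaxial accelerometer measures gravity plus dynamic
acceleration in g. With the z sensing axis perpendicular to the thigh's long
axis, the *normalized z index*

    z = |a_z| / ||a||            (clamped to [0, 1])

is the sine of the thigh's inclination from vertical: 0 when standing
(vertical thigh), 1 when sitting (horizontal thigh). The classifier
evaluates it on a gravity estimate obtained with a centered boxcar smoother
(`gravity_smooth_s`, default 2 s ≈ 12 readings at 6.25 Hz); the boxcar was
chosen over an IIR low-pass because it preserves constant signals exactly,
has no startup transient on short streams, and its residual is a natural
dynamic-acceleration estimate. An all-zero acceleration vector (free fall)
has no orientation and is rejected.

The posture rule is *sitting iff z > 0.8*; a reading at exactly 0.8 counts
as standing. The comparison carries a 1e-12 absolute guard so that a stream
sitting numerically on the boundary classifies deterministically as
standing under floating-point filter noise.

## The counter state machine

Per monitored reading:

1. If the dynamic acceleration magnitude (sample minus smoothed gravity)
   exceeds `movement_threshold_g` (default 0.15 g), the machine enters or
   extends the *stepping* state and both posture counters reset to 0.
2. Otherwise the z rule increments exactly one posture counter and zeroes
   the other. While stepping, the reading accrues tentatively as stepping.
3. When a posture counter reaches `counter_limit` readings (default 75,
   i.e. 12 s at 6.25 Hz), the span covered by that run is committed to the
   posture — retroactively relabeling it if it had accrued as stepping —
   and stepping ends. Attributing the committed run to its posture (rather
   than discarding it) conserves time exactly: the three behavior totals
   always sum to the monitored duration.

`counter_limit` is expressed in readings, not seconds, because readings are
the unit the algorithm is defined in; note that 75 readings at the nominal
6.25 Hz is 12 s, not the ~2 s a faster internal reading rate would give, so
deployments with a different reading rate should set `sampling_rate_hz`
accordingly.

Disconnection gaps (and time outside the recording window) are labeled
*unmonitored*, reset the machine, and are excluded from totals. Time lost
this way is recovered, if at all, by the weighted adjustment below. The
0.15 g movement threshold sits ≈5 sd above the generator's default sensor
noise (0.03 g per axis), so clean sitting/standing never triggers stepping,
while stride impulses (~0.9 g) always do.

The 0.8 threshold is applied to the smoothed z per reading (not to a
per-window aggregate): smoothing already suppresses jitter, and per-reading
application keeps the machine identical to a literal per-reading walk of
the decision rules, which the test suite checks against an independently
written naive reference on short streams.

## Weighted time reconciliation

If |elapsed − counted| ≥ 15 min, each behavior is rescaled by
elapsed/counted and rounded to whole minutes by the **largest-remainder
rule**, the unique standard apportionment scheme that conserves the total
exactly: floors are taken first, then leftover minutes go to the largest
fractional remainders (ties broken toward the larger component, then fixed
behavior order). The canonical scenario — (75 stepping, 10 standing, 15
sitting) counted vs 115 elapsed — rescales to (86.25, 11.5, 17.25) and
rounds to (86, 12, 17). Because that scenario has a discrepancy of exactly
15 minutes, the trigger is *at or above* the threshold, not strictly above.
An elapsed time with no counted minutes at all cannot be redistributed and
raises instead.

## Step detection

The detector scans the jerk magnitude ‖Δa‖ (first difference of the
acceleration vector) for peaks with a 0.3 s refractory spacing. Jerk passes
stride impacts and rejects slow gravity reorientation, and unlike a
moving-average residual it carries no ripple from the smoothing window.
The three sensitivity modes are prominence presets — sensitive 0.12 g,
normal 0.25 g, robust 0.40 g per reading — applied as filters over one
candidate peak set, which makes the event nesting robust ⊆ normal ⊆
sensitive structural rather than empirical. Normal balances false positives
and negatives on the generator's gait waveform; robust additionally rejects
isolated small transients such as a seated leg stretch. Windows shorter
than 5 samples yield no events.

## Synthetic data

`generate_signal` renders a bout script into a stream: the thigh
inclination angle is 0 (standing/stepping) or π/2 (sitting) with a linear
1 s ramp at posture changes (instantaneous flips would never stress the
counter logic), plus Gaussian angle jitter (sd 0.02 rad). Stepping bouts
add one impulse per stride (0.9 g, spread over the nearest readings — a
realistic peak dynamic thigh acceleration at a 100 steps/min cadence) and a
small 0.1 g sway sinusoid, plus 0.03 g white sensor noise per axis.
Dropouts follow a renewal process (exponential connected spells of mean
3600/rate, exponential gaps of mean `disconnect_mean_s`), whose long-run
disconnected fraction is mean_gap/(mean_gap + mean_connected); the tests
check coverage against this closed form.

`generate_paired_measurements` draws per-subject criterion totals around
per-behavior means and adds a device bias and disagreement noise (Gaussian
by default; optionally multiplicative lognormal with matched moments, which
produces the skewed regime in which the nonparametric branch of the test
battery gets selected). Defaults emulate a 20-subject occupational
validation study: criterion means (180.5, 75.4, 24.0) min for sitting /
standing / stepping; between-subject sds (92, 36.1, 10.5) min, with the
sitting spread back-computed from an interquartile range via IQR/1.349;
biases (−1.66, −4.85, +1.15) min and disagreement sds (14.6, 13.5, 8.3)
min, the latter derived from limits-of-agreement widths via (upper −
lower)/(2·1.96). Totals are truncated at zero (negative minutes are
impossible); when a behavior's distribution has mass near zero this
truncation slightly attenuates injected biases, so parameter-recovery
experiments use means several sds away from zero.

What the generator does *not* emulate: biomechanically realistic gait
(stride-to-stride variability, asymmetry), postural micro-movements,
fidgeting, sensor drift or calibration error, and non-stationary wear
artifacts. Passing the recovery tests therefore demonstrates the
correctness of the decision logic under the stated signal model, not
field accuracy on human recordings.

## Agreement statistics

- **Normality gate**: Shapiro-Wilk at α = 0.05 on the paired differences
  (t vs Wilcoxon) and on the margins (Pearson vs Spearman) — standard
  practice at n ≈ 20, overridable by calling the individual functions
  directly. Identical differences are reported as degenerate, without a
  fabricated p-value.
- **CCC**: Lin's moment estimator with 1/n scaling; the CI is the Fisher
  z-transform with Lin's asymptotic variance. With |CCC| = 1, zero
  correlation or n ≤ 2 the CI degenerates to the point estimate.
- **McBride bands** are hard-coded at 0.90 / 0.95 / 0.99.
- **Bland-Altman** uses the conventional 1.96 multiplier (not the
  small-sample t quantile) and ddof = 1.
- **TOST** uses the 90% CI of the mean paired difference
  (m ± t₀.₉₅,ₙ₋₁·se); equivalence = CI ⊆ ±half-width, with a 1e-12
  containment guard. Zero-variance differences collapse the CI to the
  point estimate; the verdict is still defined.
- **Equivalence regions** default to fraction × criterion *mean*, rounded
  half-up to whole minutes (an explicitly configurable policy); an absolute
  per-behavior override exists for externally pre-specified regions. The
  escalation scan in the fitted report starts at 5% and steps by 5% so it
  reports the true minimal fraction on the grid; the standalone
  `escalate_equivalence` default start is 10%.
- **Multiple testing**: none; behaviors are reported independently.
- Composites (stationary, upright, recording) are summed per subject from
  the base three *before* any statistic is computed.

## Problem sizes and runtime

Test-suite simulations use 30–240 minute sessions at 6.25 Hz (up to ~90k
readings each; the 20-session recovery check runs in a few seconds) and
paired studies of 20–4000 subjects. These sizes give Monte-Carlo error
comfortably below the asserted tolerances (e.g. recovery within 1 minute
per behavior; bias recovery at 2 standard errors of a replicate-averaged
estimate).

## Known limitations

- The step detector is a generic jerk-peak detector with preset
  prominences; it makes no claim of equivalence with any proprietary
  firmware pedometer.
- The classifier assumes the device is worn with the z axis anterior; a
  rotated mounting changes the meaning of the z index.
- Epoch ingestion supports the package's own documented 15-second CSV
  dialect only; vendor exports must be mapped to it.
- Session-total agreement only; no epoch-by-epoch (minute-level) agreement
  statistics.
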