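# Methods

## Task model and coordinate conventions

The screen is a reaching game: targets appear on a circle of radius 2 cm in
12 numbered directions, alternating with returns to the center; a target
not reached within 5 s times out. Sessions hold the two measurement laps
only (outward legs, one trial per lap × direction); practice trials and
return legs are never analyzed and are not represented.

Coordinates are metric (cm) with the origin at the circle center, x
rightward, y upward. Only distance-to-center enters the feature encoding,
so no screen/pixel calibration is needed. Direction numbering is a
clock-face convention for the right hand — direction 12 at the top,
increasing clockwise — with the left-hand layout mirrored about the
vertical axis. The assignment of numbers to angles is a documented
assumption (any bijection consistent between simulation and analysis
works); it is overridable via `direction_angle`'s geometry arguments.

## Feature encoding

Each trial's distance signal d(t)/r (clipped at 1) is linearly interpolated
onto the fixed frame grid t = 0, 0.1, …, 4.9 s. The interpolation rule is a
package choice; the 10-Hz/50-frame grid itself is part of the task
definition. For collected trials the reach frame — `round(collect_time ×
10)`, with the recorded collect time taking precedence over a
distance-threshold detection (`1 − ε`, ε = 0.02) — is set to exactly 1.0
and all later frames to exactly 0.0. Timed-out trials keep their observed
normalized distances across all 50 frames with no forced white frame; this
encoding of timeouts is a package choice. Overshoot beyond the circle clips
to 1.0. A direction missing from a lap yields a zero row and flags the
hand; flagged hands are excluded from training but still scored.

Rows are ordered by direction number (1 at top); flattening is row-major,
giving 600 values for the full image and width × 50 (default 200) for a
window slice with modular wraparound (window "12-3" = rows 12, 1, 2, 3).

## Anomaly model

The detector is a fully connected 600–10–600 autoencoder. The bottleneck
(10 units) is the screening design's fixed compression; all other
architecture and training choices are open and set as package defaults:
logistic sigmoid on both hidden and output layers (features live in [0,1],
so no further standardization is applied), seeded Glorot-uniform
initialization, full-batch Adam (lr 0.01), up to 2000 epochs with early
stopping when the training MSE has not improved by 1e-7 for 200 epochs.
The training loss is the same MSE used for scoring, so training optimizes
the screening statistic directly. Training uses 12 randomly chosen healthy
hands (the split seed is named and recorded); those hands are excluded from
scoring by default. Identical data + config reproduce the model bitwise.

Training diverging to a non-finite loss raises an error naming the epoch;
with the defaults and [0,1] inputs this does not occur in practice.

## Evaluation

Positive class is CTS and anomaly points toward higher MSE; both are fixed,
not configurable. The ROC curve places thresholds at every distinct score
(plus a sentinel above the maximum); a hand is predicted positive when its
score is ≥ the cutoff, so ties at the cutoff are classified positive. The
trapezoidal AUC under this construction is exactly the Mann–Whitney
pair-counting estimate with ties counted half (asserted property).
The Youden-optimal cutoff maximizes sensitivity + specificity − 1, ties
broken toward higher specificity — a screen feeds a confirmatory work-up,
so false positives carry explicit cost. Sensitivity and specificity are
also reported as nearest-integer percentages, matching how such tables are
conventionally printed. The window sweep retrains a fresh autoencoder
(input 200) per start direction on the same healthy training hands and
reports each window's AUC and its own Youden-point operating point.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
any particular patient population:

- **Speed profile**: minimum-jerk position s(τ) = 10τ³ − 15τ⁴ + 6τ⁵, the
  standard model of point-to-point reaching, chosen because it gives a
  closed-form oracle (peak/mean speed = 1.875).
- **Timing**: movement time = 1.875·r / (base_speed · speed_scale ·
  hand multiplier), × opposition_penalty in the penalty directions,
  preceded by a reaction time at the center.
- **Defaults**: base_speed 7.5 cm/s and reaction 0.3 s give healthy
  collect times of ~0.8 s, a comfortable fraction of the 5-s window;
  the impaired profile is speed_scale 0.6 with opposition_penalty 1.5 on
  directions {6..11} (covering both the slow and the discriminative
  opposition-like directions; the set is configurable so tests can place
  the effect anywhere), timeout probability 0.05.
- **Variability**: per-hand lognormal speed multiplier (CV 0.10), per-trial
  lognormal time jitter (CV 0.05), isotropic Gaussian per-sample tremor
  (0.03 cm healthy, 0.05 cm impaired). At 10 Hz a tremor of σ cm reads as
  ~1.4·σ·10 cm/s of apparent finite-difference speed, so tremor defaults
  are kept well below reach speeds; larger values would mask the group
  velocity contrast that the generator is supposed to exhibit.
- **Timeouts**: a timed-out reach follows the same bell-shaped course but
  stalls at 40–80 % of the radius and hovers until the window closes.

What the generator does **not** model: autocorrelated (spectral) tremor,
curved or corrective paths, handedness asymmetries, severity-graded
impairment, touch-registration artifacts. Passing tests therefore show the
pipeline recovers the simulated effect structure — not that any particular
clinical accuracy would be attained on real hands.

## Problem sizes and numerical choices

Stochastic end-to-end checks run 50/50-hand cohorts over seeds 1–10 (the
pipeline takes ~2 s per cohort, the 12-window sweep ~6 s); the acceptance
script uses the study-shaped 27/36 cohort. Degenerate inputs are errors,
not silent results: < 2 samples per trial, < 2 training vectors, a single
class in ROC analysis, an empty validation set after excluding training
hands. Session CSVs round-trip at full float precision (repr on write,
round-trip parsing on read).

## Known limitations

- The default synthetic impairment is strong; at these sample sizes the
  screen separates groups perfectly (AUC 1.0). Dial `speed_scale` toward 1
  and `opposition_penalty` toward 1 for graded difficulty.
- Student's pooled-variance t is the default group test (Welch available
  by flag); no multiple-testing correction is applied across the 12
  directions × 3 metrics.
- The autoencoder is deliberately small and shallow; no convolutional or
  deep variants, no severity regression.
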