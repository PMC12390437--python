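# Methods

This note records the models, parameter choices and numerical conventions
behind `stunwatch`, and what the synthetic-data layer does and does not
emulate.

## Brainwave energy and consciousness

"Brainwave energy" over a window is defined here as the **mean squared
amplitude** (mV²). Mean-square (rather than a sum or an integral) makes the
10% post/pre ratio independent of window length and sample rate, so the
criterion is comparable across recordings. The pre-stun window defaults to
[0, 10) s because the post-stun evaluation windows start at 10 s
(P1 = 10–20 s, P2 = 20–30 s, P3 = 30–40 s); all windows are configurable
and half-open, so no sample is counted twice.

Unconsciousness requires **all three** post-stun windows at or below
criterion = 0.10 × E_pre. The recorded scenario sheets are consistent with
this conjunction (the two unconscious scenarios have every window below
criterion; the two conscious ones have essentially every window above), and
it is the welfare-conservative reading: a single recovering window keeps
the bird classified conscious. The verdict is invariant under uniform
amplitude rescaling, since numerator and denominator scale together — so
amplifier gain does not matter for this rule. The fixed 12 mV real-time
monitor is *not* scale-invariant by construction; it exists as a cheap
per-sample check, applied to the signed amplitude (a sample is flagged
"not stunned" iff v > threshold). On a zero-mean oscillating trace the
per-sample flag therefore flickers; consumers who need a stable verdict
should aggregate over a window, as the examples do.

Displayed energies are rounded half-up to 2 decimals; internal values are
never rounded.

Label curation keeps only the two agreement scenarios (visual and
brainwave both stunned → *stunned*; both conscious → *unstunned*).
Disagreement records (scenarios 2 and 4) are marked *excluded* and logged
with their scenario id rather than dropped silently, so curation is
auditable.

## Digital twin

The conveyor is a stage-index signal 0–4 (idle, reception, stunning,
cutting, plucking). The four configured delays are **dwell times**: a bird
enters reception immediately after t = 0 and enters stage k+1 once the
cumulative dwell of the first k stages has elapsed; the plucking delay is
dwell in the final stage. Defaults (2, 7, 1, 1) s give entry to plucking at
t = 10 s, so a 10 s run traverses 0 → 4; the 7 s stunning dwell matches the
nominal 7 ± 0.6 s shock. Reaching index 4 therefore requires
duration ≥ delays[0] + delays[1] + delays[2]. The step size must not exceed
the smallest dwell, otherwise a stage could be skipped between ticks, and
this is rejected at configuration time.

The voltage loop is a **positional PID** (out = kp·e + ki·∫e·dt + kd·ė,
derivative on the error) with output clamped to a configurable range and
clamping anti-windup: the integral is frozen on any tick whose unclamped
output saturates. The weight → setpoint map is affine with a clamp,
defaulting to the 80–160 V range observed across bird weights on a real
line; the slope/offset are site calibration, deliberately configuration
rather than science. In `run_twin` the command feeds a first-order actuator
(τ = 0.5 s) whose output is the measured voltage; the emitted event voltage
is the clamped PID command, so the event stream never leaves the safe
range. Each bird gets its own pass over the line (single bird per shackle,
no queueing); with the default entry interval equal to the traversal time
at most one bird is on the line at a time.

## Tracking

State [u, v, u̇, v̇, w, h]: constant-velocity centers, random-walk size (no
size velocity). The measurement update x = x̂ + K(z − Hx̂) is implemented
exactly; K comes either from a user-supplied fixed gain or, by default,
from Kalman covariance propagation with diagonal process noise
(q_pos = 1 px², q_vel = 0.1 (px/frame)², q_size = 1 px² per frame) and
measurement noise r = 1 px². These defaults assume detector jitter of
order 1 px on ~10–100 px boxes; they are not critical for the shipped
tests, which either use full-correction fixed gains (exactness checks) or
only require boundedness.

Association maximizes total IoU via the Hungarian algorithm on a 1 − IoU
cost with a hard gate (default 0.3; pairs below the gate are never
matched). The gate sits below the 0.75 evaluation threshold on purpose:
association tolerance is a tracking concern, scoring strictness an
evaluation one. Lifecycle: birth immediately on an unmatched detection,
death after 3 consecutive misses — long enough to survive the brief
occlusions at stage boundaries, short enough not to drag stale tracks
across birds. Time is measured in frames; any frame rate lives in
configuration only.

## Evaluation

Boxes are center-format (cx, cy, w, h) everywhere; corner form appears
only inside the IoU computation. Matching is greedy in descending
confidence (ties: input order); each detection takes the best available
ground truth in its frame at IoU ≥ threshold, preferring same-class
matches, and each ground truth is consumed at most once. A cross-class
match is a misclassification FP and consumes the ground truth (so it does
not additionally count as a miss); a detection with no qualifying ground
truth is a background FP; TN ≡ 0 because "background correctly not
detected" has no countable unit in detection. Unmatched predictions count
only as FPs — the two background→prediction rows of the printed
determination table duplicate the background-FP cells and are reported as
zeros.

AP uses all-point interpolation (area under the running-max precision
envelope over recall), the modern convention. Inside PR-curve construction
the zero-recall point takes precision 1; in summary output a 0/0 precision
or recall is reported as undefined (`None`) rather than invented.
Per-class AP classifies detections by *predicted* class and scores them
against that class's ground truth only.

## Dataset operations

The 3:1:1 split takes train = floor(0.6·n) and halves the remainder
between test and validation, odd leftover to test — the unique simple
rounding rule giving 614/205/205 from 1024. The shuffle is a seeded
permutation.

Augmentation operators: horizontal flip (cx′ = W − cx, continuous, an
exact involution), uniform +10% scaling (image resampled bilinearly, box
coordinates and sizes multiplied by the factor), and HSV dithering with
per-image uniform offsets within ±(10°, 0.1, 0.1) — magnitudes are a
package default, as no canonical values exist. Hue offsets wrap modulo
360° because hue is circular (clipping would pile red hues at an arbitrary
cut); saturation and value are clipped to [0, 1]. Geometric operators never
alter class labels, and every variant carries exactly its source's boxes.
The amplification factor (3 variants per image, optionally keeping
originals) is configuration; no particular corpus size is privileged.

## Synthetic data

The generators define the study conditions for every test:

* **Scene**: birds enter at the left edge at a fixed frame interval and
  move horizontally at constant speed (default 8 px/frame in a 640×480
  field, 60×90 px boxes, ±10% per-bird size jitter), with optional seeded
  vertical sway; the class flips unstunned → stunned at a fixed per-bird
  age (default 20 frames), standing in for the water-bath passage.
* **Detector**: per-box independent misses (miss_prob), centered Gaussian
  center jitter (jitter_sigma), Poisson background false positives
  (fp_rate), confidences Beta(5,2) for true and Beta(2,5) for false
  detections so PR curves are non-degenerate. Noise acts in box-coordinate
  space; the raster chain is exercised separately, which keeps tracker and
  evaluator tests fast.
* **Imaging chain**: pixel-center sampling of a continuous field (origin
  at the first pixel's center, so halving the pitch nests the grids),
  i.i.d. Gaussian transmission noise, and a 3×3 mean-filter cleanup whose
  interior variance reduction (σ²/9) is verified by test.
* **EEG**: low-pass-filtered Gaussian noise (4th-order Butterworth,
  12 Hz cutoff at 100 Hz sampling, 40 s) with the pre-stun segment scaled
  to the requested RMS and the post-stun segment scaled so the realized
  post/pre energy ratio equals the request to floating-point precision.
* **Golden fixture**: 205 single-bird frames constructed so that matching
  at IoU 0.75 yields exactly 104 + 99 true positives, one
  misclassification in each direction and no misses — the evaluation
  module's end-to-end regression anchor.

What this does **not** emulate: real plumage appearance, lighting, wet
feathers, occlusion between adjacent shackles, correlated detector errors,
EEG artifacts (movement, electrode contact) or any learned detector's
error structure. Passing tests therefore validate the measurement and
decision logic under controlled error models, not field performance of a
trained detector.

## Problem sizes and determinism

Statistical checks use 10⁴ Bernoulli trials (detector recall) and 10⁵
pixels (noise variance), sized so their 3σ / 5% tolerances are comfortably
resolvable. PID steady-state tests run 2×10⁴ steps at dt = 0.01 s. All
stochastic components take explicit seeds; the CLI derives per-module
streams from one global seed via `numpy.random.SeedSequence` spawn-key
hashing, so modules never share a stream and runs are bit-reproducible.

## Known limitations

* The per-sample 12 mV monitor uses the signed amplitude; an RMS- or
  envelope-based monitor would be steadier but is a different rule.
* The weight→voltage setpoint map has no physiological calibration here;
  it must be fitted on site.
* The tracker has no appearance model, so two same-size birds crossing at
  high speed can swap identities; on conveyor scenes (near-parallel
  trajectories) this is rare.
* Evaluation implements a single-threshold score, not a COCO-style
  multi-threshold sweep.
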