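# stunwatch

A monitoring toolkit for **humane electrical stunning of poultry**. On a
commercial line, birds hang from an overhead conveyor, pass through an
electrified water bath, and must be verifiably unconscious before the cut.
`stunwatch` implements the computational core of a camera-plus-EEG welfare
monitor for this process: consciousness classification from brainwave
energy, a digital twin of the conveyor with PID voltage control,
multi-object tracking of birds across frames, detection-quality scoring,
and the dataset split/augmentation used to prepare a two-class
(stunned / unstunned) training corpus. A synthetic-data layer stands in for
the cameras, the trained detector, and the EEG amplifier, so everything is
testable on a laptop.

It is written for researchers and engineers in precision livestock farming
who need the *measurement and decision logic* of such a system — not the
neural network itself, which is out of scope here.

## The core rules and models

**Brainwave energy criterion.** For a trace v(t) (mV), the windowed energy
is the mean square E[a,b) = mean(v²) over t ∈ [a,b). With pre-stun energy
E_pre (window [0,10) s) and post-stun windows P1 = [10,20), P2 = [20,30),
P3 = [30,40) s, a bird is **unconscious** iff

    max(E_P1, E_P2, E_P3) ≤ 0.10 · E_pre.

A visual checklist (head raise, eye opening, wing movement — all absent ⇒
visually stunned) is crossed with the brainwave verdict into four
scenarios; only agreement scenarios (both stunned → label *stunned*; both
conscious → label *unstunned*) are kept as training labels, the two
disagreement scenarios are excluded. A separate real-time monitor flags any
sample whose amplitude exceeds a fixed 12 mV threshold as *not stunned*.

**Tracking.** Each bird carries state x = [u, v, u̇, v̇, w, h]ᵀ (box center,
center velocity, box size). Prediction is constant-velocity; a matched
detection z = (u, v, w, h) corrects it via

    x = x̂ + K (z − H x̂),

with K either fixed or computed as a Kalman gain (default). Association is
the Hungarian assignment on 1 − IoU with an IoU gate; tracks are born from
unmatched detections and die after 3 consecutive misses.

**Evaluation.** IoU = intersection / union; at the working threshold
IoU = 0.75, detections are matched greedily by descending confidence.
Precision = TP/(TP+FP), Recall = TP/(TP+FN), AP is the area under the
precision envelope over recall, and mAP is the mean AP over the two
classes. The confusion matrix distinguishes same-class matches (TP),
cross-class matches (misclassification FPs), background hallucinations,
and missed birds; true negatives are identically zero.

**Digital twin.** Stage index 0–4 (idle, reception, stunning, cutting,
plucking) advances after per-stage dwell times (default 2, 7, 1, 1 s —
a 7 s shock is the line's nominal stun). During stunning, a positional PID
controller with output clamping and anti-windup drives the voltage to an
affine weight-dependent setpoint clamped to 80–160 V.

## Worked example

```bash
python examples/classify_eeg.py
```

```
pre-stun energy       : 25.00 mV^2
criterion (10% rule)  : 2.50 mV^2
P1, P2, P3 energies   : 1.309, 1.274, 1.167 mV^2
classification        : unconscious
```

A synthetic 40 s trace with pre-stun RMS 5 mV (energy 25 mV²) and post-stun
energy at 5% of pre-stun: all three windows sit below the 2.50 mV²
criterion, so the bird is classified unconscious — a correct stun.

```bash
python examples/track_and_evaluate.py
```

```
ground-truth boxes : 84
detections         : 85
tracks created     : 8 (3 real birds)
AP[stunned  ]      : 0.957
AP[unstunned]      : 0.950
mAP                : 0.953
confusion          : {'TP_1': 23, 'TP_2': 57, 'FP_1': 0, 'FP_2': 0, 'FP_3': 3,
                      'FP_4': 2, 'FN_1': 1, 'FN_2': 3, 'FN_3': 0, 'FN_4': 0, 'TN': 0}
```

Three birds cross the camera; the emulated detector jitters boxes, misses
5% of them and hallucinates ~0.1 boxes/frame. The five spurious detections
spawn five short-lived extra tracks; four jittered boxes fall below the
0.75 IoU bar and cost recall. `examples/run_digital_twin.py` and
`examples/split_and_amplify.py` demonstrate the twin and the corpus
operations the same way.

There is also a thin CLI mirroring the library
(`stunwatch eeg-classify|eeg-monitor|simulate|track|evaluate|split|augment|synth`);
run `stunwatch --help`.

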