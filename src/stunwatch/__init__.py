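"""stunwatch: monitoring toolkit for humane electrical stunning of poultry.

Library surface:

* :mod:`stunwatch.datamodel` — domain records and file I/O,
* :mod:`stunwatch.eeg` — brainwave energy criterion, visual judgement,
  scenario curation, real-time threshold monitor,
* :mod:`stunwatch.twin` — conveyor / PID digital twin,
* :mod:`stunwatch.tracking` — Kalman-style multi-object tracking,
* :mod:`stunwatch.evaluation` — IoU, confusion counts, AP/mAP,
* :mod:`stunwatch.dataset` — 3:1:1 split and image amplification,
* :mod:`stunwatch.synthetic` — generators standing in for cameras,
  detector and EEG amplifier.
"""

from .datamodel import (
    BoundingBox,
    Detection,
    EEGTrace,
    GroundTruthBox,
    TwinEvent,
    VisualJudgement,
)
from .eeg import (
    EnergyReport,
    ScenarioRecord,
    analyze_trace,
    assign_scenario,
    classify_brainwave,
    classify_visual,
    threshold_monitor,
    unconsciousness_criterion,
    window_energy,
)
from .evaluation import (
    average_precision,
    evaluate_detections,
    iou,
    match_detections,
    mean_average_precision,
)
from .dataset import amplify, horizontal_flip, hsv_dither, scale_up, split_dataset
from .tracking import TrackerConfig, associate, predict, step_tracker, track_sequence, update
from .twin import ConveyorConfig, PIDState, TwinConfig, pid_step, run_twin, simulate_conveyor, voltage_setpoint
from .synthetic import (
    DetectorNoise,
    SceneConfig,
    emulate_detector,
    generate_eeg,
    generate_scene,
    table6_fixture,
)

__version__ = "0.1.0"


def derive_seed(seed: int, module: str) -> int:
    """Stable per-module seed derived from a single global seed.

    Uses numpy's SeedSequence spawn-key hashing so different modules never
    share a stream; the result fits in 31 bits.
    """
    import numpy as np

    ss = np.random.SeedSequence([seed, *module.encode()])
    return int(ss.generate_state(1)[0] % (2**31))
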