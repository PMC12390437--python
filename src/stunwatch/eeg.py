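"""Brainwave energy criterion, visual-judgement rule and scenario curation.

A bird is deemed unconscious when its post-stun brainwave energy drops to
10% of the pre-stun level or lower.  Energy here is the mean squared
amplitude (mV²) over a time window, which makes the 10% ratio independent of
window length.  Post-stun energy is evaluated in three windows: P1 = 10–20 s,
P2 = 20–30 s, P3 = 30–40 s after the shock; unconsciousness requires all
three to sit at or below the criterion.

The visual judgement is a three-item behavioural checklist (head raise,
eye opening, wing movement); a bird is visually stunned only when all three
are absent.  Crossing the two judgements yields four scenarios used to
curate training labels:

====  ===============  ================  =============
 #    visual           brainwave         curated label
====  ===============  ================  =============
 1    stunned          unconscious       stunned
 2    not stunned      unconscious       excluded
 3    not stunned      conscious         unstunned
 4    stunned          conscious         excluded
====  ===============  ================  =============

Only agreement scenarios (1 and 3) enter the training set; disagreements are
flagged, never silently dropped.

A separate real-time monitor thresholds the raw amplitude at a fixed level
(12 mV by default) producing a per-sample stunned / not-stunned series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from .datamodel import EEGTrace, ValidationError, VisualJudgement

__all__ = [
    "UNCONSCIOUSNESS_RATIO",
    "DEFAULT_THRESHOLD_MV",
    "DEFAULT_PRE_WINDOW",
    "DEFAULT_POST_WINDOWS",
    "EnergyReport",
    "ScenarioRecord",
    "window_energy",
    "unconsciousness_criterion",
    "display_round",
    "classify_brainwave",
    "classify_visual",
    "assign_scenario",
    "analyze_trace",
    "threshold_monitor",
]

logger = logging.getLogger(__name__)

#: Post-stun energy at or below this fraction of pre-stun energy means
#: unconscious.
UNCONSCIOUSNESS_RATIO = 0.10

#: Fixed amplitude threshold (mV) of the real-time monitor.
DEFAULT_THRESHOLD_MV = 12.0

#: Pre-stun energy window (s): the recording before the post-stun windows.
DEFAULT_PRE_WINDOW = (0.0, 10.0)

#: Post-stun evaluation windows P1, P2, P3 (s).
DEFAULT_POST_WINDOWS = ((10.0, 20.0), (20.0, 30.0), (30.0, 40.0))


@dataclass(frozen=True)
class EnergyReport:
    """Windowed energies (mV²) and the derived unconsciousness criterion."""

    e_pre: float
    criterion: float
    e_p1: float
    e_p2: float
    e_p3: float

    def __post_init__(self) -> None:
        for name in ("e_pre", "e_p1", "e_p2", "e_p3"):
            if getattr(self, name) < 0:
                raise ValidationError(f"energy {name} must be >= 0")

    @property
    def post_energies(self) -> tuple[float, float, float]:
        return (self.e_p1, self.e_p2, self.e_p3)


@dataclass(frozen=True)
class ScenarioRecord:
    """Outcome of crossing the visual and brainwave judgements for one bird."""

    visual_stunned: bool
    brainwave_unconscious: bool
    scenario: int
    curated_label: str  # "stunned" | "unstunned" | "excluded"


def window_energy(trace: EEGTrace, t_start: float, t_end: float) -> float:
    """Mean squared amplitude (mV²) of ``trace`` over ``[t_start, t_end)``.

    Scales as c² when amplitudes scale by c; raises if the window contains
    no samples.
    """
    if t_start >= t_end:
        raise ValueError(f"empty window [{t_start}, {t_end}): start must precede end")
    mask = (trace.t >= t_start) & (trace.t < t_end)
    if not np.any(mask):
        raise ValueError(
            f"window [{t_start}, {t_end}) contains no samples of the trace"
        )
    return float(np.mean(np.square(trace.v[mask])))


def unconsciousness_criterion(e_pre: float) -> float:
    """The unconsciousness criterion: 10% of the pre-stun energy (mV²)."""
    if e_pre < 0:
        raise ValueError(f"pre-stun energy must be >= 0, got {e_pre}")
    return UNCONSCIOUSNESS_RATIO * e_pre


def display_round(value: float, ndigits: int = 2) -> float:
    """Half-up rounding for display; internal values are never rounded."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def classify_brainwave(report: EnergyReport) -> str:
    """``"unconscious"`` iff every post-stun window energy ≤ the criterion.

    Invariant under uniform amplitude rescaling of the whole trace, since
    criterion and window energies scale together.
    """
    if max(report.post_energies) <= report.criterion:
        return "unconscious"
    return "conscious"


def classify_visual(judgement: VisualJudgement) -> str:
    """``"stunned"`` iff the bird neither raises its head, opens its eyes,
    nor moves its wings; otherwise ``"not_stunned"``."""
    if not (judgement.raise_head or judgement.open_eyes or judgement.move_wing):
        return "stunned"
    return "not_stunned"


_SCENARIO = {
    # (visual stunned, brainwave unconscious) -> (scenario, curated label)
    (True, True): (1, "stunned"),
    (False, True): (2, "excluded"),
    (False, False): (3, "unstunned"),
    (True, False): (4, "excluded"),
}


def assign_scenario(visual: str, brain: str) -> ScenarioRecord:
    """Combine the two judgements into a scenario (1–4) and curated label.

    Labels are kept only when the judgements agree (scenarios 1 and 3);
    disagreements are excluded from training and logged.
    """
    if visual not in ("stunned", "not_stunned"):
        raise ValueError(f"visual judgement must be stunned/not_stunned, got {visual!r}")
    if brain not in ("unconscious", "conscious"):
        raise ValueError(f"brainwave judgement must be unconscious/conscious, got {brain!r}")
    vis = visual == "stunned"
    unc = brain == "unconscious"
    scenario, label = _SCENARIO[(vis, unc)]
    if label == "excluded":
        logger.info(
            "scenario %d disagreement (visual=%s, brainwave=%s): record excluded",
            scenario, visual, brain,
        )
    return ScenarioRecord(
        visual_stunned=vis,
        brainwave_unconscious=unc,
        scenario=scenario,
        curated_label=label,
    )


def analyze_trace(
    trace: EEGTrace,
    pre_window: tuple[float, float] = DEFAULT_PRE_WINDOW,
    post_windows: tuple[tuple[float, float], ...] = DEFAULT_POST_WINDOWS,
) -> EnergyReport:
    """Windowed-energy report for a trace: pre-stun energy, criterion, P1–P3."""
    if len(post_windows) != 3:
        raise ValueError("expected exactly three post-stun windows (P1, P2, P3)")
    e_pre = window_energy(trace, *pre_window)
    e1, e2, e3 = (window_energy(trace, a, b) for a, b in post_windows)
    return EnergyReport(
        e_pre=e_pre,
        criterion=unconsciousness_criterion(e_pre),
        e_p1=e1, e_p2=e2, e_p3=e3,
    )


def threshold_monitor(
    trace: EEGTrace, threshold: float = DEFAULT_THRESHOLD_MV
) -> tuple[np.ndarray, list[tuple[float, str]]]:
    """Per-sample binary classification against a fixed amplitude threshold.

    A sample is labelled ``not_stunned`` when its amplitude exceeds
    ``threshold`` (mV), else ``stunned``.  Returns the boolean stunned mask
    (True = stunned) and the list of transition events ``(time, new_label)``,
    one at every label change including the first sample.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0 mV, got {threshold}")
    stunned = trace.v <= threshold
    transitions: list[tuple[float, str]] = []
    prev: bool | None = None
    for ti, flag in zip(trace.t, stunned):
        if prev is None or flag != prev:
            transitions.append((float(ti), "stunned" if flag else "not_stunned"))
            prev = bool(flag)
    return stunned, transitions
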