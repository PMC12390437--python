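"""Synthetic stand-ins for the cameras, the trained detector and the EEG amp.

Every downstream module is testable without slaughterhouse footage:

* :func:`generate_scene` emulates birds hanging from the overhead conveyor
  and drifting across the camera at constant speed, with seeded sway; a
  bird's class flips unstunned → stunned a fixed number of frames after it
  enters (its passage through the water bath).
* :func:`emulate_detector` corrupts ground truth the way a trained detector
  would: missed boxes, center jitter, spurious background boxes, and
  confidence scores drawn high for true detections and low for false ones.
* :func:`sample_sensor` / :func:`add_noise` / :func:`denoise` model the
  imaging chain: pixel-center discretization of a continuous intensity
  field, i.i.d. Gaussian transmission noise, and a mean-filter cleanup.
* :func:`generate_eeg` produces band-limited traces whose post-stun
  mean-square energy is an exact requested fraction of the pre-stun energy.
* :func:`table6_fixture` builds a detection set whose confusion matrix at
  IoU 0.75 is fixed by construction (104 + 99 true positives, one
  misclassification in each direction, no misses) — the golden input for
  the evaluation module.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage, signal

from .datamodel import (
    STUNNED,
    UNSTUNNED,
    BoundingBox,
    Detection,
    EEGTrace,
    GroundTruthBox,
)

__all__ = [
    "SceneConfig",
    "DetectorNoise",
    "generate_scene",
    "emulate_detector",
    "sample_sensor",
    "add_noise",
    "denoise",
    "generate_eeg",
    "table6_fixture",
]


@dataclass(frozen=True)
class SceneConfig:
    """Geometry and kinematics of a synthetic conveyor scene.

    Birds enter at the left edge every ``entry_interval`` frames and move
    right at ``speed`` px/frame; ``stun_frame`` is the per-bird age (frames
    after entry) at which its class flips to stunned.  ``sway`` is the
    standard deviation (px) of the seeded vertical sway; ``size_jitter`` the
    fractional spread of per-bird body size.
    """

    nx: int = 640
    ny: int = 480
    n_frames: int = 40
    n_birds: int = 4
    entry_interval: int = 10
    speed: float = 8.0
    box_w: float = 60.0
    box_h: float = 90.0
    size_jitter: float = 0.1
    sway: float = 0.0
    stun_frame: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nx <= 0 or self.ny <= 0:
            raise ValueError("image size must be positive")
        if self.speed < 0:
            raise ValueError("speed must be >= 0")


def generate_scene(cfg: SceneConfig) -> list[list[GroundTruthBox]]:
    """Per-frame ground truth for birds crossing the camera field.

    Deterministic per seed; with ``speed`` 0 and ``sway`` 0 every frame
    repeats the same boxes.
    """
    rng = np.random.default_rng(cfg.seed)
    sizes = []
    for _ in range(cfg.n_birds):
        jw = 1.0 + rng.uniform(-cfg.size_jitter, cfg.size_jitter)
        jh = 1.0 + rng.uniform(-cfg.size_jitter, cfg.size_jitter)
        sizes.append((cfg.box_w * jw, cfg.box_h * jh))
    sway = rng.normal(0.0, cfg.sway or 0.0, size=(cfg.n_birds, cfg.n_frames)) \
        if cfg.sway > 0 else np.zeros((cfg.n_birds, cfg.n_frames))

    frames: list[list[GroundTruthBox]] = []
    for f in range(cfg.n_frames):
        boxes: list[GroundTruthBox] = []
        for b in range(cfg.n_birds):
            age = f - b * cfg.entry_interval
            if age < 0:
                continue
            w, h = sizes[b]
            cx = w / 2.0 + cfg.speed * age
            cy = cfg.ny / 2.0 + sway[b, f]
            if cx + w / 2.0 > cfg.nx:
                continue  # bird has left the field of view
            label = STUNNED if age >= cfg.stun_frame else UNSTUNNED
            boxes.append(
                GroundTruthBox(
                    box=BoundingBox(cx, cy, w, h),
                    label=label, frame=f, object_id=b,
                )
            )
        frames.append(boxes)
    return frames


@dataclass(frozen=True)
class DetectorNoise:
    """Error profile of the emulated detector.

    True detections keep their box up to centered Gaussian center jitter
    (``jitter_sigma`` px) and are dropped independently with ``miss_prob``;
    Poisson(``fp_rate``) spurious boxes appear per frame.  Confidences are
    Beta(*tp_score*) for true and Beta(*fp_score*) for false detections, so
    PR curves are non-degenerate by default.
    """

    jitter_sigma: float = 0.0
    miss_prob: float = 0.0
    fp_rate: float = 0.0
    tp_score: tuple[float, float] = (5.0, 2.0)
    fp_score: tuple[float, float] = (2.0, 5.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.miss_prob <= 1.0:
            raise ValueError("miss_prob must lie in [0, 1]")
        if self.jitter_sigma < 0 or self.fp_rate < 0:
            raise ValueError("jitter_sigma and fp_rate must be >= 0")


def emulate_detector(
    gt_frames: Sequence[Sequence[GroundTruthBox]],
    noise: DetectorNoise,
    seed: int = 0,
    image_size: tuple[int, int] = (640, 480),
) -> list[list[Detection]]:
    """Corrupt per-frame ground truth into a per-frame detection stream."""
    rng = np.random.default_rng(seed)
    nx, ny = image_size
    out: list[list[Detection]] = []
    for f, frame_gt in enumerate(gt_frames):
        dets: list[Detection] = []
        for g in frame_gt:
            if rng.random() < noise.miss_prob:
                continue
            dx, dy = rng.normal(0.0, noise.jitter_sigma, size=2) \
                if noise.jitter_sigma > 0 else (0.0, 0.0)
            score = float(rng.beta(*noise.tp_score))
            dets.append(
                Detection(
                    box=BoundingBox(g.box.cx + dx, g.box.cy + dy, g.box.w, g.box.h),
                    score=score, label=g.label, frame=g.frame,
                )
            )
        for _ in range(rng.poisson(noise.fp_rate)):
            w = float(rng.uniform(20.0, 100.0))
            h = float(rng.uniform(20.0, 120.0))
            cx = float(rng.uniform(w / 2, nx - w / 2))
            cy = float(rng.uniform(h / 2, ny - h / 2))
            label = STUNNED if rng.random() < 0.5 else UNSTUNNED
            dets.append(
                Detection(
                    box=BoundingBox(cx, cy, w, h),
                    score=float(rng.beta(*noise.fp_score)),
                    label=label, frame=f,
                )
            )
        out.append(dets)
    return out


# ---------------------------------------------------------------------------
# Imaging-chain model: discretization, transmission noise, edge processing
# ---------------------------------------------------------------------------

def sample_sensor(
    image_fn: Callable[[np.ndarray, np.ndarray], np.ndarray],
    nx: int,
    ny: int,
    pitch: float = 1.0,
) -> np.ndarray:
    """Discretize a continuous intensity field at the pixel centers.

    ``I[j, i] = image_fn(x_i, y_j)`` with the origin at the first pixel's
    center and ``pitch`` spacing, so halving the pitch while doubling the
    resolution keeps every coincident center's value.  ``image_fn`` must
    accept numpy arrays (it is evaluated on a meshgrid).
    """
    if nx < 1 or ny < 1:
        raise ValueError("resolution must be at least 1×1")
    x = np.arange(nx) * pitch
    y = np.arange(ny) * pitch
    xx, yy = np.meshgrid(x, y)
    return np.asarray(image_fn(xx, yy), dtype=float)


def add_noise(raster: np.ndarray, sigma: float, seed: int = 0) -> np.ndarray:
    """Add i.i.d. centered Gaussian transmission noise of variance sigma²."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    raster = np.asarray(raster, dtype=float)
    if sigma == 0:
        return raster.copy()
    rng = np.random.default_rng(seed)
    return raster + rng.normal(0.0, sigma, size=raster.shape)


def denoise(raster: np.ndarray, size: int = 3) -> np.ndarray:
    """Edge-processing cleanup: a ``size``×``size`` mean filter.

    For i.i.d. noise the interior-pixel variance drops by 1/size².
    """
    if size < 1 or size % 2 == 0:
        raise ValueError("filter size must be a positive odd integer")
    return ndimage.uniform_filter(np.asarray(raster, dtype=float),
                                  size=size, mode="nearest")


# ---------------------------------------------------------------------------
# EEG generator
# ---------------------------------------------------------------------------

def generate_eeg(
    pre_level: float,
    post_ratio: float,
    t_stun: float = 10.0,
    t_end: float = 40.0,
    sample_rate: float = 100.0,
    cutoff_hz: float = 12.0,
    seed: int = 0,
) -> EEGTrace:
    """Band-limited EEG whose post-stun energy ratio is exactly as requested.

    The trace runs on [0, ``t_end``) at ``sample_rate``; the pre-stun
    segment [0, ``t_stun``) has mean-square energy ``pre_level``² (so
    ``pre_level`` is the RMS amplitude in mV) and the post-stun segment's
    mean-square energy is ``post_ratio`` × the pre-stun energy.  Both
    segments are rescaled to their measured energies, so the realized ratio
    matches the request to floating-point precision.
    """
    if pre_level <= 0:
        raise ValueError("pre_level must be > 0 mV")
    if post_ratio < 0:
        raise ValueError("post_ratio must be >= 0")
    if not 0 < t_stun < t_end:
        raise ValueError("need 0 < t_stun < t_end")
    rng = np.random.default_rng(seed)
    n = int(round(t_end * sample_rate))
    t = np.arange(n) / sample_rate
    white = rng.standard_normal(n)
    nyq = sample_rate / 2.0
    b, a = signal.butter(4, min(cutoff_hz / nyq, 0.99))
    band = signal.filtfilt(b, a, white)

    pre = t < t_stun
    post = ~pre
    v = band.copy()
    ms_pre = float(np.mean(np.square(v[pre])))
    v[pre] *= pre_level / np.sqrt(ms_pre)
    e_pre = pre_level ** 2
    if post_ratio == 0:
        v[post] = 0.0
    else:
        ms_post = float(np.mean(np.square(v[post])))
        v[post] *= np.sqrt(post_ratio * e_pre / ms_post)
    return EEGTrace(t=t, v=v, sample_rate=sample_rate)


# ---------------------------------------------------------------------------
# Golden evaluation fixture
# ---------------------------------------------------------------------------

def table6_fixture(
    seed: int = 0,
    n_tp_stunned: int = 104,
    n_tp_unstunned: int = 99,
    n_cross_stunned: int = 1,
    n_cross_unstunned: int = 1,
) -> tuple[list[GroundTruthBox], list[Detection]]:
    """A detection set with a confusion matrix fixed by construction.

    One ground-truth bird per frame.  ``n_tp_*`` birds of each class get a
    high-IoU same-class prediction; ``n_cross_stunned`` actually-unstunned
    birds are predicted stunned and ``n_cross_unstunned`` actually-stunned
    birds are predicted unstunned (still high IoU).  Every ground truth is
    matched, so at IoU 0.75 the matcher reports exactly these counts with
    zero misses.  Scores and sub-threshold box jitter are seeded.
    """
    rng = np.random.default_rng(seed)
    gt: list[GroundTruthBox] = []
    preds: list[Detection] = []
    plan = (
        [(STUNNED, STUNNED)] * n_tp_stunned
        + [(UNSTUNNED, UNSTUNNED)] * n_tp_unstunned
        + [(UNSTUNNED, STUNNED)] * n_cross_stunned   # FP_1 cells
        + [(STUNNED, UNSTUNNED)] * n_cross_unstunned  # FP_2 cells
    )
    for frame, (actual, predicted) in enumerate(plan):
        w = float(rng.uniform(50.0, 80.0))
        h = float(rng.uniform(70.0, 110.0))
        cx = float(rng.uniform(100.0, 500.0))
        cy = float(rng.uniform(100.0, 350.0))
        gt.append(
            GroundTruthBox(box=BoundingBox(cx, cy, w, h), label=actual,
                           frame=frame, object_id=frame)
        )
        # jitter small enough that IoU stays well above 0.75
        dx, dy = rng.uniform(-1.5, 1.5, size=2)
        preds.append(
            Detection(
                box=BoundingBox(cx + dx, cy + dy, w, h),
                score=float(rng.beta(5.0, 2.0)),
                label=predicted, frame=frame,
            )
        )
    return gt, preds
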