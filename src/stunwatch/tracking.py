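"""Multi-object tracking of birds on the conveyor.

Each tracked bird carries a six-component motion state
``x = [u, v, du, dv, w, h]``: box center, center velocity (px/frame) and box
size.  Centers propagate at constant velocity; width and height follow a
random walk (no size velocity in the state).  A matched detection
``z = (u, v, w, h)`` corrects the prediction through the gain-based update

    x = x_hat + K (z - H x_hat)

where ``H`` projects the state onto measurement space.  Two modes are
provided: a fixed-gain mode with user-supplied ``K``, and a full Kalman mode
(the default) where ``K`` is computed each frame from propagated covariance
with diagonal process/measurement noise.

Track-detection association is a one-to-one assignment maximizing total IoU
(Hungarian algorithm on a 1 − IoU cost), gated so pairs below the IoU gate
are never matched.  Lifecycle: an unmatched detection spawns a track
immediately; an unmatched track increments its miss counter and is dropped
after ``max_misses`` consecutive misses (brief occlusions at stage
boundaries survive).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .datamodel import BoundingBox, Detection
from .evaluation import iou

__all__ = [
    "TrackState",
    "UpdateGains",
    "TrackerConfig",
    "observation_matrix",
    "full_correction_gains",
    "predict",
    "update",
    "associate",
    "step_tracker",
    "track_sequence",
]


def observation_matrix() -> np.ndarray:
    """H mapping the 6-state [u, v, du, dv, w, h] to the measurement
    (u, v, w, h)."""
    H = np.zeros((4, 6))
    H[0, 0] = H[1, 1] = H[2, 4] = H[3, 5] = 1.0
    return H


@dataclass(frozen=True)
class UpdateGains:
    """Gain matrix K (6×4) and observation matrix H (4×6) of the update."""

    K: np.ndarray
    H: np.ndarray = field(default_factory=observation_matrix)

    def __post_init__(self) -> None:
        K = np.asarray(self.K, dtype=float)
        H = np.asarray(self.H, dtype=float)
        object.__setattr__(self, "K", K)
        object.__setattr__(self, "H", H)
        if H.shape != (4, 6):
            raise ValueError(f"H must be 4x6, got {H.shape}")
        if K.shape != (6, 4):
            raise ValueError(f"K must be 6x4, got {K.shape}")


def full_correction_gains() -> UpdateGains:
    """Gains that copy every measured component straight from the detection."""
    return UpdateGains(K=observation_matrix().T)


@dataclass(frozen=True)
class TrackState:
    """Motion state of one tracked bird plus lifecycle bookkeeping."""

    u: float
    v: float
    du: float
    dv: float
    w: float
    h: float
    track_id: int
    miss_count: int = 0
    label: str = "unstunned"
    cov: np.ndarray | None = None  # 6x6, Kalman mode only

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("track box size must be positive")
        if self.miss_count < 0:
            raise ValueError("miss_count must be >= 0")

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.u, self.v, self.du, self.dv, self.w, self.h])

    @property
    def box(self) -> BoundingBox:
        return BoundingBox(self.u, self.v, self.w, self.h)

    def with_vector(self, x: np.ndarray, **kwargs) -> "TrackState":
        u, v, du, dv, w, h = (float(c) for c in x)
        return replace(self, u=u, v=v, du=du, dv=dv,
                       w=max(w, 1e-6), h=max(h, 1e-6), **kwargs)


def _transition_matrix(dt: float) -> np.ndarray:
    F = np.eye(6)
    F[0, 2] = dt
    F[1, 3] = dt
    return F


@dataclass(frozen=True)
class TrackerConfig:
    """Association gate, lifecycle limits, and update-gain mode.

    mode "kalman": K recomputed per frame from covariance with diagonal
    process noise (q_pos, q_vel, q_size per component) and measurement noise
    r.  mode "fixed": the supplied ``gains`` are used verbatim.
    """

    gate: float = 0.3
    max_misses: int = 3
    mode: str = "kalman"
    gains: UpdateGains | None = None
    q_pos: float = 1.0
    q_vel: float = 0.1
    q_size: float = 1.0
    r: float = 1.0
    p0: float = 10.0  # initial state variance

    def __post_init__(self) -> None:
        if not 0.0 <= self.gate <= 1.0:
            raise ValueError("gate must lie in [0, 1]")
        if self.mode not in ("kalman", "fixed"):
            raise ValueError("mode must be 'kalman' or 'fixed'")
        if self.mode == "fixed" and self.gains is None:
            raise ValueError("fixed mode requires explicit gains")

    def process_noise(self) -> np.ndarray:
        return np.diag([self.q_pos, self.q_pos, self.q_vel, self.q_vel,
                        self.q_size, self.q_size])


def predict(state: TrackState, dt: float = 1.0) -> TrackState:
    """Constant-velocity propagation: centers advance by velocity·dt;
    velocities and sizes are unchanged (size is a random walk)."""
    if dt < 0:
        raise ValueError("dt must be >= 0 frames")
    x = _transition_matrix(dt) @ state.vector
    return state.with_vector(x)


def _predict_covariance(cov: np.ndarray, dt: float, Q: np.ndarray) -> np.ndarray:
    F = _transition_matrix(dt)
    return F @ cov @ F.T + Q * dt if dt > 0 else cov.copy()


def update(predicted: TrackState, z: Sequence[float], gains: UpdateGains) -> TrackState:
    """Gain-based measurement correction: x = x̂ + K (z − H x̂), exactly."""
    z = np.asarray(z, dtype=float)
    if z.shape != (4,):
        raise ValueError(f"measurement must be (u, v, w, h), got shape {z.shape}")
    x_hat = predicted.vector
    x = x_hat + gains.K @ (z - gains.H @ x_hat)
    return predicted.with_vector(x)


def _kalman_gains(cov: np.ndarray, r: float) -> UpdateGains:
    H = observation_matrix()
    S = H @ cov @ H.T + r * np.eye(4)
    K = cov @ H.T @ np.linalg.inv(S)
    return UpdateGains(K=K, H=H)


def associate(
    tracks: Sequence[TrackState],
    detections: Sequence[Detection],
    gate: float = 0.3,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """One-to-one track ↔ detection assignment maximizing total IoU.

    Pairs with IoU below ``gate`` are never matched.  Returns
    ``(matches, unmatched_track_indices, unmatched_detection_indices)``;
    every input index appears exactly once across the three outputs.
    """
    if not 0.0 <= gate <= 1.0:
        raise ValueError("gate must lie in [0, 1]")
    if not tracks or not detections:
        return [], list(range(len(tracks))), list(range(len(detections)))
    iou_mat = np.array(
        [[iou(trk.box, det.box) for det in detections] for trk in tracks]
    )
    cost = 1.0 - iou_mat
    cost[iou_mat < gate] = 1e6  # forbidden: below the gate
    rows, cols = linear_sum_assignment(cost)
    matches = [(int(r), int(c)) for r, c in zip(rows, cols) if iou_mat[r, c] >= gate]
    matched_t = {r for r, _ in matches}
    matched_d = {c for _, c in matches}
    unmatched_t = [i for i in range(len(tracks)) if i not in matched_t]
    unmatched_d = [j for j in range(len(detections)) if j not in matched_d]
    return matches, unmatched_t, unmatched_d


def _spawn(det: Detection, track_id: int, cfg: TrackerConfig) -> TrackState:
    cov = cfg.p0 * np.eye(6) if cfg.mode == "kalman" else None
    return TrackState(
        u=det.box.cx, v=det.box.cy, du=0.0, dv=0.0,
        w=det.box.w, h=det.box.h,
        track_id=track_id, miss_count=0, label=det.label, cov=cov,
    )


def step_tracker(
    tracks: Sequence[TrackState],
    frame_detections: Sequence[Detection],
    cfg: TrackerConfig | None = None,
    id_counter: itertools.count | None = None,
) -> list[TrackState]:
    """Advance the tracker one frame: predict → associate → update/lifecycle.

    Matched tracks are corrected with the detection and adopt its class
    label; unmatched detections spawn new tracks; unmatched tracks age and
    die after ``cfg.max_misses`` consecutive misses.
    """
    cfg = cfg or TrackerConfig()
    ids = id_counter if id_counter is not None else itertools.count(
        max((t.track_id for t in tracks), default=-1) + 1
    )
    Q = cfg.process_noise()
    predicted: list[TrackState] = []
    for trk in tracks:
        new = predict(trk, dt=1.0)
        if cfg.mode == "kalman" and trk.cov is not None:
            new = replace(new, cov=_predict_covariance(trk.cov, 1.0, Q))
        predicted.append(new)

    matches, unmatched_t, unmatched_d = associate(predicted, frame_detections, cfg.gate)
    out: list[TrackState] = []
    for ti, di in matches:
        trk, det = predicted[ti], frame_detections[di]
        z = (det.box.cx, det.box.cy, det.box.w, det.box.h)
        if cfg.mode == "kalman":
            gains = _kalman_gains(trk.cov, cfg.r)
            new = update(trk, z, gains)
            cov = (np.eye(6) - gains.K @ gains.H) @ trk.cov
            new = replace(new, cov=cov, miss_count=0, label=det.label)
        else:
            new = update(trk, z, cfg.gains)
            new = replace(new, miss_count=0, label=det.label)
        out.append(new)
    for ti in unmatched_t:
        trk = predicted[ti]
        if trk.miss_count + 1 < cfg.max_misses:
            out.append(replace(trk, miss_count=trk.miss_count + 1))
    for di in unmatched_d:
        out.append(_spawn(frame_detections[di], next(ids), cfg))
    return out


def track_sequence(
    detections_by_frame: Sequence[Sequence[Detection]],
    cfg: TrackerConfig | None = None,
) -> list[list[TrackState]]:
    """Run the tracker over a whole detection sequence.

    Returns the post-update track list at every frame.
    """
    cfg = cfg or TrackerConfig()
    ids = itertools.count(0)
    tracks: list[TrackState] = []
    history: list[list[TrackState]] = []
    for dets in detections_by_frame:
        tracks = step_tracker(tracks, list(dets), cfg, id_counter=ids)
        history.append(list(tracks))
    return history
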