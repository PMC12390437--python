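"""Motion prediction, gain update, IoU association and track lifecycle."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stunwatch.datamodel import BoundingBox, Detection
from stunwatch.evaluation import iou
from stunwatch.synthetic import DetectorNoise, SceneConfig, emulate_detector, generate_scene
from stunwatch.tracking import (
    TrackerConfig,
    TrackState,
    UpdateGains,
    associate,
    full_correction_gains,
    observation_matrix,
    predict,
    step_tracker,
    track_sequence,
    update,
)


def make_track(u=0.0, v=0.0, du=0.0, dv=0.0, w=10.0, h=10.0, tid=0):
    return TrackState(u=u, v=v, du=du, dv=dv, w=w, h=h, track_id=tid)


def det(cx, cy, w=10.0, h=10.0, score=0.9, label="stunned", frame=0):
    return Detection(BoundingBox(cx, cy, w, h), score, label, frame)


class TestPredict:
    def test_constant_velocity_advances_center(self):
        trk = make_track(u=0, v=0, du=1.0, dv=0.0)
        out = predict(trk, dt=1.0)
        assert (out.u, out.v) == (1.0, 0.0)
        assert (out.du, out.dv, out.w, out.h) == (1.0, 0.0, 10.0, 10.0)

    def test_zero_velocity_is_fixed_point(self):
        trk = make_track(u=5, v=7)
        for dt in (0.0, 1.0, 10.0):
            out = predict(trk, dt)
            assert (out.u, out.v, out.w, out.h) == (5.0, 7.0, 10.0, 10.0)

    def test_zero_dt_is_identity(self):
        trk = make_track(u=3, v=4, du=2, dv=-1)
        out = predict(trk, dt=0.0)
        assert np.allclose(out.vector, trk.vector)


class TestUpdate:
    def test_zero_gain_returns_prediction(self):
        trk = make_track(u=3, v=4, du=1, dv=1)
        out = update(trk, (10, 10, 5, 5), UpdateGains(K=np.zeros((6, 4))))
        assert np.allclose(out.vector, trk.vector)

    def test_full_correction_copies_measured_components(self):
        trk = make_track(u=3, v=4, du=1, dv=2, w=10, h=10)
        out = update(trk, (20.0, 30.0, 7.0, 9.0), full_correction_gains())
        assert (out.u, out.v, out.w, out.h) == (20.0, 30.0, 7.0, 9.0)
        assert (out.du, out.dv) == (1.0, 2.0)  # unmeasured components untouched

    def test_scalar_analogue_half_gain(self):
        # x = x_hat + K (z - H x_hat) with x_hat = 0, z = 2, K = 0.5 -> 1.0
        K = np.zeros((6, 4))
        K[0, 0] = 0.5
        trk = make_track(u=0.0)
        out = update(trk, (2.0, 0.0, 10.0, 10.0), UpdateGains(K=K))
        assert out.u == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            update(make_track(), (1.0, 2.0), full_correction_gains())


def brute_force_best_assignment(iou_mat, gate):
    """Exhaustive enumeration over all one-to-one assignments."""
    n_t, n_d = iou_mat.shape
    best, best_total = [], 0.0
    k = min(n_t, n_d)
    for rows in itertools.permutations(range(n_t), k):
        for cols in itertools.permutations(range(n_d), k):
            pairs = [(r, c) for r, c in zip(rows, cols) if iou_mat[r, c] >= gate]
            total = sum(iou_mat[r, c] for r, c in pairs)
            if total > best_total + 1e-12:
                best, best_total = pairs, total
    return best_total


class TestAssociate:
    def test_single_overlapping_pair_matches(self):
        trk = make_track(u=10, v=10, w=10, h=10)
        d = det(11, 10)
        matches, ut, ud = associate([trk], [d], gate=0.3)
        assert matches == [(0, 0)] and ut == [] and ud == []

    def test_below_gate_leaves_both_unmatched(self):
        trk = make_track(u=0, v=0, w=10, h=10)
        d = det(100, 100)
        matches, ut, ud = associate([trk], [d], gate=0.3)
        assert matches == [] and ut == [0] and ud == [0]

    def test_optimal_not_greedy_on_crafted_2x2(self):
        # greedy would grab the single best pair and strand the rest;
        # the optimal assignment takes two moderate overlaps instead
        t1 = make_track(u=0, v=0, w=10, h=10, tid=0)
        t2 = make_track(u=8, v=0, w=10, h=10, tid=1)
        d1 = det(4, 0)   # good with t1, best with t2
        d2 = det(12, 0)  # only decent with t2
        iou_mat = np.array([
            [iou(t1.box, d1.box), iou(t1.box, d2.box)],
            [iou(t2.box, d1.box), iou(t2.box, d2.box)],
        ])
        matches, _, _ = associate([t1, t2], [d1, d2], gate=0.05)
        total = sum(iou_mat[r, c] for r, c in matches)
        assert total == pytest.approx(brute_force_best_assignment(iou_mat, 0.05))
        assert len(matches) == 2

    @given(
        n_tracks=st.integers(0, 4),
        n_dets=st.integers(0, 4),
        seed=st.integers(0, 100),
    )
    def test_association_partitions_inputs(self, n_tracks, n_dets, seed):
        rng = np.random.default_rng(seed)
        tracks = [
            make_track(u=rng.uniform(0, 50), v=rng.uniform(0, 50),
                       w=rng.uniform(5, 15), h=rng.uniform(5, 15), tid=i)
            for i in range(n_tracks)
        ]
        dets = [
            det(rng.uniform(0, 50), rng.uniform(0, 50),
                rng.uniform(5, 15), rng.uniform(5, 15))
            for _ in range(n_dets)
        ]
        matches, ut, ud = associate(tracks, dets, gate=0.3)
        t_seen = sorted([m[0] for m in matches] + ut)
        d_seen = sorted([m[1] for m in matches] + ud)
        assert t_seen == list(range(n_tracks))
        assert d_seen == list(range(n_dets))

    @given(n=st.integers(1, 4), seed=st.integers(0, 50))
    def test_matches_exhaustive_enumeration_total_iou(self, n, seed):
        rng = np.random.default_rng(seed)
        tracks = [make_track(u=rng.uniform(0, 30), v=rng.uniform(0, 30),
                             w=10, h=10, tid=i) for i in range(n)]
        dets = [det(rng.uniform(0, 30), rng.uniform(0, 30)) for _ in range(n)]
        iou_mat = np.array([[iou(t.box, d.box) for d in dets] for t in tracks])
        matches, _, _ = associate(tracks, dets, gate=0.1)
        total = sum(iou_mat[r, c] for r, c in matches)
        assert total == pytest.approx(brute_force_best_assignment(iou_mat, 0.1),
                                      abs=1e-9)


class TestLifecycle:
    def test_new_detection_spawns_exactly_one_track(self):
        tracks = step_tracker([], [det(10, 10)], TrackerConfig())
        assert len(tracks) == 1
        assert (tracks[0].u, tracks[0].v) == (10.0, 10.0)

    def test_tracks_die_after_max_misses_empty_frames(self):
        cfg = TrackerConfig(max_misses=3)
        tracks = step_tracker([], [det(10, 10)], cfg)
        for _ in range(cfg.max_misses):
            tracks = step_tracker(tracks, [], cfg)
        assert tracks == []

    def test_track_survives_brief_occlusion(self):
        cfg = TrackerConfig(max_misses=3, gate=0.1)
        tracks = step_tracker([], [det(10, 10)], cfg)
        tracks = step_tracker(tracks, [], cfg)  # one missed frame
        tid = tracks[0].track_id
        tracks = step_tracker(tracks, [det(10, 10)], cfg)
        assert [t.track_id for t in tracks] == [tid]
        assert tracks[0].miss_count == 0


class TestTrajectoryRecovery:
    def test_noiseless_line_tracked_to_machine_precision(self):
        # known trajectory: center moves +3 px/frame horizontally
        cfg = TrackerConfig(mode="fixed", gains=full_correction_gains(), gate=0.2)
        frames = [[det(10 + 3 * f, 50, frame=f)] for f in range(20)]
        history = track_sequence(frames, cfg)
        for f in range(2, 20):  # burn-in: first frames establish the track
            (trk,) = history[f]
            assert abs(trk.u - (10 + 3 * f)) < 1e-6
            assert abs(trk.v - 50) < 1e-6

    @pytest.mark.parametrize("sigma_pair", [(2.0, 0.5), (0.5, 0.05)])
    def test_mean_error_decreases_with_jitter(self, sigma_pair):
        hi, lo = sigma_pair

        def mean_error(sigma):
            scene = generate_scene(SceneConfig(n_birds=2, n_frames=30, seed=4))
            dets = emulate_detector(scene, DetectorNoise(jitter_sigma=sigma), seed=5)
            history = track_sequence(dets, TrackerConfig(gate=0.2))
            errs = []
            for f, gts in enumerate(scene):
                for g in gts:
                    if not history[f]:
                        continue
                    d = min(np.hypot(t.u - g.box.cx, t.v - g.box.cy)
                            for t in history[f])
                    errs.append(d)
            return np.mean(errs)

        assert mean_error(lo) < mean_error(hi)
        assert mean_error(lo) < 3 * lo + 1.0  # bounded by the noise scale

    def test_id_stability_on_two_object_crossing(self):
        # two birds with distinct sizes cross paths; identities must persist
        cfg = TrackerConfig(gate=0.1)
        frames = []
        for f in range(21):
            a = det(10 + 4 * f, 50, w=10, h=10, frame=f)          # small, L->R
            b = det(90 - 4 * f, 50, w=30, h=30, label="unstunned", frame=f)
            frames.append([a, b])
        history = track_sequence(frames, cfg)
        first = {t.track_id: t.w for t in history[0]}
        last = {t.track_id: t.w for t in history[-1]}
        assert set(first) == set(last)
        small_id = min(first, key=first.get)
        # the small track is still the small box at the end
        assert last[small_id] == min(last.values())
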