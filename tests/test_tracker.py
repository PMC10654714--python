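"""Tracker gating, working-set identities, motion prediction and the
miss-tolerance boundary."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lite3d.roi import BoundingBox
from lite3d.synthetic import FishSpec, SceneConfig, ground_truth_detector, render_scene
from lite3d.tracker import (
    TrackerParams,
    TrackerState,
    TrackThread,
    iou,
    match,
    predict_position,
    step,
)


def _box(x, y, w=10, h=10, frame=0, conf=1.0):
    return BoundingBox(frame, x, y, w, h, confidence=conf)


class TestIoU:
    def test_identical_boxes(self):
        assert iou(_box(3, 4), _box(3, 4)) == 1.0

    def test_disjoint_boxes(self):
        assert iou(_box(0, 0), _box(50, 50)) == 0.0

    def test_half_overlap_area_arithmetic(self):
        # two 10x10 boxes offset by (5,0): inter 50, union 150
        assert iou(_box(0, 0), _box(5, 0)) == pytest.approx(1 / 3)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0, 50), st.floats(0, 50), st.floats(1, 30), st.floats(1, 30),
           st.floats(0, 50), st.floats(0, 50), st.floats(1, 30), st.floats(1, 30))
    def test_symmetric_and_bounded(self, x1, y1, w1, h1, x2, y2, w2, h2):
        b1, b2 = _box(x1, y1, w1, h1), _box(x2, y2, w2, h2)
        v = iou(b1, b2)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(iou(b2, b1))


class TestMatch:
    def _state_with_thread(self, box):
        state = TrackerState(TrackerParams(alpha=0.3, beta=50.0))
        state._new_thread(box)
        return state

    def test_overlapping_detection_matches(self):
        state = self._state_with_thread(_box(100, 100))
        res = match([_box(103, 100, frame=1)], state)
        assert res == {0: 0}

    def test_distance_gate_blocks_high_iou(self):
        # large boxes: big overlap but centers 60 px apart (beta = 50)
        state = TrackerState(TrackerParams(alpha=0.05, beta=50.0))
        state._new_thread(_box(0, 0, 200, 200))
        res = match([_box(60, 0, 200, 200, frame=1)], state)
        assert res == {}

    def test_iou_gate_blocks_near_disjoint(self):
        state = self._state_with_thread(_box(100, 100))
        res = match([_box(112, 100, frame=1)], state)  # close but IoU 0
        assert res == {}

    def test_nearest_center_wins_tie(self):
        state = TrackerState(TrackerParams(alpha=0.1, beta=80.0))
        state._new_thread(_box(100, 100, 30, 30))   # id 0
        state._new_thread(_box(110, 100, 30, 30))   # id 1, nearer
        res = match([_box(108, 100, 30, 30, frame=1)], state)
        assert res == {0: 1}

    def test_one_to_one_assignment(self):
        state = TrackerState(TrackerParams(alpha=0.1, beta=80.0))
        state._new_thread(_box(100, 100, 30, 30))
        dets = [_box(102, 100, 30, 30, frame=1, conf=0.9),
                _box(104, 100, 30, 30, frame=1, conf=0.8)]
        res = match(dets, state)
        assert list(res.values()).count(0) == 1


class TestPredictPosition:
    def test_linear_extrapolation(self):
        t = TrackThread(id=0)
        t.push(_box(-5, -5, 10, 10, frame=0))     # center (0, 0)
        t.push(_box(-3, -4, 10, 10, frame=1))     # center (2, 1)
        pred = t and predict_position(t, 2)
        assert pred.center == (4, 2)
        assert pred.source == "predicted"

    def test_single_box_carried_forward(self):
        t = TrackThread(id=0)
        t.push(_box(10, 20, 8, 8, frame=0))
        pred = predict_position(t, 1)
        assert pred.center == _box(10, 20, 8, 8).center

    def test_stationary_history(self):
        t = TrackThread(id=0)
        t.push(_box(10, 20, frame=0))
        t.push(_box(10, 20, frame=1))
        pred = predict_position(t, 2)
        assert (pred.x, pred.y, pred.w, pred.h) == (10, 20, 10, 10)


class TestStep:
    def test_new_detections_spawn_distinct_threads(self):
        state = TrackerState(TrackerParams())
        res = step(state, [_box(10, 10), _box(200, 200)], 0)
        assert sorted(res.added) == [0, 1]
        assert len(state.threads) == 2

    def test_working_sets_partition(self):
        """P = T - U after every step; A disjoint from U and P."""
        state = TrackerState(TrackerParams(alpha=0.2, beta=60.0, k=10))
        rngpos = [(50.0, 50.0), (250.0, 80.0)]
        for t in range(12):
            live_before = set(state.threads)
            dets = []
            if t < 10:  # target 0 visible for 10 frames
                dets.append(_box(rngpos[0][0] + 2 * t, rngpos[0][1], frame=t))
            if t >= 2:  # target 1 appears at frame 2
                dets.append(_box(rngpos[1][0], rngpos[1][1] + 2 * t, frame=t))
            res = step(state, dets, t)
            u, p, a = set(res.updated), set(res.predicted), set(res.added)
            assert u | p == live_before
            assert u & p == set()
            assert a & (u | p) == set()

    def test_miss_boundary_r_minus_one_survives_r_dies(self):
        params = TrackerParams(alpha=0.2, beta=60.0, k=10)  # r = 5
        assert params.r == 5
        for misses, survives in [(4, True), (5, False)]:
            state = TrackerState(params)
            t = 0
            for _ in range(6):
                step(state, [_box(50.0 + 2 * t, 50, frame=t)], t)
                t += 1
            for _ in range(misses):
                step(state, [], t)
                t += 1
            if survives:
                assert 0 in state.threads
                res = step(state, [_box(50.0 + 2 * t, 50, frame=t)], t)
                assert res.updated == [0]
                assert state.threads[0].consecutive_misses == 0
            else:
                assert 0 not in state.threads

    def test_predicted_boxes_fill_gaps(self):
        state = TrackerState(TrackerParams(alpha=0.2, beta=60.0, k=10))
        for t in range(4):
            step(state, [_box(50 + 3 * t, 50, frame=t)], t)
        step(state, [], 4)
        last = state.threads[0].last_box
        assert last.source == "predicted"
        assert last.frame_index == 4
        # centers 55, 58, 61, 64 -> extrapolated 67 (velocity 3 px/frame)
        assert last.center[0] == pytest.approx(67)

    def test_sequences_emitted_once_stack_full(self):
        params = TrackerParams(alpha=0.2, beta=60.0, k=10)
        state = TrackerState(params)
        for t in range(15):
            res = step(state, [_box(50.0 + t, 50, frame=t)], t)
            if t < 9:
                assert res.ready == []
            else:
                (tid, boxes), = res.ready
                assert tid == 0 and len(boxes) == 10
                assert boxes[-1].frame_index == t

    def test_ids_never_reused(self):
        state = TrackerState(TrackerParams(alpha=0.2, beta=60.0, k=4))
        step(state, [_box(50, 50, frame=0)], 0)
        for t in range(1, 4):  # let thread 0 die (r = 2)
            step(state, [], t)
        assert state.threads == {}
        res = step(state, [_box(50, 50, frame=4)], 4)
        assert res.added == [1]


class TestOnSyntheticScenes:
    def _two_fish_scene(self, dropout=0.0, seed=3):
        cfg = SceneConfig(
            frame_size=(320, 240),
            n_frames=40,
            fish=(
                FishSpec("normal", position=(60.0, 60.0), speed=2.5),
                FishSpec("normal", position=(260.0, 180.0), speed=2.5),
            ),
            seed=seed,
        )
        _, truth = render_scene(cfg)
        dets = ground_truth_detector(truth, dropout_rate=dropout, seed=seed)
        return truth, dets

    def _run(self, dets, params):
        state = TrackerState(params)
        id_by_frame = []
        for t, frame_dets in enumerate(dets):
            step(state, frame_dets, t, params)
            id_by_frame.append({
                tid: th.last_box for tid, th in state.threads.items()
                if th.last_box.frame_index == t
            })
        return state, id_by_frame

    def test_zero_identity_switches_perfect_detections(self):
        truth, dets = self._two_fish_scene(dropout=0.0)
        params = TrackerParams.for_frame((240, 320), k=10)
        state, id_by_frame = self._run(dets, params)
        assert len(state.threads) == 2
        # each tracker id must follow exactly one ground-truth identity
        for tid in state.threads:
            gt_ids = set()
            for t, boxes in enumerate(id_by_frame):
                if tid not in boxes:
                    continue
                bx = boxes[tid]
                best = min(
                    truth.per_frame[t],
                    key=lambda e: abs(e.box.center[0] - bx.center[0])
                    + abs(e.box.center[1] - bx.center[1]),
                )
                gt_ids.add(best.track_id)
            assert len(gt_ids) == 1

    def test_short_dropout_preserves_identity(self, rng):
        truth, dets = self._two_fish_scene(dropout=0.0)
        # knock target 0's detections out for frames 15-16 (2 < r frames)
        for t in (15, 16):
            dets[t] = [d for d in dets[t] if d.center[0] > 150]
        params = TrackerParams.for_frame((240, 320), k=10)
        state, id_by_frame = self._run(dets, params)
        assert sorted(state.threads) == [0, 1]
        gap_sources = [id_by_frame[t][0].source for t in (15, 16)]
        assert gap_sources == ["predicted", "predicted"]
        assert id_by_frame[20][0].source == "detected"
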