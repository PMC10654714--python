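"""Scene-generator contracts: determinism, per-behavior kinematics,
dataset bookkeeping and the detector stand-in."""

import numpy as np
import pytest

from lite3d.losses import class_weights
from lite3d.synthetic import (
    BEHAVIORS,
    BOTTOM_STRIP,
    FishSpec,
    SceneConfig,
    SceneConfigError,
    classify_by_kinematics,
    ground_truth_detector,
    make_dataset,
    render_scene,
)


class TestRenderScene:
    def test_empty_scene(self):
        frames, truth = render_scene(SceneConfig(n_frames=4, fish=(), seed=0))
        assert frames.shape[0] == 4
        assert all(len(e) == 0 for e in truth.per_frame)

    def test_same_seed_bit_identical(self):
        cfg = SceneConfig(n_frames=8, fish=(FishSpec("normal"),), seed=9)
        f1, t1 = render_scene(cfg)
        f2, t2 = render_scene(cfg)
        np.testing.assert_array_equal(f1, f2)
        assert t1 == t2

    def test_different_seeds_differ(self):
        f1, _ = render_scene(SceneConfig(n_frames=4, fish=(FishSpec("normal"),), seed=1))
        f2, _ = render_scene(SceneConfig(n_frames=4, fish=(FishSpec("normal"),), seed=2))
        assert not np.array_equal(f1, f2)

    def test_boxes_inside_frame(self):
        cfg = SceneConfig(
            n_frames=30,
            fish=tuple(FishSpec(b) for b in BEHAVIORS),
            seed=4,
        )
        _, truth = render_scene(cfg)
        w, h = cfg.frame_size
        for entries in truth.per_frame:
            for e in entries:
                assert 0 <= e.box.x and e.box.x + e.box.w <= w
                assert 0 <= e.box.y and e.box.y + e.box.h <= h

    def test_oversized_sprite_rejected(self):
        with pytest.raises(SceneConfigError, match="does not fit"):
            SceneConfig(frame_size=(60, 60), fish=(FishSpec("normal", size=50),))

    def test_frames_in_unit_range(self):
        frames, _ = render_scene(
            SceneConfig(n_frames=5, fish=(FishSpec("normal"),), seed=3)
        )
        assert frames.min() >= 0.0 and frames.max() <= 1.0


@pytest.fixture(scope="module")
def tracks():
    out = {}
    for b in BEHAVIORS:
        cfg = SceneConfig(n_frames=45, fish=(FishSpec(b),), seed=17)
        _, truth = render_scene(cfg)
        out[b] = (cfg, truth.track(0))
    return out


@pytest.fixture(scope="module")
def truth():
    cfg = SceneConfig(
        n_frames=60,
        fish=tuple(FishSpec("normal") for _ in range(3)),
        seed=8,
    )
    return render_scene(cfg)[1]


class TestBehaviorKinematics:
    def test_lifeless_never_moves(self, tracks):
        _, tr = tracks["lifeless"]
        boxes = {(e.box.x, e.box.y, e.box.w, e.box.h) for e in tr}
        assert len(boxes) == 1

    def test_grinding_stays_in_bottom_strip(self, tracks):
        cfg, tr = tracks["grinding"]
        h = cfg.frame_size[1]
        for e in tr:
            assert e.box.y + e.box.h >= (1 - BOTTOM_STRIP) * h

    def test_grinding_oscillates_but_stays_put(self, tracks):
        _, tr = tracks["grinding"]
        xs = [e.box.center[0] for e in tr]
        assert max(xs) - min(xs) > 2.0          # visible rubbing motion
        assert max(xs) - min(xs) < 40.0         # ... confined to one spot

    def test_cartwheeling_full_turn_per_40_frames(self, tracks):
        _, tr = tracks["cartwheeling"]
        ors = [e.orientation for e in tr[:41]]
        assert max(ors) - min(ors) >= 2 * np.pi

    def test_normal_translates_far(self, tracks):
        _, tr = tracks["normal"]
        cs = [e.box.center for e in tr]
        total = sum(
            abs(a[0] - b[0]) + abs(a[1] - b[1]) for a, b in zip(cs, cs[1:])
        )
        assert total > 50.0

    def test_behavior_switch_changes_truth_label(self):
        cfg = SceneConfig(
            n_frames=30,
            fish=(FishSpec("normal", behavior_switch=(15, "lifeless")),),
            seed=6,
        )
        _, truth = render_scene(cfg)
        labels = [truth.per_frame[t][0].behavior for t in range(30)]
        assert labels[:15] == ["normal"] * 15
        assert labels[15:] == ["lifeless"] * 15


class TestKinematicSeparability:
    def test_hand_coded_summaries_classify_perfectly(self):
        """Path length, orientation span, bottom occupancy and body aspect
        separate the five behaviors on default scenes — the learning task
        is solvable, so classifier failures are model/training bugs."""
        k = 10
        total = correct = 0
        for ci, behavior in enumerate(BEHAVIORS):
            for si in range(30):
                cfg = SceneConfig(
                    n_frames=k + (si % 20),
                    fish=(FishSpec(behavior),),
                    seed=9000 + 100 * ci + si,
                )
                _, truth = render_scene(cfg)
                window = truth.track(0)[-k:]
                pred = classify_by_kinematics(window, cfg.frame_size[1])
                total += 1
                correct += pred == behavior
        assert correct == total

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            classify_by_kinematics([])


class TestGroundTruthDetector:
    def test_no_degradation_is_identity(self, truth):
        dets = ground_truth_detector(truth, dropout_rate=0.0, jitter_std=0.0)
        for t, entries in enumerate(truth.per_frame):
            assert dets[t] == [e.box for e in entries]

    def test_full_dropout_no_detections(self, truth):
        dets = ground_truth_detector(truth, dropout_rate=1.0)
        assert all(d == [] for d in dets)

    def test_dropout_rate_within_binomial_bounds(self, truth):
        n = sum(len(e) for e in truth.per_frame)
        kept = sum(
            len(d) for d in ground_truth_detector(truth, dropout_rate=0.2, seed=3)
        )
        sd = np.sqrt(n * 0.2 * 0.8)
        assert abs(kept - 0.8 * n) <= 3 * sd

    def test_deterministic_under_seed(self, truth):
        d1 = ground_truth_detector(truth, 0.3, 1.0, seed=11)
        d2 = ground_truth_detector(truth, 0.3, 1.0, seed=11)
        assert d1 == d2


class TestMakeDataset:
    def test_bookkeeping(self, tiny_dataset):
        seqs, counts = tiny_dataset
        assert counts == {b: 4 for b in BEHAVIORS}
        assert len(seqs) == 20
        assert all(s.k == 10 for s in seqs)

    def test_imbalanced_counts_feed_class_weights(self):
        _, counts = make_dataset(
            SceneConfig(seed=2),
            sequences_per_class={"normal": 9, "lifeless": 1},
        )
        w = class_weights([counts["normal"], counts["lifeless"]])
        np.testing.assert_allclose(w, [0.1, 0.9])

    def test_clips_zero_outside_roi(self, tiny_dataset):
        seqs, _ = tiny_dataset
        cfg = SceneConfig(seed=5)
        w_f, h_f = cfg.frame_size
        for seq in seqs[:6]:
            for clip, box in zip(seq.clips, seq.boxes):
                sx, sy = 64 / w_f, 64 / h_f
                xs0 = max(int(np.floor(box.x * sx)) - 1, 0)
                ys0 = max(int(np.floor(box.y * sy)) - 1, 0)
                xs1 = int(np.ceil((box.x + box.w) * sx)) + 1
                ys1 = int(np.ceil((box.y + box.h) * sy)) + 1
                mask = np.zeros((64, 64), bool)
                mask[ys0:ys1, xs0:xs1] = True
                outside = clip.sum(axis=0)[~mask]
                assert outside.size == 0 or outside.max() == 0.0

    def test_deterministic_under_seed(self):
        s1, _ = make_dataset(SceneConfig(seed=7), sequences_per_class=2)
        s2, _ = make_dataset(SceneConfig(seed=7), sequences_per_class=2)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.clips, b.clips)
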