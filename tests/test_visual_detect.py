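"""Skin colour model, segment scoring, track linking/refinement, evaluation."""

import numpy as np
import pytest

from elemon.types import EvalReport
from elemon.video.detect import (
    ColorModel,
    Segment,
    Track,
    evaluate_visual,
    group_candidates,
    link_and_merge,
    refine_tracks,
    score_segments,
    train_skin_model,
)
from elemon.video.synth import MaskSequence


def _seg(frame, x, y, w, h, H=60, W=80, score=1.0):
    mask = np.zeros((H, W), dtype=bool)
    mask[y : y + h, x : x + w] = True
    return Segment(
        frame_index=frame,
        mask=mask,
        bbox=(x, y, w, h),
        area=int(mask.sum()),
        mean_color=np.zeros(3),
        skin_score=score,
    )


class TestSkinModel:
    def _clouds(self, seed=0, n=300):
        rng = np.random.default_rng(seed)
        fg = np.clip(rng.normal((120, 105, 100), 6, (n, 3)), 0, 255).astype(np.uint8)
        bg = np.clip(rng.normal((90, 140, 60), 6, (n, 3)), 0, 255).astype(np.uint8)
        return fg, bg

    def test_separable_clouds_train_accuracy_one(self):
        fg, bg = self._clouds()
        model = train_skin_model(fg, bg)
        assert np.all(model.decision_rgb(fg) > 0)
        assert np.all(model.decision_rgb(bg) < 0)

    def test_label_swap_negates_decision(self):
        fg, bg = self._clouds(seed=1)
        m1 = train_skin_model(fg, bg)
        m2 = train_skin_model(bg, fg)
        probe = np.vstack([fg[:20], bg[:20]])
        np.testing.assert_allclose(
            m1.decision_rgb(probe), -m2.decision_rgb(probe), atol=1e-4
        )

    def test_planted_plane_recovered_within_5_degrees(self):
        # classes split by a plane through Lab space along direction u
        rng = np.random.default_rng(2)
        u = np.array([1.0, 1.0, -1.0]) / np.sqrt(3)
        base = np.array([50.0, 5.0, 15.0])
        pts = base + rng.normal(0, 4.0, (800, 3))
        side = (pts - base) @ u
        fg_lab = pts[side > 1.0]
        bg_lab = pts[side < -1.0]
        model = ColorModel(
            weights=np.zeros(3), bias=0.0, feature_means=np.zeros(3), feature_scales=np.ones(3)
        )
        from skimage.color import lab2rgb

        fg = np.clip(lab2rgb(fg_lab) * 255, 0, 255).astype(np.uint8)
        bg = np.clip(lab2rgb(bg_lab) * 255, 0, 255).astype(np.uint8)
        fitted = train_skin_model(fg, bg)
        w_raw = fitted.weights / fitted.feature_scales
        cos = abs(w_raw @ u) / np.linalg.norm(w_raw)
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 5.0

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            train_skin_model(np.zeros((0, 3)), np.ones((5, 3)))


class TestScoreSegments:
    def test_mean_score_equals_brute_force(self):
        rng = np.random.default_rng(3)
        model = ColorModel(
            weights=rng.normal(0, 1, 3),
            bias=0.3,
            feature_means=rng.normal(0, 1, 3),
            feature_scales=np.abs(rng.normal(1, 0.2, 3)),
        )
        colors = rng.normal(50, 10, (40, 40, 3))
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:20, 10:30] = True
        seg = Segment(0, mask, (10, 5, 20, 15), int(mask.sum()), colors[mask].mean(axis=0))
        score_segments([seg], model)
        brute = float(model.decision(colors[mask]).mean())
        assert seg.skin_score == pytest.approx(brute, abs=1e-6)

    def test_candidates_are_positive_scores_only(self):
        model = ColorModel(
            weights=np.array([1.0, 0, 0]),
            bias=0.0,
            feature_means=np.zeros(3),
            feature_scales=np.ones(3),
        )
        hot = _seg(0, 0, 0, 5, 5)
        hot.mean_color = np.array([5.0, 0, 0])
        cold = _seg(0, 10, 10, 5, 5)
        cold.mean_color = np.array([-5.0, 0, 0])
        out = score_segments([hot, cold], model)
        assert out == [hot]
        assert cold.skin_score < 0


class TestGrouping:
    def test_adjacent_fragments_form_one_group(self):
        a = _seg(0, 10, 10, 10, 10)
        b = _seg(0, 22, 10, 10, 10)  # 2 px gap
        c = _seg(0, 60, 40, 8, 8)  # far away
        groups = group_candidates([a, b, c], group_gap=12.0)
        sizes = sorted(len(g) for g in groups)
        assert sizes == [1, 2]


class TestLinkAndMerge:
    def test_static_candidate_single_track(self):
        cands = {f: [_seg(f, 20, 20, 10, 10)] for f in range(8)}
        tracks = link_and_merge(cands)
        assert len(tracks) == 1
        assert tracks[0].length == 8

    def test_distant_candidates_two_tracks(self):
        cands = {
            f: [_seg(f, 2, 2, 6, 6), _seg(f, 60, 50, 6, 6)] for f in range(5)
        }
        tracks = link_and_merge(cands, max_centroid_dist=10.0, group_gap=5.0)
        assert len(tracks) == 2

    def test_half_blobs_merge_into_one_member_set(self):
        # frame 0: whole blob; frame 1: two halves both overlapping its bbox
        cands = {
            0: [_seg(0, 20, 20, 20, 10)],
            1: [_seg(1, 20, 20, 9, 10), _seg(1, 31, 20, 9, 10)],
        }
        tracks = link_and_merge(cands, group_gap=1.0)
        assert len(tracks) == 1
        assert len(tracks[0].members[1]) == 2

    def test_gap_tolerance(self):
        cands = {0: [_seg(0, 20, 20, 10, 10)], 3: [_seg(3, 21, 20, 10, 10)]}
        assert len(link_and_merge(cands, max_frame_gap=2)) == 2
        cands2 = {0: [_seg(0, 20, 20, 10, 10)], 2: [_seg(2, 21, 20, 10, 10)]}
        assert len(link_and_merge(cands2, max_frame_gap=2)) == 1


class TestRefineTracks:
    def _track(self, n_frames, step=0.0):
        t = Track(0)
        for f in range(n_frames):
            t.add(_seg(f, int(10 + f * step), 20, 10, 10))
        return t

    def test_short_track_discarded(self):
        assert refine_tracks([self._track(4)], min_length=5) == []

    def test_long_smooth_track_kept(self):
        t = self._track(8, step=1.0)
        assert refine_tracks([t], min_length=5, max_step=5.0) == [t]

    def test_jumping_track_discarded(self):
        t = Track(0)
        for f, x in enumerate([10, 11, 12, 50, 51, 52]):
            t.add(_seg(f, x, 20, 10, 10))
        assert refine_tracks([t], min_length=5, max_step=10.0) == []

    def test_empty_input(self):
        assert refine_tracks([], min_length=5) == []

    def test_min_length_monotonicity(self):
        tracks = [self._track(n) for n in (3, 5, 8, 12)]
        counts = [
            len(refine_tracks(tracks, min_length=k, max_step=99)) for k in (1, 4, 6, 10, 20)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestEvaluateVisual:
    def _mask_seq(self, n_frames=3, H=60, W=80):
        m = np.zeros((n_frames, H, W), dtype=np.uint8)
        m[:, 10:20, 10:30] = 1
        m[:, 40:50, 50:70] = 2
        return MaskSequence(m)

    def test_tracks_equal_masks_perfect(self):
        masks = self._mask_seq()
        t1, t2 = Track(0), Track(1)
        for f in range(3):
            t1.add(_seg(f, 10, 10, 20, 10))
            t2.add(_seg(f, 50, 40, 20, 10))
        rep = evaluate_visual([t1, t2], masks)
        assert rep.detection_rate == 1.0
        assert rep.false_positive_rate == 0.0

    def test_no_tracks_zero_conventions(self):
        rep = evaluate_visual([], self._mask_seq())
        assert rep.detection_rate == 0.0
        assert rep.false_positive_rate == 0.0

    def test_hand_enumerated_counts(self):
        """2 objects x 3 frames; one spurious off-mask track-frame."""
        masks = self._mask_seq()
        t1 = Track(0)
        for f in range(3):
            t1.add(_seg(f, 10, 10, 20, 10))  # covers object 1 fully
        spurious = Track(1)
        spurious.add(_seg(0, 0, 50, 6, 6))  # off every mask
        rep = evaluate_visual([t1, spurious], masks)
        # object 1 detected in 3 frames; object 2 never; 6 object-frames total
        assert rep.n_truth == 6
        assert rep.n_matched == 3
        assert rep.detection_rate == pytest.approx(0.5)
        # 4 track-frames, 1 false
        assert rep.n_detections == 4
        assert rep.false_positive_rate == pytest.approx(0.25)

    def test_cover_threshold_boundary(self):
        masks = self._mask_seq(n_frames=1)
        t = Track(0)
        t.add(_seg(0, 10, 10, 10, 10))  # covers exactly half of object 1
        rep = evaluate_visual([t], masks, cover_thresh=0.5)
        assert rep.n_matched == 1
        rep2 = evaluate_visual([t], masks, cover_thresh=0.6)
        assert rep2.n_matched == 0
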