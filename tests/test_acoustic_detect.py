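"""Training split, linear classifier geometry, sliding detection post-processing."""

import numpy as np
import pytest

from elemon.audio.detect import (
    DetectorModel,
    FrontEndConfig,
    detect_events,
    extract_context_features,
    make_training_split,
    merge_positive_windows,
    train_acoustic_model,
    with_threshold,
)
from elemon.audio.gfcc import ContextFeature
from elemon.types import AudioClip, EventAnnotation


def _anns(n):
    return [EventAnnotation(10 * i, 10 * i + 2, "rumble") for i in range(n)]


class TestTrainingSplit:
    def test_ten_percent_of_633_is_63(self):
        split = make_training_split(_anns(633), negatives=0, frac=0.10, seed=0)
        assert len(split.train_ids) == 63
        assert len(split.test_ids) == 570

    def test_floor_rule_small(self):
        split = make_training_split(_anns(10), negatives=0, frac=0.10, seed=1)
        assert len(split.train_ids) == 1
        assert len(split.test_ids) == 9

    def test_half_of_four_and_determinism(self):
        a = make_training_split(_anns(4), negatives=0, frac=0.5, seed=3)
        b = make_training_split(_anns(4), negatives=0, frac=0.5, seed=3)
        assert len(a.train_ids) == 2
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids

    def test_disjoint_and_complete(self):
        split = make_training_split(_anns(20), negatives=0, frac=0.3, seed=5)
        assert set(split.train_ids) | set(split.test_ids) == set(range(20))
        assert set(split.train_ids) & set(split.test_ids) == set()

    def test_negative_spans_avoid_annotations(self):
        anns = _anns(5)
        split = make_training_split(
            anns, negatives=10, frac=0.2, seed=2, total_duration=100.0
        )
        assert len(split.negative_spans) == 10
        for s, e in split.negative_spans:
            for a in anns:
                assert min(e, a.end) - max(s, a.start) <= 0

    def test_zero_positive_fraction_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            make_training_split(_anns(5), negatives=0, frac=0.1, seed=0)


def _cf(vec):
    return ContextFeature(np.asarray(vec, dtype=float), (0.0, 1.0))


class TestTrainAcousticModel:
    def test_separable_classes_train_accuracy_one(self):
        rng = np.random.default_rng(0)
        pos = [_cf(rng.normal([5, 5], 0.3)) for _ in range(30)]
        neg = [_cf(rng.normal([-5, -5], 0.3)) for _ in range(30)]
        model = train_acoustic_model(pos, neg)
        assert np.all(model.decision(np.vstack([f.vector for f in pos])) > 0)
        assert np.all(model.decision(np.vstack([f.vector for f in neg])) < 0)

    def test_symmetric_point_classes_recover_normal(self):
        rng = np.random.default_rng(1)
        # equal component magnitudes keep per-dimension standardisation
        # isotropic, so the raw-space normal is comparable to u
        u = np.array([1.0, -1.0, 1.0, 1.0]) / 2.0
        pos = [_cf(u * 2 + rng.normal(0, 0.05, 4)) for _ in range(50)]
        neg = [_cf(-u * 2 + rng.normal(0, 0.05, 4)) for _ in range(50)]
        model = train_acoustic_model(pos, neg)
        # undo the standardisation to compare directions in raw feature space
        w_raw = model.weights / model.feature_scales
        cos = abs(w_raw @ u) / np.linalg.norm(w_raw)
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 5.0

    def test_duplication_leaves_decision_unchanged(self):
        rng = np.random.default_rng(2)
        pos = [_cf(rng.normal([2, 1], 0.5)) for _ in range(15)]
        neg = [_cf(rng.normal([-2, -1], 0.5)) for _ in range(20)]
        m1 = train_acoustic_model(pos, neg)
        m2 = train_acoustic_model(pos + pos, neg + neg)
        probe = rng.normal(0, 2, (40, 2))
        np.testing.assert_allclose(m1.decision(probe), m2.decision(probe), atol=1e-4)

    def test_zero_variance_dimension_gets_unit_scale(self):
        pos = [_cf([1.0, 7.0]) for _ in range(5)]
        neg = [_cf([-1.0, 7.0]) for _ in range(5)]
        model = train_acoustic_model(pos, neg)
        assert model.feature_scales[1] == 1.0

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            train_acoustic_model([], [_cf([0, 0])])


class TestMergeWindows:
    def test_three_windows_merge_into_one_event(self):
        spans = [(3.0, 4.2), (3.5, 4.7), (3.9, 4.2)]
        (ev,) = merge_positive_windows(spans, np.array([0.5, 0.9, 0.2]), 0.3, 0.5)
        assert (ev.start, ev.end) == (3.0, 4.7)
        assert ev.score == pytest.approx(0.9)

    def test_gap_beyond_max_gap_splits(self):
        spans = [(1.0, 2.0), (3.0, 4.0)]
        events = merge_positive_windows(spans, np.array([0.1, 0.2]), 0.3, 0.5)
        assert len(events) == 2

    def test_short_event_discarded(self):
        spans = [(1.0, 1.3)]
        assert merge_positive_windows(spans, np.array([1.0]), 0.3, 0.5) == []

    def test_single_long_window_retained(self):
        spans = [(1.0, 2.2)]
        (ev,) = merge_positive_windows(spans, np.array([1.0]), 0.3, 0.5)
        assert ev.duration == pytest.approx(1.2)


class TestDetectEvents:
    @pytest.fixture(scope="class")
    def cfg(self):
        return FrontEndConfig(enhance=False)

    def _negative_model(self, dim):
        return DetectorModel(
            weights=np.zeros(dim),
            bias=-1.0,
            feature_means=np.zeros(dim),
            feature_scales=np.ones(dim),
        )

    def test_all_negative_scores_give_empty_list(self, cfg):
        clip = AudioClip(np.zeros(40000), 4000)
        model = self._negative_model(cfg.feature_dim)
        assert detect_events(clip, model, cfg) == []

    def test_clip_shorter_than_context_span_empty(self, cfg):
        clip = AudioClip(np.zeros(2000), 4000)  # 0.5 s < one context window
        model = self._negative_model(cfg.feature_dim)
        assert detect_events(clip, model, cfg) == []

    def test_threshold_monotonicity(self, cfg, wind_rumble_scene):
        feats = extract_context_features(wind_rumble_scene.clip, cfg)
        rng = np.random.default_rng(0)
        model = DetectorModel(
            weights=rng.normal(0, 1, cfg.feature_dim),
            bias=0.0,
            feature_means=np.zeros(cfg.feature_dim),
            feature_scales=np.ones(cfg.feature_dim),
        )
        counts = []
        for thr in [-2.0, -1.0, 0.0, 1.0, 2.0]:
            n = len(detect_events(wind_rumble_scene.clip, with_threshold(model, thr), cfg))
            counts.append(n)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_weakly_voiced_stretch_splits_without_hysteresis(self):
        # two strong windows around a weak stretch: seeds alone give two
        # events; the low-threshold run containing both seeds gives one
        spans = [(float(i), float(i) + 1.2) for i in range(6)]
        scores = np.array([1.0, 0.2, 0.2, 0.2, 1.0, -5.0])
        strong = [s for s, sc in zip(spans, scores) if sc > 0.5]
        assert len(merge_positive_windows(strong, scores[scores > 0.5], 0.3, 0.5)) == 2
        bridged = [s for s, sc in zip(spans, scores) if sc > 0.1]
        assert len(merge_positive_windows(bridged, scores[scores > 0.1], 0.3, 0.5)) == 1
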