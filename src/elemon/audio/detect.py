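"""Linear rumble detector: training split, SVM training, sliding detection.

The decision rule is a linear max-margin classifier over context features
(mean||variance of GFCC frames).  Sliding the rule over a recording yields
per-window scores; consecutive positive windows are merged into events, and
events that are too short are discarded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from ..types import AudioClip, DetectionEvent, EventAnnotation
from .gfcc import ContextFeature, aggregate_context, build_filterbank, gfcc_frames, greenwood_from_range
from .spectral import EnhanceParams, enhance_spectrogram, stft_spectrogram


@dataclass(frozen=True)
class FrontEndConfig:
    """Everything needed to turn a waveform into context features."""

    frame_len: float = 0.3
    hop: float = 0.1
    enhance: bool = True
    enhance_params: EnhanceParams = field(default_factory=EnhanceParams)
    fmin: float = 8.0
    fmax: float = 2000.0
    greenwood_k: float = 0.88
    n_filters: int = 26
    n_ceps: int = 12
    drop_c0: bool = True
    context_window: int = 10
    context_hop: int = 5

    @property
    def feature_dim(self) -> int:
        return 2 * self.n_ceps


def extract_context_features(clip: AudioClip, cfg: FrontEndConfig) -> list[ContextFeature]:
    """Full front end: spectrogram -> (optional) enhancement -> GFCC -> context."""
    spec = stft_spectrogram(clip, cfg.frame_len, cfg.hop)
    if cfg.enhance:
        spec = enhance_spectrogram(spec, cfg.enhance_params)
    n_frame = int(round(cfg.frame_len * clip.rate))
    gmap = greenwood_from_range(cfg.fmin, min(cfg.fmax, clip.rate / 2), cfg.greenwood_k)
    fb = build_filterbank(
        gmap, cfg.n_filters, cfg.fmin, min(cfg.fmax, clip.rate / 2), clip.rate, n_frame
    )
    feats = gfcc_frames(spec, fb, cfg.n_ceps, cfg.drop_c0)
    if feats.vectors.shape[0] < cfg.context_window:
        return []
    return aggregate_context(feats, cfg.context_window, cfg.context_hop)


@dataclass
class DetectorModel:
    """Trained linear decision rule with its standardisation."""

    weights: np.ndarray
    bias: float
    feature_means: np.ndarray
    feature_scales: np.ndarray
    threshold: float = 0.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.feature_means = np.asarray(self.feature_means, dtype=np.float64)
        self.feature_scales = np.asarray(self.feature_scales, dtype=np.float64)
        if np.any(self.feature_scales <= 0):
            raise ValueError("feature scales must be strictly positive")

    def decision(self, vectors: np.ndarray) -> np.ndarray:
        z = (np.atleast_2d(vectors) - self.feature_means) / self.feature_scales
        return z @ self.weights + self.bias

    def to_json(self, path: str | Path, extra: dict | None = None) -> None:
        doc = {
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "feature_means": self.feature_means.tolist(),
            "feature_scales": self.feature_scales.tolist(),
            "threshold": self.threshold,
        }
        if extra:
            doc.update(extra)
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DetectorModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            weights=np.array(doc["weights"]),
            bias=float(doc["bias"]),
            feature_means=np.array(doc["feature_means"]),
            feature_scales=np.array(doc["feature_scales"]),
            threshold=float(doc.get("threshold", 0.0)),
        )


@dataclass(frozen=True)
class TrainingSplit:
    """Indices of annotations kept for training vs held out for testing."""

    train_ids: tuple[int, ...]
    test_ids: tuple[int, ...]
    negative_spans: tuple[tuple[float, float], ...] = ()


def make_training_split(
    annotations: list[EventAnnotation],
    negatives: int,
    frac: float,
    seed: int,
    total_duration: float | None = None,
    negative_span: float = 2.0,
) -> TrainingSplit:
    """Sample floor(frac * n) annotations for training, uniformly without replacement.

    With ``total_duration`` given, ``negatives`` annotation-free spans of
    ``negative_span`` seconds are also drawn (rejection sampling against the
    annotated intervals).
    """
    if not 0 < frac < 1:
        raise ValueError(f"frac must lie in (0, 1), got {frac}")
    n = len(annotations)
    n_train = int(np.floor(frac * n))
    if n_train == 0:
        raise ValueError(f"frac {frac} of {n} annotations yields zero training positives")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = tuple(sorted(int(i) for i in perm[:n_train]))
    test = tuple(sorted(int(i) for i in perm[n_train:]))
    spans: list[tuple[float, float]] = []
    if total_duration is not None and negatives > 0:
        tries = 0
        while len(spans) < negatives and tries < 10000 * negatives:
            tries += 1
            s = rng.uniform(0, max(total_duration - negative_span, 0))
            e = s + negative_span
            if all(min(e, a.end) - max(s, a.start) <= 0 for a in annotations):
                spans.append((s, e))
    return TrainingSplit(train, test, tuple(spans))


def train_acoustic_model(
    positives: list[ContextFeature],
    negatives: list[ContextFeature],
    C: float = 1.0,
) -> DetectorModel:
    """Fit the standardised linear max-margin classifier.

    Per-sample weights are 1/(2 * class size), so classes contribute equally
    regardless of imbalance and duplicating the training set leaves the
    decision function unchanged.
    """
    if not positives or not negatives:
        raise ValueError("both positive and negative training sets must be non-empty")
    X = np.vstack([f.vector for f in positives] + [f.vector for f in negatives])
    y = np.concatenate([np.ones(len(positives)), -np.ones(len(negatives))])
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales[scales == 0] = 1.0  # zero-variance dimensions: leave unscaled
    Z = (X - means) / scales
    w = np.where(y > 0, 1.0 / (2 * len(positives)), 1.0 / (2 * len(negatives)))
    svc = SVC(kernel="linear", C=C, tol=1e-8)
    svc.fit(Z, y, sample_weight=w)
    return DetectorModel(
        weights=svc.coef_.ravel(),
        bias=float(svc.intercept_[0]),
        feature_means=means,
        feature_scales=scales,
    )


def merge_positive_windows(
    spans: list[tuple[float, float]],
    scores: np.ndarray,
    max_gap: float,
    min_duration: float,
) -> list[DetectionEvent]:
    """Merge overlapping/nearby positive window spans into events."""
    events: list[DetectionEvent] = []
    cur: list[int] = []
    for i, (s, e) in enumerate(spans):
        if cur and s - spans[cur[-1]][1] > max_gap:
            start, end = spans[cur[0]][0], max(spans[j][1] for j in cur)
            events.append(DetectionEvent(start, end, float(np.max(scores[cur]))))
            cur = []
        cur.append(i)
    if cur:
        start, end = spans[cur[0]][0], max(spans[j][1] for j in cur)
        events.append(DetectionEvent(start, end, float(np.max(scores[cur]))))
    return [ev for ev in events if ev.duration >= min_duration]


def detect_events(
    clip: AudioClip,
    model: DetectorModel,
    cfg: FrontEndConfig,
    max_gap: float = 0.3,
    min_duration: float = 0.5,
    hysteresis: float = 0.0,
    edge_margin: float = 0.0,
) -> list[DetectionEvent]:
    """Slide the detector over a clip and post-process decisions into events.

    Windows scoring above ``model.threshold`` seed events.  With a positive
    ``hysteresis``, windows above ``threshold - hysteresis`` extend or bridge
    seeded events (one weakly voiced stretch stays one event instead of
    shattering into several).  ``edge_margin`` excludes windows that start
    within that many seconds of either clip edge, where the enhancement's
    background estimate rests on boundary padding.
    """
    feats = extract_context_features(clip, cfg)
    if not feats:
        return []  # clip shorter than one context span
    X = np.vstack([f.vector for f in feats])
    scores = model.decision(X)
    if edge_margin > 0:
        t_end = float(feats[-1].span[1])
        keep = np.array(
            [edge_margin <= f.span[0] and f.span[1] <= t_end - edge_margin for f in feats]
        )
        scores = np.where(keep, scores, -np.inf)
    seed = scores > model.threshold
    if not seed.any():
        return []
    if hysteresis > 0:
        low = scores > model.threshold - hysteresis
        # keep low-threshold runs that contain at least one seed window
        accept = np.zeros_like(seed)
        i = 0
        n = len(low)
        while i < n:
            if low[i]:
                j = i
                while j < n and low[j]:
                    j += 1
                if seed[i:j].any():
                    accept[i:j] = True
                i = j
            else:
                i += 1
    else:
        accept = seed
    spans = [feats[i].span for i in np.flatnonzero(accept)]
    return merge_positive_windows(spans, scores[accept], max_gap, min_duration)


def with_threshold(model: DetectorModel, threshold: float) -> DetectorModel:
    return replace(model, threshold=threshold)
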