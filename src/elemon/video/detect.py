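"""Visual elephant detection: colour model, segments, tracks, evaluation.

Pipeline per sequence: each frame is over-segmented with joint spatial-range
mean-shift in CIELAB; a linear skin-colour classifier (chromaticity features
by default, for invariance to illumination gain and shading) scores every
segment by its mean decision value; positively scored segments become
candidate detections; candidates are associated across frames by
bounding-box overlap (falling back to centroid distance), several same-frame
candidates joining one track — this repairs the deliberate
over-segmentation; finally, tracks that are short or jump abruptly are
discarded.  Evaluation is per object-frame against visible-pixel masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2lab
from sklearn.svm import SVC

from ..types import EvalReport
from .meanshift import mean_shift_segment
from .synth import MaskSequence


@dataclass
class ColorModel:
    """Linear skin/background decision rule over pixel colours.

    ``space`` selects the feature space: "lab" (CIELAB, D65) or "rgbn"
    (normalised RGB / chromaticity, invariant to illumination gain).
    """

    weights: np.ndarray  # (3,)
    bias: float
    feature_means: np.ndarray
    feature_scales: np.ndarray
    space: str = "lab"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if np.any(self.feature_scales <= 0):
            raise ValueError("feature scales must be strictly positive")

    def to_space(self, rgb: np.ndarray) -> np.ndarray:
        """uint8 sRGB (..., 3) -> model colour space."""
        arr = np.asarray(rgb, dtype=np.float64) / 255.0
        if self.space == "lab":
            return rgb2lab(arr)
        if self.space == "rgbn":  # normalised RGB
            s = arr.sum(axis=-1, keepdims=True) + 1e-12
            return arr / s
        raise ValueError(f"unknown colour space {self.space!r}")

    def decision(self, colors_in_space: np.ndarray) -> np.ndarray:
        z = (colors_in_space - self.feature_means) / self.feature_scales
        return z @ self.weights + self.bias

    def decision_rgb(self, rgb: np.ndarray) -> np.ndarray:
        return self.decision(self.to_space(rgb))


def train_skin_model(
    fg: np.ndarray,
    bg: np.ndarray,
    C: float = 1.0,
    space: str = "lab",
) -> ColorModel:
    """Fit the linear max-margin skin/background boundary; decision > 0 <=> skin."""
    if len(fg) == 0 or len(bg) == 0:
        raise ValueError("both colour classes must be non-empty")
    model = ColorModel(
        weights=np.zeros(3), bias=0.0, feature_means=np.zeros(3), feature_scales=np.ones(3), space=space
    )
    X = np.vstack([model.to_space(np.asarray(fg)), model.to_space(np.asarray(bg))])
    y = np.concatenate([np.ones(len(fg)), -np.ones(len(bg))])
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales[scales == 0] = 1.0
    Z = (X - means) / scales
    w = np.where(y > 0, 1.0 / (2 * len(fg)), 1.0 / (2 * len(bg)))
    svc = SVC(kernel="linear", C=C, tol=1e-8)
    svc.fit(Z, y, sample_weight=w)
    return ColorModel(
        weights=svc.coef_.ravel(),
        bias=float(svc.intercept_[0]),
        feature_means=means,
        feature_scales=scales,
        space=space,
    )


@dataclass
class Segment:
    """One region of the frame partition."""

    frame_index: int
    mask: np.ndarray  # (H, W) bool
    bbox: tuple[int, int, int, int]  # x, y, w, h
    area: int
    mean_color: np.ndarray  # in the scoring colour space
    skin_score: float = 0.0

    @property
    def centroid(self) -> tuple[float, float]:
        x, y, w, h = self.bbox
        ys, xs = np.nonzero(self.mask)
        return float(xs.mean()), float(ys.mean())


def _segments_from_labels(
    labels: np.ndarray, frame_index: int, colors_in_space: np.ndarray
) -> list[Segment]:
    segs: list[Segment] = []
    flat = labels.ravel()
    n = int(labels.max()) + 1
    counts = np.bincount(flat, minlength=n)
    sums = np.column_stack(
        [
            np.bincount(flat, weights=colors_in_space[..., k].ravel(), minlength=n)
            for k in range(colors_in_space.shape[-1])
        ]
    )
    for lab in range(n):
        mask = labels == lab
        ys, xs = np.nonzero(mask)
        bbox = (int(xs.min()), int(ys.min()), int(xs.max() - xs.min() + 1), int(ys.max() - ys.min() + 1))
        segs.append(
            Segment(
                frame_index=frame_index,
                mask=mask,
                bbox=bbox,
                area=int(counts[lab]),
                mean_color=sums[lab] / counts[lab],
            )
        )
    return segs


def segment_frame(
    frame: np.ndarray,
    hs: float = 8.0,
    hr: float = 8.0,
    min_region: int = 20,
    max_iter: int = 50,
    tol: float = 0.1,
    model: ColorModel | None = None,
    frame_index: int = 0,
) -> list[Segment]:
    """Mean-shift over-segmentation of one uint8 sRGB frame into a partition.

    Segmentation always runs in CIELAB, where the range bandwidth is
    approximately perceptual.  Segment mean colours are recorded in the
    scoring model's colour space (possibly different, e.g. normalised RGB),
    so that the mean segment score equals the mean of per-pixel scores.
    """
    lab = rgb2lab(np.asarray(frame, dtype=np.float64) / 255.0)
    labels = mean_shift_segment(lab, hs, hr, min_region, max_iter=max_iter, tol=tol)
    score_cols = model.to_space(frame) if model is not None else lab
    return _segments_from_labels(labels, frame_index, score_cols)


def score_segments(
    segments: list[Segment],
    model: ColorModel,
    frame: np.ndarray | None = None,
) -> list[Segment]:
    """Attach mean per-pixel skin scores; return the positive candidates.

    The decision rule is linear, so the mean per-pixel decision equals the
    decision of the mean colour; segments carry their mean colour already.
    """
    candidates = []
    for seg in segments:
        seg.skin_score = float(model.decision(seg.mean_color[None, :])[0])
        if seg.skin_score > 0:
            candidates.append(seg)
    return candidates


@dataclass
class Track:
    """Temporally linked candidate detections."""

    id: int
    members: dict[int, list[Segment]] = field(default_factory=dict)  # frame -> segments

    def add(self, seg: Segment) -> None:
        self.members.setdefault(seg.frame_index, []).append(seg)

    @property
    def frames(self) -> list[int]:
        return sorted(self.members)

    @property
    def length(self) -> int:
        return len(self.members)

    def bbox_at(self, frame: int) -> tuple[float, float, float, float]:
        segs = self.members[frame]
        x0 = min(s.bbox[0] for s in segs)
        y0 = min(s.bbox[1] for s in segs)
        x1 = max(s.bbox[0] + s.bbox[2] for s in segs)
        y1 = max(s.bbox[1] + s.bbox[3] for s in segs)
        return (x0, y0, x1 - x0, y1 - y0)

    def centroid_at(self, frame: int) -> tuple[float, float]:
        segs = self.members[frame]
        tot = sum(s.area for s in segs)
        cx = sum(s.centroid[0] * s.area for s in segs) / tot
        cy = sum(s.centroid[1] * s.area for s in segs) / tot
        return cx, cy

    def pixels_at(self, frame: int) -> np.ndarray:
        segs = self.members[frame]
        out = segs[0].mask.copy()
        for s in segs[1:]:
            out |= s.mask
        return out

    def max_centroid_step(self) -> float:
        frs = self.frames
        if len(frs) < 2:
            return 0.0
        cents = [self.centroid_at(f) for f in frs]
        steps = [
            np.hypot(b[0] - a[0], b[1] - a[1]) / max(1, fb - fa)
            for (a, b), (fa, fb) in zip(zip(cents[:-1], cents[1:]), zip(frs[:-1], frs[1:]))
        ]
        return float(max(steps))

    @property
    def total_displacement(self) -> float:
        frs = self.frames
        a = self.centroid_at(frs[0])
        b = self.centroid_at(frs[-1])
        return float(np.hypot(b[0] - a[0], b[1] - a[1]))


def _bbox_overlap(a, b) -> float:
    """Intersection over the smaller box.

    A fragment of an over-segmented object lying inside the track's box
    scores 1 regardless of how small it is, which is what temporal
    over-segmentation repair needs; plain IoU would starve small fragments.
    """
    ax0, ay0, aw, ah = a
    bx0, by0, bw, bh = b
    ix = max(0.0, min(ax0 + aw, bx0 + bw) - max(ax0, bx0))
    iy = max(0.0, min(ay0 + ah, by0 + bh) - max(ay0, by0))
    inter = ix * iy
    smaller = min(aw * ah, bw * bh)
    return inter / smaller if smaller > 0 else 0.0


def _expanded_overlap(a, b, gap: float) -> bool:
    """True when bboxes ``a`` and ``b`` come within ``gap`` pixels of touching."""
    ax0, ay0, aw, ah = a
    bx0, by0, bw, bh = b
    return (
        ax0 - gap < bx0 + bw
        and bx0 - gap < ax0 + aw
        and ay0 - gap < by0 + bh
        and by0 - gap < ay0 + ah
    )


def group_candidates(candidates: list[Segment], group_gap: float = 12.0) -> list[list[Segment]]:
    """Spatially merge same-frame candidates into multi-segment detections.

    Over-segmentation splits one animal into many skin-positive fragments;
    fragments whose bounding boxes lie within ``group_gap`` pixels of each
    other (bridging thin occluders) are taken as one candidate detection.
    Connected components over that adjacency relation form the groups.
    """
    n = len(candidates)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _expanded_overlap(candidates[i].bbox, candidates[j].bbox, group_gap):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[Segment]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(candidates[i])
    return list(groups.values())


def link_and_merge(
    candidates_per_frame: dict[int, list[Segment]],
    max_centroid_dist: float = 40.0,
    min_bbox_overlap: float = 0.2,
    max_frame_gap: int = 2,
    group_gap: float = 12.0,
) -> list[Track]:
    """Greedy frame-to-frame association of candidate detections into tracks.

    Same-frame candidates are first spatially grouped (over-segmentation
    repair; see :func:`group_candidates`).  Each group is then matched to the
    active track with the highest bounding-box overlap (intersection over the
    smaller box, >= min_bbox_overlap), falling back to the nearest track
    centroid within max_centroid_dist.  Several same-frame groups may join
    one track; unmatched groups open new tracks; a track stays active across
    gaps of up to max_frame_gap frames.
    """
    tracks: list[Track] = []
    next_id = 0
    for frame in sorted(candidates_per_frame):
        active = [
            t for t in tracks if t.frames[-1] < frame and frame - t.frames[-1] <= max_frame_gap
        ]
        # association is always against the state of the previous frame
        refs = [(t, t.bbox_at(t.frames[-1]), t.centroid_at(t.frames[-1])) for t in active]
        unmatched: list[Segment] = []
        for seg in candidates_per_frame[frame]:
            cx, cy = seg.centroid
            best_t = None
            best_key = None
            for t, bbox, (tx, ty) in refs:
                ov = _bbox_overlap(seg.bbox, bbox)
                if ov < min_bbox_overlap:
                    continue
                # prefer higher overlap; break ties (e.g. a fragment inside
                # two overlapping track boxes) by nearer track centroid
                key = (ov, -float(np.hypot(cx - tx, cy - ty)))
                if best_key is None or key > best_key:
                    best_t, best_key = t, key
            if best_t is None:
                best_d = max_centroid_dist
                for t, _, (tx, ty) in refs:
                    d = float(np.hypot(cx - tx, cy - ty))
                    if d <= best_d:
                        best_t, best_d = t, d
            if best_t is not None:
                best_t.add(seg)
            else:
                unmatched.append(seg)
        # leftovers open new tracks, one per spatially coherent group
        for segs in group_candidates(unmatched, group_gap):
            t = Track(next_id)
            next_id += 1
            for seg in segs:
                t.add(seg)
            tracks.append(t)
    return tracks


def refine_tracks(
    tracks: list[Track],
    min_length: int = 5,
    max_step: float = 20.0,
) -> list[Track]:
    """Keep tracks that persist and move smoothly; drop the rest."""
    return [
        t
        for t in tracks
        if t.length >= min_length and t.max_centroid_step() <= max_step
    ]


def evaluate_visual(
    tracks: list[Track],
    masks: MaskSequence,
    cover_thresh: float = 0.5,
    fp_thresh: float = 0.1,
) -> EvalReport:
    """Object-frame scoring against visible-pixel ground truth.

    An (object, frame) pair counts as detected iff some final track's pixels
    in that frame cover at least ``cover_thresh`` of the object's visible
    mask.  A track-frame is false iff less than ``fp_thresh`` of its pixels
    lie on any object mask.
    """
    m = masks.masks
    n_frames = m.shape[0]
    object_ids = [int(v) for v in np.unique(m) if v != 0]

    track_pixels: dict[int, list[np.ndarray]] = {f: [] for f in range(n_frames)}
    for t in tracks:
        for f in t.frames:
            if 0 <= f < n_frames:
                track_pixels[f].append(t.pixels_at(f))

    n_truth = 0
    n_detected = 0
    for f in range(n_frames):
        for oid in object_ids:
            obj = m[f] == oid
            area = int(obj.sum())
            if area == 0:
                continue  # object fully occluded / absent in this frame
            n_truth += 1
            for px in track_pixels[f]:
                if int((px & obj).sum()) >= cover_thresh * area:
                    n_detected += 1
                    break

    n_track_frames = 0
    n_false = 0
    any_mask_per_frame = m > 0
    for t in tracks:
        for f in t.frames:
            if not 0 <= f < n_frames:
                continue
            n_track_frames += 1
            px = t.pixels_at(f)
            on = int((px & any_mask_per_frame[f]).sum())
            if on < fp_thresh * int(px.sum()):
                n_false += 1

    return EvalReport(
        n_truth=n_truth,
        n_detections=n_track_frames,
        n_matched=n_detected,
        n_matched_detections=n_track_frames - n_false,
    )
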