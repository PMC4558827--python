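"""Shared domain containers for the acoustic and visual pipelines."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class AudioClip:
    """A mono waveform with its sample rate.

    ``samples`` are float amplitudes in [-1, 1]; ``rate`` is in Hz.
    """

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        peak = float(np.max(np.abs(self.samples))) if self.samples.size else 0.0
        if peak > 1.0 + 1e-9:
            raise ValueError(f"sample amplitudes must lie in [-1, 1]; peak {peak:.4f}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass(frozen=True)
class EventAnnotation:
    """A labelled time interval: the start/end cues of one call (or noise event)."""

    start: float
    end: float
    label: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"annotation requires 0 <= start < end, got start={self.start}, end={self.end}"
            )
        if not self.label:
            raise ValueError("annotation label must be non-empty")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def overlap(self, other: "EventAnnotation | DetectionEvent") -> float:
        return max(0.0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class DetectionEvent:
    """A detected time interval with the peak decision score inside it."""

    start: float
    end: float
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"event requires start < end, got {self.start}, {self.end}")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class EvalReport:
    """Detection-rate / false-positive-rate bookkeeping shared by both pipelines.

    ``detection_rate`` is the fraction of ground-truth items matched by at
    least one detection; ``false_positive_rate`` is the fraction of emitted
    detections that match no ground truth.  Degenerate denominators follow the
    zero convention (0 truths => rate 0; 0 detections => FPR 0).
    """

    n_truth: int
    n_detections: int
    n_matched: int
    n_matched_detections: int | None = None
    detection_rate: float = field(init=False)
    false_positive_rate: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_matched_detections is None:
            # one-to-one matching: matched truths == matched detections
            object.__setattr__(self, "n_matched_detections", self.n_matched)
        if not 0 <= self.n_matched <= self.n_truth:
            raise ValueError("n_matched must lie in [0, n_truth]")
        if not 0 <= self.n_matched_detections <= self.n_detections:
            raise ValueError("n_matched_detections must lie in [0, n_detections]")
        dr = self.n_matched / self.n_truth if self.n_truth else 0.0
        fpr = (
            (self.n_detections - self.n_matched_detections) / self.n_detections
            if self.n_detections
            else 0.0
        )
        object.__setattr__(self, "detection_rate", dr)
        object.__setattr__(self, "false_positive_rate", fpr)
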