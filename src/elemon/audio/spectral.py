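"""Spectrogram computation and ridge-preserving noise reduction.

The noise reducer treats the dB spectrogram as an image: a 2-D median filter
estimates the local background level, and a logistic soft mask keeps only
cells that stand out from that background by more than a contrast threshold.
Well-localised spectro-temporal ridges (call contours, harmonic stacks)
survive; diffuse energy from wind and rain is attenuated.  The mask is
strictly below 1, so enhancement never adds energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter, uniform_filter1d
from scipy.signal.windows import hann
from scipy.special import expit

from ..types import AudioClip, EventAnnotation

DB_FLOOR = 80.0  # dB below the spectrogram max at which levels are floored


@dataclass
class Spectrogram:
    """Magnitude STFT on a regular time-frequency grid."""

    values: np.ndarray  # (n_frames, n_bins), non-negative magnitudes
    times: np.ndarray  # frame centres, s
    freqs: np.ndarray  # bin frequencies, Hz (0 .. rate/2)
    frame_len: float
    hop: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("spectrogram magnitudes must be non-negative")
        if self.values.shape != (self.times.size, self.freqs.size):
            raise ValueError("values must be (n_frames, n_bins)")

    @property
    def energy(self) -> float:
        return float(np.sum(self.values**2))


@dataclass(frozen=True)
class EnhanceParams:
    """Free parameters of the enhancement operator."""

    bg_window_t: float = 1.5  # s, temporal extent of the background median
    bg_window_f: float = 20.0  # Hz, spectral extent of the background median
    beta: float = 2.0  # mask steepness, 1/dB
    tau: float = 3.0  # contrast threshold, dB
    ridge_window_t: float = 1.5  # s, temporal coherence window for the contrast

    def __post_init__(self) -> None:
        for name in ("bg_window_t", "bg_window_f", "beta", "tau", "ridge_window_t"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def stft_spectrogram(
    clip: AudioClip,
    frame_len: float = 0.3,
    hop: float = 0.1,
    window: str = "hann",
) -> Spectrogram:
    """Magnitude STFT with 300 ms frames and 100 ms hop by default (2/3 overlap).

    Frame count is floor((n_samples - frame_samples)/hop_samples) + 1; no
    zero-padding beyond the final full frame.
    """
    if not frame_len > hop > 0:
        raise ValueError(f"need frame_len > hop > 0, got {frame_len}, {hop}")
    n_frame = int(round(frame_len * clip.rate))
    n_hop = int(round(hop * clip.rate))
    x = clip.samples
    if x.size < n_frame:
        raise ValueError(
            f"clip of {x.size} samples shorter than one frame ({n_frame} samples)"
        )
    n_frames = (x.size - n_frame) // n_hop + 1
    if window == "hann":
        win = hann(n_frame, sym=False)
    else:
        from scipy.signal import get_window

        win = get_window(window, n_frame, fftbins=True)
    idx = np.arange(n_frame)[None, :] + n_hop * np.arange(n_frames)[:, None]
    frames = x[idx] * win[None, :]
    values = np.abs(np.fft.rfft(frames, axis=1))
    freqs = np.fft.rfftfreq(n_frame, 1 / clip.rate)
    times = (np.arange(n_frames) * n_hop + n_frame / 2) / clip.rate
    return Spectrogram(values, times, freqs, frame_len, hop)


def enhance_spectrogram(spec: Spectrogram, params: EnhanceParams | None = None) -> Spectrogram:
    """Soft-mask the spectrogram by local dB contrast.

    L = floored dB magnitudes; B = 2-D median of L over the background
    window; C = L - B, averaged along time over the ridge-coherence window
    (a genuine frequency contour persists across frames, an isolated noise
    spike does not); mask M = logistic(beta * (C - tau)) in (0, 1); output
    magnitudes = input * M.  Shape, times and freqs are unchanged.
    """
    params = params or EnhanceParams()
    hop = spec.hop
    df = spec.freqs[1] - spec.freqs[0] if spec.freqs.size > 1 else 1.0
    wt = max(1, int(round(params.bg_window_t / hop)))
    wf = max(1, int(round(params.bg_window_f / df)))
    wt += 1 - wt % 2  # odd sizes centre the window
    wf += 1 - wf % 2
    if wt > spec.values.shape[0] or wf > spec.values.shape[1]:
        raise ValueError(
            f"background window ({wt} frames x {wf} bins) exceeds the "
            f"spectrogram shape {spec.values.shape}"
        )
    vmax = spec.values.max()
    if vmax == 0:
        return Spectrogram(
            spec.values.copy(), spec.times, spec.freqs, spec.frame_len, spec.hop
        )
    L = 20 * np.log10(np.maximum(spec.values, vmax * 10 ** (-DB_FLOOR / 20)))
    B = median_filter(L, size=(wt, wf), mode="nearest")
    C = L - B
    wr = max(1, int(round(params.ridge_window_t / hop)))
    if wr > 1:
        C = uniform_filter1d(C, size=wr, axis=0, mode="nearest")
    M = expit(params.beta * (C - params.tau))
    return Spectrogram(spec.values * M, spec.times, spec.freqs, spec.frame_len, spec.hop)


def snr_ridge(
    spec: Spectrogram,
    annotation: EventAnnotation,
    band: tuple[float, float],
) -> float:
    """Ridge-to-background diagnostic in dB.

    10*log10 of the mean energy inside (annotation interval x band) over the
    mean energy outside the interval within the same band.
    """
    t_in = (spec.times >= annotation.start) & (spec.times <= annotation.end)
    f_in = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
    if not t_in.any() or t_in.all():
        raise ValueError("annotation must cover some but not all frames")
    if not f_in.any():
        raise ValueError(f"band {band} does not intersect the frequency grid")
    e = spec.values**2
    inside = e[np.ix_(t_in, f_in)].mean()
    outside = e[np.ix_(~t_in, f_in)].mean()
    if outside == 0:
        raise ValueError("outside region carries no energy")
    return float(10 * np.log10(inside / outside))
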