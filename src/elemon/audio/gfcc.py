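"""Greenwood-warped filterbank and cepstral features (GFCC).

The Greenwood function f(x) = A * (10**(a*x) - k) maps normalised cochlear
position x in [0, 1] to frequency and generalises the mel warp to arbitrary
species: fitting A and a to a hearing range [fmin, fmax] places filterbank
centres according to that species' critical bands.  GFCCs are then computed
exactly like MFCCs — filterbank energies on the warped axis, log, DCT-II —
but on the elephant-appropriate axis, which concentrates resolution in the
infrasonic band where rumbles live.

Frame features are aggregated over a sliding context window by concatenating
the per-dimension mean and population variance, giving the classifier a
longer-term view (roughly a second) than a single 300 ms frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct

from .spectral import Spectrogram

#: conventional Greenwood integration constant
GREENWOOD_K = 0.88


@dataclass(frozen=True)
class GreenwoodMap:
    """Greenwood cochlear-position warp f(x) = A * (10**(a*x) - k)."""

    A: float
    a: float
    k: float

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError(f"A must be positive, got {self.A}")
        if self.a <= 0:
            raise ValueError(f"a must be positive, got {self.a}")
        if not 0 < self.k < 1:
            raise ValueError(f"k must lie in (0, 1), got {self.k}")

    def forward(self, x: np.ndarray | float) -> np.ndarray | float:
        """Cochlear position x in [0, 1] -> frequency in Hz."""
        return self.A * (10 ** (self.a * np.asarray(x, dtype=float)) - self.k)

    def inverse(self, f: np.ndarray | float) -> np.ndarray | float:
        """Frequency in Hz -> cochlear position x."""
        return np.log10(np.asarray(f, dtype=float) / self.A + self.k) / self.a


def greenwood_from_range(fmin: float, fmax: float, k: float = GREENWOOD_K) -> GreenwoodMap:
    """Fit the Greenwood map so that f(0) = fmin and f(1) = fmax exactly."""
    if not 0 < fmin:
        raise ValueError(f"fmin must be positive, got {fmin}")
    if not fmin < fmax:
        raise ValueError(f"fmax must exceed fmin, got fmin={fmin}, fmax={fmax}")
    if not 0 < k < 1:
        raise ValueError(f"k must lie in (0, 1), got {k}")
    A = fmin / (1 - k)
    a = np.log10(fmax / A + k)
    return GreenwoodMap(A=A, a=float(a), k=k)


@dataclass
class Filterbank:
    """Triangular filters with unit peaks on the Greenwood-warped axis."""

    n_filters: int
    rate: float
    fft_size: int
    centers: np.ndarray  # Hz, strictly increasing
    weights: np.ndarray  # (n_filters, n_bins), non-negative

    def __post_init__(self) -> None:
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("filter centers must be strictly increasing")
        if np.any(self.weights < 0):
            raise ValueError("filter weights must be non-negative")


def build_filterbank(
    gmap: GreenwoodMap,
    n_filters: int,
    fmin: float,
    fmax: float,
    rate: float,
    fft_size: int,
) -> Filterbank:
    """Place n_filters triangles between fmin and fmax, equal-width in warp space.

    n_filters + 2 edge points are equally spaced on the warped axis between
    x(fmin) and x(fmax) and mapped back to Hz; filter i is the triangle over
    edges (i, i+1, i+2) evaluated at the FFT bin frequencies, peak-normalised
    to 1.
    """
    if n_filters < 2:
        raise ValueError(f"n_filters must be >= 2, got {n_filters}")
    if fmax > rate / 2 + 1e-9:
        raise ValueError(f"fmax {fmax} Hz exceeds the Nyquist frequency {rate / 2} Hz")
    x_edges = np.linspace(gmap.inverse(fmin), gmap.inverse(fmax), n_filters + 2)
    edges = np.asarray(gmap.forward(x_edges), dtype=float)
    bin_freqs = np.fft.rfftfreq(fft_size, 1 / rate)
    weights = np.zeros((n_filters, bin_freqs.size))
    for i in range(n_filters):
        lo, c, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (bin_freqs - lo) / (c - lo)
        down = (hi - bin_freqs) / (hi - c)
        weights[i] = np.clip(np.minimum(up, down), 0, None)
    return Filterbank(n_filters, rate, fft_size, edges[1:-1], weights)


@dataclass
class FeatureSequence:
    """One feature vector per spectrogram frame."""

    vectors: np.ndarray  # (n_frames, dim)
    times: np.ndarray  # s per frame

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.shape[0] != np.asarray(self.times).size:
            raise ValueError("one vector per frame required")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("feature vectors must be finite")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


@dataclass(frozen=True)
class ContextFeature:
    """Concatenated mean || variance over one context window of frames."""

    vector: np.ndarray  # (2*dim,)
    span: tuple[float, float]  # (start s, end s)


LOG_FLOOR_REL = 1e-10  # energy floor relative to the frame's max filter energy


def gfcc_frames(
    spec: Spectrogram,
    fb: Filterbank,
    n_ceps: int = 12,
    drop_c0: bool = True,
) -> FeatureSequence:
    """Per frame: squared magnitudes -> filterbank energies -> log -> DCT-II.

    The orthonormal type-II DCT of the log energies is truncated to the first
    ``n_ceps`` coefficients; with ``drop_c0`` the energy term c0 is excluded,
    which makes the features gain-invariant (up to the log floor).
    """
    if n_ceps > fb.n_filters:
        raise ValueError("n_ceps must not exceed n_filters")
    expected = np.fft.rfftfreq(fb.fft_size, 1 / fb.rate)
    if spec.freqs.size != expected.size or not np.allclose(spec.freqs, expected):
        raise ValueError(
            "spectrogram frequency grid does not match the filterbank FFT layout"
        )
    power = spec.values**2
    energies = power @ fb.weights.T  # (n_frames, n_filters)
    # floor relative to the sequence-wide maximum: frames silenced by
    # enhancement collapse to a constant log-energy profile instead of
    # amplifying whatever speck of energy survived in them
    floor = LOG_FLOOR_REL * max(float(energies.max()), 1e-300)
    log_e = np.log(np.maximum(energies, floor))
    ceps = dct(log_e, type=2, norm="ortho", axis=1)
    if drop_c0:
        vectors = ceps[:, 1 : n_ceps + 1]
    else:
        vectors = ceps[:, :n_ceps]
    return FeatureSequence(vectors, spec.times)


def aggregate_context(
    features: FeatureSequence,
    window: int = 10,
    hop: int = 5,
) -> list[ContextFeature]:
    """Sliding-window mean || population-variance aggregation."""
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    n = features.vectors.shape[0]
    if window > n:
        raise ValueError(f"window of {window} frames exceeds the {n} available frames")
    out: list[ContextFeature] = []
    for s in range(0, n - window + 1, hop):
        block = features.vectors[s : s + window]
        mean = block.mean(axis=0)
        var = block.var(axis=0)  # population variance
        out.append(
            ContextFeature(
                np.concatenate([mean, var]),
                (float(features.times[s]), float(features.times[s + window - 1])),
            )
        )
    return out
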