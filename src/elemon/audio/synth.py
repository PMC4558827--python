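"""Seeded synthetic soundscapes: rumbles, field noise and annotated mixtures.

Elephant rumbles are low-frequency harmonic calls with a fundamental around
10-30 Hz.  The generator emulates the properties an acoustic detector relies
on — a slowly gliding fundamental with a harmonic stack, a formant-like
spectral envelope and a smooth attack/release — without claiming to model
elephant vocal production.  Background events cover the dominant field
confounds: wind (low-passed, gust-modulated broadband noise), rain (sparse
broadband impulses) and engines (near-stationary harmonic stacks that mimic
the rumble's structure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from ..types import AudioClip, EventAnnotation

# band used for in-band SNR accounting; rumble energy lives well inside it
SNR_BAND = (5.0, 150.0)

DEFAULT_RATE = 4000.0
NOISE_KINDS = ("wind", "rain", "engine")


@dataclass(frozen=True)
class RumbleSpec:
    """Parameters of one synthetic rumble."""

    f0_start: float = 20.0
    f0_end: float = 20.0
    duration: float = 3.0
    n_harmonics: int = 8
    envelope_attack: float = 0.3
    envelope_release: float = 0.4
    formant_centers: tuple[float, ...] = (40.0, 120.0)
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        for name in ("f0_start", "f0_end"):
            f0 = getattr(self, name)
            if not 5.0 <= f0 <= 40.0:
                raise ValueError(f"{name} must lie in [5, 40] Hz, got {f0}")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.n_harmonics < 1:
            raise ValueError(f"n_harmonics must be >= 1, got {self.n_harmonics}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")


@dataclass(frozen=True)
class NoiseSpec:
    """Parameters of one background-noise event."""

    kind: str
    duration: float
    level: float = 0.2
    engine_f0: float = 30.0

    def __post_init__(self) -> None:
        if self.kind not in NOISE_KINDS:
            raise ValueError(
                f"unknown noise kind {self.kind!r}; legal kinds: {', '.join(NOISE_KINDS)}"
            )
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.level < 0:
            raise ValueError(f"level must be >= 0, got {self.level}")
        if self.kind == "engine" and not 15.0 <= self.engine_f0 <= 60.0:
            raise ValueError(f"engine_f0 must lie in [15, 60] Hz, got {self.engine_f0}")


@dataclass(frozen=True)
class SoundscapeSpec:
    """A full annotated scene: rumbles and noises placed on a timeline."""

    total_duration: float
    rate: float = DEFAULT_RATE
    events: tuple[tuple[RumbleSpec, float], ...] = ()
    noises: tuple[tuple[NoiseSpec, float], ...] = ()
    in_band_snr: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_duration <= 0:
            raise ValueError("total_duration must be positive")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        for spec, onset in self.events:
            if onset < 0 or onset + spec.duration > self.total_duration + 1e-9:
                raise ValueError(
                    f"rumble at onset {onset}s with duration {spec.duration}s "
                    f"exceeds total_duration {self.total_duration}s"
                )
        for spec, onset in self.noises:
            if onset < 0 or onset + spec.duration > self.total_duration + 1e-9:
                raise ValueError(
                    f"noise at onset {onset}s with duration {spec.duration}s "
                    f"exceeds total_duration {self.total_duration}s"
                )


def _formant_envelope(freqs: np.ndarray, centers: tuple[float, ...]) -> np.ndarray:
    """Raised-Gaussian spectral envelope: unit floor plus a bump per formant."""
    env = np.full_like(freqs, 0.25, dtype=np.float64)
    for c in centers:
        env += np.exp(-0.5 * ((freqs - c) / (0.35 * c)) ** 2)
    return env


def synth_rumble(spec: RumbleSpec, rate: float = DEFAULT_RATE, seed: int = 0) -> AudioClip:
    """Render one rumble: harmonic stack on a linear F0 glide.

    Harmonic h carries relative amplitude (1/h) x formant envelope; harmonics
    at or above Nyquist are dropped silently.  An attack/release ramp shapes
    the onset and offset, and the waveform is peak-normalised to
    ``spec.amplitude``.
    """
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    rng = np.random.default_rng(seed)
    n = max(1, int(round(spec.duration * rate)))
    t = np.arange(n) / rate
    f0 = np.linspace(spec.f0_start, spec.f0_end, n)
    phase0 = 2 * np.pi * np.cumsum(f0) / rate
    x = np.zeros(n)
    for h in range(1, spec.n_harmonics + 1):
        fh = f0 * h
        if fh.max() >= rate / 2:
            continue  # above Nyquist: drop
        centre = h * 0.5 * (spec.f0_start + spec.f0_end)
        gain = (1.0 / h) * float(_formant_envelope(np.array([centre]), spec.formant_centers)[0])
        x += gain * np.sin(h * phase0 + rng.uniform(0, 2 * np.pi))
    # attack / release amplitude shaping (clipped to at most half the call each)
    env = np.ones(n)
    na = min(int(spec.envelope_attack * rate), n // 2)
    nr = min(int(spec.envelope_release * rate), n // 2)
    if na > 0:
        env[:na] = np.linspace(0, 1, na)
    if nr > 0:
        env[-nr:] = np.linspace(1, 0, nr)
    x *= env
    peak = np.max(np.abs(x))
    if peak > 0 and spec.amplitude > 0:
        x *= spec.amplitude / peak
    else:
        x[:] = 0.0
    return AudioClip(np.clip(x, -1, 1), rate)


def synth_noise(spec: NoiseSpec, rate: float = DEFAULT_RATE, seed: int = 0) -> AudioClip:
    """Render one noise event (wind, rain or engine); deterministic per seed."""
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    rng = np.random.default_rng(seed)
    n = max(1, int(round(spec.duration * rate)))
    if spec.level == 0:
        return AudioClip(np.zeros(n), rate)
    if spec.kind == "wind":
        # pad before filtering and trim after, so the clip edges are as
        # stationary as the interior (no filter start-up transient)
        pad = int(2.0 * rate)
        x = rng.standard_normal(n + 2 * pad)
        sos = butter(4, min(200.0, 0.45 * rate) / (rate / 2), btype="low", output="sos")
        x = sosfiltfilt(sos, x)[pad : pad + n]
        # slow gust modulation: smoothed positive envelope, ~0.3 Hz variation
        g = rng.standard_normal(n + 2 * pad)
        sos_g = butter(2, 0.3 / (rate / 2), btype="low", output="sos")
        g = sosfiltfilt(sos_g, g)[pad : pad + n]
        g = 0.4 + np.abs(g) / (np.std(g) + 1e-12)
        x = x * g
    elif spec.kind == "rain":
        x = np.zeros(n)
        n_drops = max(1, int(spec.duration * 40))  # ~40 impulses per second
        starts = rng.integers(0, n, n_drops)
        for s in starts:
            burst_len = int(rng.uniform(0.002, 0.02) * rate)
            e = min(n, s + max(1, burst_len))
            x[s:e] += rng.uniform(0.2, 1.0) * rng.standard_normal(e - s) * np.hanning(
                2 * (e - s)
            )[: e - s]
    else:  # engine
        t = np.arange(n) / rate
        # tiny F0 wobble keeps it from being a perfect comb
        f0 = spec.engine_f0 * (1 + 0.005 * np.sin(2 * np.pi * 0.5 * t))
        phase0 = 2 * np.pi * np.cumsum(f0) / rate
        x = np.zeros(n)
        for h in range(1, 13):
            if spec.engine_f0 * h >= rate / 2:
                break
            x += (1.0 / h) * np.sin(h * phase0 + rng.uniform(0, 2 * np.pi))
        x += 0.05 * rng.standard_normal(n)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x * (spec.level / peak)
    return AudioClip(np.clip(x, -1, 1), rate)


def band_energy(x: np.ndarray, rate: float, band: tuple[float, float] = SNR_BAND) -> float:
    """Total spectral energy of ``x`` inside ``band`` (rfft accounting)."""
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), 1 / rate)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(spec[sel].sum())


@dataclass
class Soundscape:
    """Result of :func:`compose_soundscape`."""

    clip: AudioClip
    events: list[EventAnnotation] = field(default_factory=list)
    noise_events: list[EventAnnotation] = field(default_factory=list)

    def __iter__(self):
        # tuple-style unpacking: (clip, rumble annotations, noise annotations)
        return iter((self.clip, self.events, self.noise_events))


def compose_soundscape(spec: SoundscapeSpec) -> Soundscape:
    """Mix rumbles and noises into one annotated clip.

    Noises are summed first into a background track.  Each rumble is then
    rescaled so that, inside its own interval and the 5-150 Hz band, the
    rumble-to-background energy ratio equals ``in_band_snr`` dB (skipped when
    ``in_band_snr`` is None or the local background has no in-band energy).
    The final mix is peak-normalised to 0.9.  Rumbles are annotated exactly at
    their onsets/offsets; engine noises are annotated separately so that
    evaluation can report confusions — they are never positives.
    """
    rate = spec.rate
    n_total = int(round(spec.total_duration * rate))
    root = np.random.default_rng(spec.seed)
    noise_seeds = root.integers(0, 2**31 - 1, size=max(1, len(spec.noises)))
    event_seeds = root.integers(0, 2**31 - 1, size=max(1, len(spec.events)))

    background = np.zeros(n_total)
    noise_events: list[EventAnnotation] = []
    for k, (nspec, onset) in enumerate(spec.noises):
        clip = synth_noise(nspec, rate, seed=int(noise_seeds[k]))
        i0 = int(round(onset * rate))
        i1 = min(n_total, i0 + clip.samples.size)
        background[i0:i1] += clip.samples[: i1 - i0]
        if nspec.kind == "engine":
            noise_events.append(EventAnnotation(onset, onset + nspec.duration, "engine"))

    mix = background.copy()
    events: list[EventAnnotation] = []
    for k, (rspec, onset) in enumerate(spec.events):
        clip = synth_rumble(rspec, rate, seed=int(event_seeds[k]))
        i0 = int(round(onset * rate))
        i1 = min(n_total, i0 + clip.samples.size)
        seg = clip.samples[: i1 - i0]
        if spec.in_band_snr is not None:
            e_sig = band_energy(seg, rate)
            e_bg = band_energy(background[i0:i1], rate)
            if e_bg > 0 and e_sig > 0:
                target = 10 ** (spec.in_band_snr / 10)
                seg = seg * np.sqrt(target * e_bg / e_sig)
        mix[i0:i1] += seg
        events.append(EventAnnotation(onset, onset + rspec.duration, "rumble"))

    peak = np.max(np.abs(mix)) if n_total else 0.0
    if peak > 0:
        mix *= 0.9 / peak
    return Soundscape(AudioClip(mix, rate), events, noise_events)
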