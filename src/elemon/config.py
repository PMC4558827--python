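"""Run configuration: every tunable default, grouped by namespace.

A :class:`RunConfig` collects the knobs of the audio synthesiser, spectral
enhancement, GFCC front end, acoustic detector, scene synthesiser and visual
detector.  Configs load from YAML; unknown keys are rejected so that typos
fail loudly, and every CLI command writes a config echo next to its outputs
so a run can be reproduced bit-for-bit from the echo alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class AudioConfig:
    rate: float = 4000.0
    snr_band: tuple[float, float] = (5.0, 150.0)
    default_rumble_duration: tuple[float, float] = (1.0, 5.0)


@dataclass
class EnhanceConfig:
    enabled: bool = True
    bg_window_t: float = 1.5
    bg_window_f: float = 20.0
    beta: float = 2.0
    tau: float = 3.0
    ridge_window_t: float = 1.5


@dataclass
class GfccConfig:
    fmin: float = 8.0
    fmax: float = 2000.0
    k: float = 0.88
    n_filters: int = 26
    n_ceps: int = 12
    drop_c0: bool = True
    context_window: int = 10
    context_hop: int = 5


@dataclass
class DetectConfig:
    frame_len: float = 0.3
    hop: float = 0.1
    C: float = 1.0
    threshold: float = 0.0
    max_gap: float = 1.5
    min_duration: float = 0.5
    hysteresis: float = 0.3
    edge_margin: float = 1.0
    train_frac: float = 0.10


@dataclass
class SceneConfig:
    width: int = 320
    height: int = 240
    fps: float = 25.0
    n_frames: int = 50
    distance_class: str = "near"
    n_elephants: int = 1
    occlusion_fraction: float = 0.0
    illumination_drift: float = 0.01
    camera_jitter: float = 1.0


@dataclass
class VisualConfig:
    color_space: str = "rgbn"
    hs: float = 6.0
    hr: float = 5.0
    min_region: int = 20
    max_iter: int = 50
    tol: float = 0.1
    min_bbox_overlap: float = 0.2
    group_gap: float = 12.0
    max_centroid_dist_frac: float = 0.1  # of the frame diagonal
    max_frame_gap: int = 2
    min_length: int = 5
    max_step_frac: float = 0.05  # of the frame diagonal
    cover_thresh: float = 0.5
    fp_thresh: float = 0.1
    C: float = 300.0


@dataclass
class RunConfig:
    audio: AudioConfig = field(default_factory=AudioConfig)
    enhance: EnhanceConfig = field(default_factory=EnhanceConfig)
    gfcc: GfccConfig = field(default_factory=GfccConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    scene: SceneConfig = field(default_factory=SceneConfig)
    visual: VisualConfig = field(default_factory=VisualConfig)
    seed: int = 0

    def front_end(self, enhance: bool | None = None):
        from .audio.detect import FrontEndConfig
        from .audio.spectral import EnhanceParams

        return FrontEndConfig(
            frame_len=self.detect.frame_len,
            hop=self.detect.hop,
            enhance=self.enhance.enabled if enhance is None else enhance,
            enhance_params=EnhanceParams(
                bg_window_t=self.enhance.bg_window_t,
                bg_window_f=self.enhance.bg_window_f,
                beta=self.enhance.beta,
                tau=self.enhance.tau,
                ridge_window_t=self.enhance.ridge_window_t,
            ),
            fmin=self.gfcc.fmin,
            fmax=self.gfcc.fmax,
            greenwood_k=self.gfcc.k,
            n_filters=self.gfcc.n_filters,
            n_ceps=self.gfcc.n_ceps,
            drop_c0=self.gfcc.drop_c0,
            context_window=self.gfcc.context_window,
            context_hop=self.gfcc.context_hop,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def echo(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _update_dataclass(obj, values: dict, path: str):
    names = {f.name for f in dataclasses.fields(obj)}
    for key, val in values.items():
        if key not in names:
            raise ValueError(f"unknown config key {path}{key!r}")
        cur = getattr(obj, key)
        if dataclasses.is_dataclass(cur) and isinstance(val, dict):
            _update_dataclass(cur, val, f"{path}{key}.")
        elif isinstance(cur, tuple) and isinstance(val, (list, tuple)):
            setattr(obj, key, tuple(val))
        else:
            setattr(obj, key, type(cur)(val) if cur is not None else val)
    return obj


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config over the defaults; unknown keys are rejected."""
    cfg = RunConfig()
    if path is None:
        return cfg
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    _update_dataclass(cfg, data, "")
    return cfg
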