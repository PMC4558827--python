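"""Seeded synthetic wildlife scenes with per-pixel elephant masks.

Frames emulate the features a colour-and-continuity detector must cope with
in field footage: gray-brown elephant bodies of near (large) or far (small)
apparent size, a green/brown textured background with darker shadow patches
whose colours deliberately approach elephant skin, vegetation strips that
occlude parts of each body, slow object motion, camera jitter and smooth
illumination drift.  Masks record only the visible elephant pixels, matching
ground truth in which partly occluded bodies are annotated as the visible
fragments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

# sRGB mean of the elephant skin distribution; per-blob jitter +-15, per-pixel
# texture +-10 per channel
ELEPHANT_MEAN = np.array([110.0, 100.0, 95.0])
BLOB_JITTER = 15.0
PIXEL_TEXTURE = 10.0

# dry bare earth: gray-brown like the animals, slightly browner chromaticity
SOIL_MEAN = np.array([138.0, 110.0, 80.0])

#: blob area as a fraction of the frame, per distance class
AREA_RANGE = {"near": (0.05, 0.25), "far": (0.001, 0.01)}


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one rendered sequence."""

    width: int = 320
    height: int = 240
    n_frames: int = 50
    fps: float = 25.0
    distance_class: str = "near"
    n_elephants: int = 1
    occlusion_fraction: float = 0.0
    illumination_drift: float = 0.01
    camera_jitter: float = 1.0
    n_shadows: int = 3
    n_soil: int = 4
    optics_blur: float = 0.7  # camera PSF sigma, px
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distance_class not in AREA_RANGE:
            raise ValueError(
                f"distance_class must be one of {sorted(AREA_RANGE)}, got {self.distance_class!r}"
            )
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0 <= self.occlusion_fraction < 1:
            raise ValueError("occlusion_fraction must lie in [0, 1)")
        if self.n_elephants < 0:
            raise ValueError("n_elephants must be >= 0")


@dataclass
class FrameSequence:
    frames: np.ndarray  # (n, H, W, 3) uint8 sRGB
    timestamps: np.ndarray  # s, spaced 1/fps


@dataclass
class MaskSequence:
    masks: np.ndarray  # (n, H, W) uint8; 0 background, 1..n_elephants object ids


def _superellipse_blob(rng: np.random.Generator, area_px: float) -> tuple[np.ndarray, int, int]:
    """An irregular superellipse-ish binary blob of approximately area_px pixels."""
    aspect = rng.uniform(1.2, 1.9)  # elephants are wider than tall
    p = rng.uniform(2.0, 3.0)  # superellipse exponent
    b = np.sqrt(area_px / (4 * aspect))  # coarse area ~ 4*a*b for p~2.5
    a = aspect * b
    h = int(np.ceil(2.4 * b))
    w = int(np.ceil(2.4 * a))
    yy, xx = np.mgrid[:h, :w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    # irregular boundary: angular radius perturbation from a few harmonics
    ang = np.arctan2(yy - cy, xx - cx)
    wob = np.ones_like(ang)
    for m in range(2, 6):
        wob += 0.08 * rng.uniform(-1, 1) * np.cos(m * ang + rng.uniform(0, 2 * np.pi))
    r = (np.abs((xx - cx) / (a * wob)) ** p + np.abs((yy - cy) / (b * wob)) ** p) ** (1 / p)
    return r <= 1.0, h, w


def render_scene(spec: SceneSpec) -> tuple[FrameSequence, MaskSequence]:
    """Render the sequence and its visible-pixel ground-truth masks."""
    rng = np.random.default_rng(spec.seed)
    H, W, n = spec.height, spec.width, spec.n_frames
    frame_area = H * W

    # --- static background: smooth green/brown hue field + fine texture
    base = gaussian_filter(rng.normal(0, 1, (H, W)), 25)
    base = (base - base.min()) / (np.ptp(base) + 1e-12)
    green = np.array([95.0, 130.0, 70.0])
    brown = np.array([140.0, 115.0, 75.0])
    background = base[..., None] * green + (1 - base[..., None]) * brown
    background += gaussian_filter(rng.normal(0, 1, (H, W, 3)), (1.2, 1.2, 0)) * 12

    # bare-soil patches: dry earth shares the elephants' gray-brown hue
    # (elephants dust-bathe in it), so its chromaticity sits just outside
    # the skin colour distribution — the honest confusable material that
    # makes colour-based detection non-trivial, especially for small
    # far-distance segments whose mean colours are noisy.
    for _ in range(spec.n_soil):
        so_area = rng.uniform(0.0005, 0.002) * frame_area
        blob, bh, bw = _superellipse_blob(rng, so_area)
        y0 = rng.integers(0, max(1, H - bh))
        x0 = rng.integers(0, max(1, W - bw))
        # earth colour is consistent across a site (small patch-to-patch
        # jitter) but strongly textured at pixel scale: large segments
        # average it out, small far-distance fragments do not
        colour = SOIL_MEAN + rng.uniform(-2, 2, 3)
        sub = background[y0 : y0 + bh, x0 : x0 + bw]
        b = blob[: sub.shape[0], : sub.shape[1]]
        sub[b] = colour + rng.normal(0, 5, (int(b.sum()), 3))

    # shadow patches: the local vegetation/ground colours darkened, as cast
    # shadow does.  Individual shadow pixels overlap the dark tail of the
    # skin distribution in lightness, but a shadow region keeps the
    # background's hue, so the task stays learnable rather than trivial.
    for _ in range(spec.n_shadows):
        sh_area = rng.uniform(0.002, 0.004) * frame_area
        blob, bh, bw = _superellipse_blob(rng, sh_area)
        y0 = rng.integers(0, max(1, H - bh))
        x0 = rng.integers(0, max(1, W - bw))
        sub = background[y0 : y0 + bh, x0 : x0 + bw]
        b = blob[: sub.shape[0], : sub.shape[1]]
        # direct light blocked; what remains is blue-biased ambient skylight
        ambient = np.array([0.0, 1.5, 4.0]) + rng.uniform(-1, 1, 3)
        sub[b] = sub[b] * rng.uniform(0.45, 0.60) + ambient

    # --- elephants
    lo, hi = AREA_RANGE[spec.distance_class]
    blobs = []
    for obj in range(spec.n_elephants):
        area = rng.uniform(lo, hi) * frame_area
        blob, bh, bw = _superellipse_blob(rng, area)
        if bh >= H or bw >= W:
            raise ValueError(
                f"blob of {bh}x{bw} px cannot fit the {H}x{W} frame at the requested area"
            )
        colour = ELEPHANT_MEAN + rng.uniform(-BLOB_JITTER, BLOB_JITTER, 3)
        texture = 1 + gaussian_filter(rng.normal(0, 1, (bh, bw)), 1.5) * (
            PIXEL_TEXTURE / 255.0
        )
        pos = np.array(
            [
                rng.uniform(0, H - bh),
                rng.uniform(0, W - bw),
            ]
        )
        speed = rng.uniform(0.2, 1.5)  # px per frame, slow motion
        heading = rng.uniform(0, 2 * np.pi)
        # occlusion: vegetation-coloured vertical strips over the blob,
        # chosen so they cover ~occlusion_fraction of the blob pixels
        occ = np.zeros((bh, bw), dtype=bool)
        if spec.occlusion_fraction > 0:
            col_area = blob.sum(axis=0).astype(float)
            target = spec.occlusion_fraction * blob.sum()
            cols = rng.permutation(bw)
            covered = 0.0
            strip_cols = []
            for c in cols:
                if covered >= target:
                    break
                strip_cols.append(c)
                covered += col_area[c]
            occ[:, strip_cols] = True
        veg_colour = np.array([70.0, 110.0, 55.0]) + rng.uniform(-10, 10, 3)
        blobs.append(
            dict(
                mask=blob,
                occ=occ,
                colour=colour,
                texture=texture,
                pos=pos,
                vel=speed * np.array([np.sin(heading), np.cos(heading)]),
                veg=veg_colour,
                shape=(bh, bw),
            )
        )

    frames = np.empty((n, H, W, 3), dtype=np.uint8)
    masks = np.zeros((n, H, W), dtype=np.uint8)
    gain = 1.0
    jitter = np.zeros(2)
    for f in range(n):
        if f > 0:
            gain = float(
                np.clip(
                    gain + rng.uniform(-spec.illumination_drift, spec.illumination_drift),
                    0.8,
                    1.2,
                )
            )
            jitter = np.clip(
                jitter + rng.uniform(-spec.camera_jitter, spec.camera_jitter, 2),
                -3 * spec.camera_jitter - 1e-9,
                3 * spec.camera_jitter + 1e-9,
            )
        canvas = background.copy()
        mask = np.zeros((H, W), dtype=np.uint8)
        for oid, b in enumerate(blobs, start=1):
            bh, bw = b["shape"]
            if f > 0:
                step = b["vel"] + rng.normal(0, 0.2, 2)
                newpos = b["pos"] + step
                # bounce off the frame edges
                for k, limit in enumerate((H - bh, W - bw)):
                    if newpos[k] < 0 or newpos[k] > limit:
                        b["vel"][k] *= -1
                        newpos[k] = np.clip(newpos[k], 0, limit)
                b["pos"] = newpos
            y0 = int(round(b["pos"][0] + jitter[0]))
            x0 = int(round(b["pos"][1] + jitter[1]))
            y0 = int(np.clip(y0, 0, H - bh))
            x0 = int(np.clip(x0, 0, W - bw))
            body = b["mask"]
            visible = body & ~b["occ"]
            sub = canvas[y0 : y0 + bh, x0 : x0 + bw]
            sub[visible] = b["colour"] * b["texture"][visible][:, None]
            sub[body & b["occ"]] = b["veg"]
            mask[y0 : y0 + bh, x0 : x0 + bw][visible] = oid
        if spec.optics_blur > 0:
            # camera point-spread function: boundary pixels mix object and
            # background colour — negligible for large bodies, substantial
            # for far-distance blobs whose rim is a large area fraction
            canvas = gaussian_filter(canvas, (spec.optics_blur, spec.optics_blur, 0))
        canvas = canvas + rng.normal(0, 2.0, canvas.shape)  # sensor noise
        frames[f] = np.clip(canvas * gain, 0, 255).astype(np.uint8)
        masks[f] = mask
    times = np.arange(n) / spec.fps
    return FrameSequence(frames, times), MaskSequence(masks)


def sample_pixels(
    frames: FrameSequence,
    masks: MaskSequence,
    n_per_class: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform without-replacement samples of foreground and background colours.

    Returns (foreground, background) arrays of shape (n_per_class, 3), uint8
    sRGB, drawn across all frames of the sequence.
    """
    rng = np.random.default_rng(seed)
    fg_idx = np.flatnonzero(masks.masks.ravel() > 0)
    bg_idx = np.flatnonzero(masks.masks.ravel() == 0)
    if fg_idx.size == 0 or bg_idx.size == 0:
        raise ValueError("both foreground and background pixels must be present")
    flat = frames.frames.reshape(-1, 3)
    fg = flat[rng.choice(fg_idx, size=min(n_per_class, fg_idx.size), replace=False)]
    bg = flat[rng.choice(bg_idx, size=min(n_per_class, bg_idx.size), replace=False)]
    return fg, bg
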