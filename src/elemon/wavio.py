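"""16-bit PCM mono WAV read/write for AudioClip objects."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .types import AudioClip


def write_wav(clip: AudioClip, path: str | Path) -> None:
    data = np.clip(np.round(clip.samples * 32767), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), int(clip.rate), data)


def read_wav(path: str | Path) -> AudioClip:
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data.mean(axis=1)
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32767.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483647.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128) / 127.0
    else:
        samples = data.astype(np.float64)
    return AudioClip(np.clip(samples, -1, 1), float(rate))
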