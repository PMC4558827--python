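import numpy as np
import pytest

from elemon.audio.synth import (
    NoiseSpec,
    RumbleSpec,
    SoundscapeSpec,
    compose_soundscape,
)


@pytest.fixture(scope="session")
def wind_rumble_scene():
    """A 20 s soundscape: two rumbles over wind at -5 dB in-band SNR."""
    spec = SoundscapeSpec(
        total_duration=20.0,
        rate=4000.0,
        events=(
            (RumbleSpec(duration=3.0), 5.0),
            (RumbleSpec(duration=2.0, f0_start=15.0, f0_end=18.0), 12.0),
        ),
        noises=((NoiseSpec("wind", 20.0, level=0.3), 0.0),),
        in_band_snr=-5.0,
        seed=7,
    )
    return compose_soundscape(spec)


@pytest.fixture(scope="session")
def rumble_fixture_suite():
    """Seeded single-rumble scenes across SNRs, for enhancement properties."""
    scenes = []
    for seed, snr in [(0, -5.0), (1, 0.0), (2, 5.0), (3, 0.0)]:
        rng = np.random.default_rng(seed)
        spec = SoundscapeSpec(
            total_duration=20.0,
            rate=4000.0,
            events=((RumbleSpec(duration=3.0, f0_start=float(rng.uniform(10, 30))), 8.0),),
            noises=((NoiseSpec("wind", 20.0, level=0.3), 0.0),),
            in_band_snr=snr,
            seed=seed,
        )
        scenes.append(compose_soundscape(spec))
    return scenes
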