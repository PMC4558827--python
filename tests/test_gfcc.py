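"""Greenwood warp, filterbank construction, cepstra and context aggregation."""

import numpy as np
import pytest

from elemon.audio.gfcc import (
    ContextFeature,
    FeatureSequence,
    aggregate_context,
    build_filterbank,
    gfcc_frames,
    greenwood_from_range,
)
from elemon.audio.spectral import Spectrogram, stft_spectrogram
from elemon.types import AudioClip


class TestGreenwoodMap:
    def test_closed_form_parameters(self):
        g = greenwood_from_range(10.0, 10000.0, 0.88)
        assert g.A == pytest.approx(83.3333, rel=1e-4)
        assert g.a == pytest.approx(2.0824, rel=1e-4)

    def test_endpoints_exact(self):
        g = greenwood_from_range(8.0, 2000.0)
        assert g.forward(0.0) == pytest.approx(8.0, rel=1e-9)
        assert g.forward(1.0) == pytest.approx(2000.0, rel=1e-9)

    def test_midpoint_value(self):
        g = greenwood_from_range(10.0, 10000.0, 0.88)
        assert g.forward(0.5) == pytest.approx(842.9, abs=0.5)

    def test_round_trip_dense(self):
        g = greenwood_from_range(8.0, 2000.0)
        x = np.linspace(0, 1, 1001)
        np.testing.assert_allclose(g.inverse(g.forward(x)), x, atol=1e-9)

    def test_monotone_increasing(self):
        g = greenwood_from_range(8.0, 2000.0)
        f = np.asarray(g.forward(np.linspace(0, 1, 200)))
        assert np.all(np.diff(f) > 0)

    @pytest.mark.parametrize(
        "fmin,fmax,k,field",
        [(-1.0, 100.0, 0.88, "fmin"), (100.0, 50.0, 0.88, "fmax"), (10.0, 100.0, 1.5, "k")],
    )
    def test_invalid_arguments_named(self, fmin, fmax, k, field):
        with pytest.raises(ValueError, match=field):
            greenwood_from_range(fmin, fmax, k)


class TestFilterbank:
    @pytest.fixture(scope="class")
    def fb(self):
        g = greenwood_from_range(8.0, 2000.0)
        return build_filterbank(g, 26, 8.0, 2000.0, 4000.0, 1200)

    def test_edges_equally_spaced_in_warp(self, fb):
        g = greenwood_from_range(8.0, 2000.0)
        all_edges = np.concatenate([[8.0], fb.centers, [2000.0]])
        x = np.asarray(g.inverse(all_edges))
        steps = np.diff(x)
        np.testing.assert_allclose(steps, steps[0], rtol=1e-9)

    def test_every_filter_has_positive_weight(self, fb):
        assert np.all(fb.weights.sum(axis=1) > 0)

    def test_unit_peak_triangles(self, fb):
        # the analytic triangle peak is 1 at the centre frequency
        bin_freqs = np.fft.rfftfreq(1200, 1 / 4000.0)
        for i in range(fb.n_filters):
            w = fb.weights[i]
            assert 0 < w.max() <= 1.0 + 1e-12
            # weights rise then fall (triangle shape)
            nz = np.flatnonzero(w)
            peak = nz[np.argmax(w[nz])]
            assert np.all(np.diff(w[nz[0] : peak + 1]) >= -1e-12)
            assert np.all(np.diff(w[peak : nz[-1] + 1]) <= 1e-12)

    def test_nyquist_violation_rejected(self):
        g = greenwood_from_range(8.0, 3000.0)
        with pytest.raises(ValueError, match="Nyquist"):
            build_filterbank(g, 26, 8.0, 3000.0, 4000.0, 1200)


def _spec_from_frames(frame_mags, rate=4000.0, frame=0.3, hop=0.1):
    n = int(frame * rate)
    freqs = np.fft.rfftfreq(n, 1 / rate)
    vals = np.atleast_2d(frame_mags)
    times = (np.arange(vals.shape[0]) * hop * rate + n / 2) / rate
    return Spectrogram(vals, times, freqs, frame, hop)


class TestGfccFrames:
    @pytest.fixture(scope="class")
    def fb(self):
        g = greenwood_from_range(8.0, 2000.0)
        return build_filterbank(g, 26, 8.0, 2000.0, 4000.0, 1200)

    def test_dct_matches_brute_force_cosine_sum(self, fb):
        rng = np.random.default_rng(0)
        clip = AudioClip(np.clip(rng.standard_normal(8000) * 0.1, -1, 1), 4000)
        spec = stft_spectrogram(clip)
        feats = gfcc_frames(spec, fb, n_ceps=12, drop_c0=False)
        # brute-force orthonormal DCT-II on the log filterbank energies
        power = spec.values**2
        energies = power @ fb.weights.T
        floor = 1e-10 * energies.max()
        log_e = np.log(np.maximum(energies, floor))
        N = fb.n_filters
        for t in range(0, log_e.shape[0], 7):
            for k in range(12):
                scale = np.sqrt(1.0 / N) if k == 0 else np.sqrt(2.0 / N)
                ref = scale * sum(
                    log_e[t, n] * np.cos(np.pi * k * (2 * n + 1) / (2 * N)) for n in range(N)
                )
                assert feats.vectors[t, k] == pytest.approx(ref, abs=1e-9)

    def test_constant_log_energy_gives_zero_non_dc(self, fb):
        spec = _spec_from_frames(np.zeros((3, 601)))
        feats = gfcc_frames(spec, fb, n_ceps=12, drop_c0=True)
        np.testing.assert_allclose(feats.vectors, 0.0, atol=1e-9)

    def test_gain_invariance_with_drop_c0(self, fb):
        rng = np.random.default_rng(1)
        clip = AudioClip(np.clip(rng.standard_normal(8000) * 0.1, -1, 1), 4000)
        s1 = stft_spectrogram(clip)
        s2 = Spectrogram(2 * s1.values, s1.times, s1.freqs, s1.frame_len, s1.hop)
        f1 = gfcc_frames(s1, fb, 12, drop_c0=True)
        f2 = gfcc_frames(s2, fb, 12, drop_c0=True)
        np.testing.assert_allclose(f1.vectors, f2.vectors, atol=1e-8)

    def test_grid_mismatch_rejected(self, fb):
        bad = _spec_from_frames(np.zeros((2, 301)), rate=4000.0, frame=0.15)
        with pytest.raises(ValueError, match="grid"):
            gfcc_frames(bad, fb)

    def test_finite_on_soundscape(self, fb, wind_rumble_scene):
        spec = stft_spectrogram(wind_rumble_scene.clip)
        feats = gfcc_frames(spec, fb)
        assert np.all(np.isfinite(feats.vectors))


class TestAggregateContext:
    def _seq(self, vectors):
        v = np.asarray(vectors, dtype=float)
        return FeatureSequence(v, np.arange(v.shape[0]) * 0.1)

    def test_constant_sequence(self):
        out = aggregate_context(self._seq(np.full((12, 3), 2.5)), window=4, hop=2)
        for cf in out:
            np.testing.assert_allclose(cf.vector[:3], 2.5)
            np.testing.assert_allclose(cf.vector[3:], 0.0)

    def test_single_window_when_window_equals_length(self):
        out = aggregate_context(self._seq(np.ones((6, 2))), window=6, hop=3)
        assert len(out) == 1

    def test_alternating_scalar_mean_zero_var_one(self):
        seq = self._seq(np.array([[1.0], [-1.0], [1.0], [-1.0]]))
        (cf,) = aggregate_context(seq, window=4, hop=4)
        assert cf.vector[0] == pytest.approx(0.0)
        assert cf.vector[1] == pytest.approx(1.0)  # population variance

    def test_variance_part_non_negative(self):
        rng = np.random.default_rng(2)
        out = aggregate_context(self._seq(rng.normal(size=(30, 5))), window=10, hop=5)
        for cf in out:
            assert np.all(cf.vector[5:] >= 0)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="window"):
            aggregate_context(self._seq(np.ones((3, 2))), window=10, hop=5)
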