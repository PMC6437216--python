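import numpy as np
import pytest
from scipy.signal import hilbert

from seizkit.recording import EEGRecording
from seizkit.spectral import (BAND_TABLE, BandDefinition,
                              DegenerateBaselineError, band_power,
                              compute_baseline_stats, compute_spectrogram,
                              wigner_transform, zscore_bands)

FS = 2000.0


def _tone(freq, dur=10.0, amp=1.0):
    t = np.arange(int(dur * FS)) / FS
    return amp * np.sin(2 * np.pi * freq * t)


class TestSpectrogram:
    def test_tone_power_concentrates_at_tone_frequency(self):
        spec = compute_spectrogram(_tone(100.0), FS)
        total = spec.power.sum()
        near = np.abs(spec.frequencies - 100.0) <= 2.0
        assert spec.power[:, near].sum() / total > 0.95

    def test_zero_signal_gives_zero_power(self):
        spec = compute_spectrogram(np.zeros(int(5 * FS)), FS)
        assert np.all(spec.power == 0)

    def test_parseval_white_noise(self, rng):
        x = rng.standard_normal(int(30 * FS))
        spec = compute_spectrogram(x, FS)
        summed = (spec.power.sum(axis=1) * spec.df).mean()
        assert summed == pytest.approx(np.mean(x ** 2), rel=0.02)

    def test_amplitude_scaling_is_quadratic(self, rng):
        x = rng.standard_normal(int(5 * FS))
        p1 = compute_spectrogram(x, FS).power
        p2 = compute_spectrogram(3.0 * x, FS).power
        assert np.allclose(p2, 9.0 * p1)

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            compute_spectrogram(np.zeros(100), FS, window_s=1.0)

    def test_step_cannot_exceed_window(self):
        with pytest.raises(ValueError):
            compute_spectrogram(np.zeros(int(5 * FS)), FS,
                                window_s=0.5, step_s=1.0)


class TestBandPower:
    def test_band_table_tiles_0_to_500(self):
        assert BAND_TABLE[0].f_low == 0.0
        assert BAND_TABLE[-1].f_high == 500.0
        for a, b in zip(BAND_TABLE[:-1], BAND_TABLE[1:]):
            assert a.f_high == b.f_low
        names = [b.name for b in BAND_TABLE]
        assert names == ["delta", "theta", "alpha", "beta", "gamma",
                         "ripple", "fast_ripple"]

    def test_tone_lands_in_ripple_not_delta(self):
        spec = compute_spectrogram(_tone(100.0), FS)
        ripple = band_power(spec, BAND_TABLE[5]).mean()
        delta = band_power(spec, BAND_TABLE[0]).mean()
        assert ripple > 1000 * delta

    def test_equal_tones_give_equal_band_means_per_hz(self):
        x = _tone(2.0) + _tone(150.0)
        spec = compute_spectrogram(x, FS)
        delta = band_power(spec, BandDefinition("d", 0, 4))
        ripple = band_power(spec, BandDefinition("r", 80, 250))
        # mean-over-bins normalizes per Hz: equal-amplitude tones in 4-Hz
        # vs 170-Hz bands differ by the bin-count ratio
        ratio = (delta.mean() * 4) / (ripple.mean() * 170)
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_empty_band_rejected(self):
        spec = compute_spectrogram(_tone(10.0), FS)
        with pytest.raises(ValueError, match="no frequency bins"):
            band_power(spec, BandDefinition("x", 1100.0, 1200.0))

    def test_invalid_band_edges_rejected(self):
        with pytest.raises(ValueError):
            BandDefinition("bad", 30.0, 10.0)


class TestZScoring:
    def test_baseline_self_normalizes(self, quiet_session, short_protocol):
        rec, _ = quiet_session
        spec = compute_spectrogram(rec)
        baseline = compute_baseline_stats(spec, short_protocol)
        zs = zscore_bands(spec, baseline)
        half = spec.window_s / 2
        keep = ((spec.window_centers - half >= 0)
                & (spec.window_centers + half
                   <= short_protocol.baseline_pre_s))
        for series in zs:
            assert abs(np.mean(series.z[keep])) < 0.15
            assert abs(np.std(series.z[keep], ddof=1) - 1) < 0.15

    def test_gain_invariance(self, quiet_session, short_protocol):
        rec, _ = quiet_session
        spec1 = compute_spectrogram(rec)
        scaled = EEGRecording(data=rec.data * 7.5, fs=rec.fs)
        spec2 = compute_spectrogram(scaled)
        z1 = zscore_bands(spec1,
                          compute_baseline_stats(spec1, short_protocol))
        z2 = zscore_bands(spec2,
                          compute_baseline_stats(spec2, short_protocol))
        for a, b in zip(z1, z2):
            assert np.allclose(a.z, b.z)

    def test_constant_power_raises_degenerate_baseline(self, short_protocol):
        rec = EEGRecording(data=np.zeros(int(short_protocol.total_s * FS)),
                           fs=FS)
        spec = compute_spectrogram(rec)
        with pytest.raises(DegenerateBaselineError):
            compute_baseline_stats(spec, short_protocol)

    def test_seizure_ripple_z_exceeds_3(self, seizure_session,
                                        short_protocol):
        rec, truth = seizure_session
        spec = compute_spectrogram(rec)
        baseline = compute_baseline_stats(spec, short_protocol)
        ripple = [z for z in zscore_bands(spec, baseline)
                  if z.band.name == "ripple"][0]
        a, b = truth.seizure_intervals[0]
        sel = (ripple.times >= a) & (ripple.times <= b)
        assert ripple.z[sel].max() > 3.0


class TestWigner:
    def test_tone_ridge_at_tone_frequency(self):
        x = _tone(100.0, dur=0.5)
        times, freqs, w = wigner_transform(x, FS, mode="plain")
        mid = w[w.shape[0] // 4: 3 * w.shape[0] // 4]
        ridge = freqs[np.argmax(mid, axis=1)]
        assert np.abs(ridge - 100.0).max() <= freqs[1] - freqs[0]

    def test_chirp_follows_linear_frequency_law(self):
        t = np.arange(int(0.5 * FS)) / FS
        f0, rate = 50.0, 400.0
        x = np.cos(2 * np.pi * (f0 * t + 0.5 * rate * t ** 2))
        times, freqs, w = wigner_transform(x, FS, mode="plain")
        df = freqs[1] - freqs[0]
        sel = slice(100, len(t) - 100)
        ridge = freqs[np.argmax(w[sel], axis=1)]
        law = f0 + rate * times[sel]
        assert np.median(np.abs(ridge - law)) <= df

    def test_plain_time_marginal_matches_instantaneous_power(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(400)
        _, _, w = wigner_transform(x, FS, mode="plain")
        inst = np.abs(hilbert(x)) ** 2
        marg = w.sum(axis=1)
        err = np.max(np.abs(marg - inst)) / inst.max()
        assert err < 0.01

    def test_smoothed_pseudo_attenuates_cross_terms(self):
        x = _tone(50.0, 0.4) + _tone(300.0, 0.4)
        _, freqs, w_plain = wigner_transform(x, FS, mode="plain")
        _, _, w_sp = wigner_transform(x, FS, mode="smoothed-pseudo")
        cross = np.abs(freqs - 175.0) < 20.0   # midpoint artifact region
        on = (np.abs(freqs - 50.0) < 10) | (np.abs(freqs - 300.0) < 10)
        rel_plain = np.abs(w_plain[:, cross]).max() / np.abs(
            w_plain[:, on]).max()
        rel_sp = np.abs(w_sp[:, cross]).max() / np.abs(w_sp[:, on]).max()
        assert rel_sp < rel_plain

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            wigner_transform(np.zeros(200), FS, mode="reassigned")

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="64"):
            wigner_transform(np.zeros(32), FS)
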