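import numpy as np
import pytest

from seizkit.protocol import StimProtocol
from seizkit.spectral import (BAND_TABLE, compute_baseline_stats,
                              compute_spectrogram, zscore_bands)
from seizkit.synth import (ConfigError, SimConfig, draw_session_truth,
                           generate_racine, iter_cohort_sessions,
                           pink_noise, simulate_cohort, simulate_session)


class TestConfig:
    def test_suppression_fraction_must_be_subunit(self):
        with pytest.raises(ConfigError):
            SimConfig(postictal_fraction=1.0)

    def test_sampling_rate_must_cover_fast_ripples(self):
        with pytest.raises(ConfigError, match="fast-ripple"):
            SimConfig(fs_hz=800.0)


class TestDeterminism:
    def test_identical_seed_and_session_bit_identical(self, short_protocol):
        cfg = SimConfig(seed=5)
        r1, t1 = simulate_session(cfg, short_protocol, 3, animal_index=2)
        r2, t2 = simulate_session(cfg, short_protocol, 3, animal_index=2)
        assert np.array_equal(r1.data, r2.data)
        assert t1.seizure_intervals == t2.seizure_intervals
        assert t1.racine_score == t2.racine_score

    def test_different_sessions_differ(self, short_protocol):
        cfg = SimConfig(seed=5)
        r1, _ = simulate_session(cfg, short_protocol, 3, animal_index=2)
        r2, _ = simulate_session(cfg, short_protocol, 4, animal_index=2)
        assert not np.array_equal(r1.data, r2.data)


class TestGroundTruth:
    def test_zero_probability_never_seizes(self, short_protocol):
        cfg = SimConfig(seed=1, seizure_prob_midpoint=1e9)
        for s in (1, 10, 30):
            _, truth = simulate_session(cfg, short_protocol, s)
            assert truth.seizure_intervals == []

    def test_recording_length_matches_protocol(self, short_protocol,
                                               default_cfg):
        rec, _ = simulate_session(default_cfg, short_protocol, 1)
        assert rec.n_samples == round(short_protocol.total_s
                                      * default_cfg.fs_hz)

    def test_intervals_inside_recording(self, short_protocol):
        cfg = SimConfig(seed=3)
        rng = np.random.default_rng(0)
        for s in range(10, 40, 3):
            truth = draw_session_truth(cfg, short_protocol, s, rng)
            for a, b in truth.seizure_intervals:
                assert short_protocol.induction_start_s <= a < b
                assert b <= short_protocol.total_s

    def test_seizure_frequency_grows_with_session(self, short_protocol):
        # Monte-Carlo over the logistic occurrence rule
        cfg = SimConfig(seed=11)
        rng = np.random.default_rng(1)
        hits = {1: 0, 25: 0}
        n = 200
        for s in hits:
            for _ in range(n):
                t = draw_session_truth(cfg, short_protocol, s, rng)
                hits[s] += bool(t.seizure_intervals)
        assert hits[25] > hits[1]
        assert hits[25] > 0.9 * n and hits[1] < 0.1 * n


class TestSeizureSpectralContent:
    def test_ripple_power_exceeds_background_during_hfo_phase(
            self, seizure_session, short_protocol):
        rec, truth = seizure_session
        spec = compute_spectrogram(rec)
        baseline = compute_baseline_stats(spec, short_protocol)
        ripple = [z for z in zscore_bands(spec, baseline)
                  if z.band.name == "ripple"][0]
        t_hfo = truth.hfo_peak_times[0]
        sel = np.abs(ripple.times - t_hfo) <= 1.0
        assert ripple.z[sel].max() > 3.0

    def test_no_spurious_suppression_when_fraction_zero(self, short_protocol):
        cfg = SimConfig(seed=21, postictal_fraction=0.0)
        rec, truth = simulate_session(cfg, short_protocol, 15)
        (a, b) = truth.seizure_intervals[0]
        x = rec.channel(0)
        fs = rec.fs
        pre = x[int((a - 61) * fs):int((a - 1) * fs)]
        post = x[int((b + 1) * fs):int((b + 61) * fs)]
        # same pink-noise process on both sides, modulo evoked pulses
        assert np.mean(post ** 2) == pytest.approx(np.mean(pre ** 2),
                                                   rel=0.35)


class TestRacine:
    def test_deterministic_formula(self):
        cfg = SimConfig(racine_intercept=2.0, racine_slope=0.0,
                        racine_noise_sd=0.0)
        rng = np.random.default_rng(0)
        assert all(generate_racine(cfg, s, False, rng) == 2.0
                   for s in (1, 10, 30))

    def test_scores_on_half_grid_and_clipped(self):
        cfg = SimConfig(racine_noise_sd=2.0)
        rng = np.random.default_rng(3)
        scores = [generate_racine(cfg, s, True, rng)
                  for s in range(1, 60)]
        assert all(0 <= v <= 6 and (2 * v) == int(2 * v) for v in scores)

    def test_cap_at_six(self):
        cfg = SimConfig(racine_intercept=1.0, racine_slope=0.2,
                        racine_noise_sd=0.0)
        rng = np.random.default_rng(0)
        assert generate_racine(cfg, 30, False, rng) == 6.0


class TestCohort:
    def test_control_groups_have_no_seizures(self, short_protocol):
        cfg = SimConfig(seed=9)
        for group in ("no-stim-ChR2", "stim-no-ChR2"):
            timeline, _ = simulate_cohort(cfg, 3, 20, group,
                                          protocol=short_protocol)
            assert not timeline["had_seizure"].any()

    def test_unknown_group_rejected(self, short_protocol):
        with pytest.raises(ConfigError, match="unknown group"):
            simulate_cohort(SimConfig(), 1, 1, "sham",
                            protocol=short_protocol)

    def test_single_session_manifest(self, short_protocol):
        _, manifest = simulate_cohort(SimConfig(), 1, 1, "stim-ChR2",
                                      protocol=short_protocol)
        assert len(manifest) == 1

    def test_majority_of_stimulated_animals_seize(self, short_protocol):
        timeline, _ = simulate_cohort(SimConfig(seed=4), 12, 25,
                                      "stim-ChR2", protocol=short_protocol)
        positive = timeline.groupby("animal_id")["had_seizure"].any()
        assert positive.sum() > 6

    def test_timeline_matches_synthesized_truth(self, short_protocol):
        # the cheap timeline draw and full synthesis share one rng stream
        cfg = SimConfig(seed=13)
        timeline, _ = simulate_cohort(cfg, 1, 16, "stim-ChR2",
                                      protocol=short_protocol)
        rows = {int(r.session): r for r in timeline.itertuples()}
        for aid, s, rec, truth in iter_cohort_sessions(
                cfg, 1, 16, "stim-ChR2", short_protocol):
            assert rows[s].had_seizure == bool(truth.seizure_intervals)
            if truth.seizure_intervals:
                assert rows[s].start_s == truth.seizure_intervals[0][0]


class TestPinkNoise:
    def test_spectral_slope_near_target(self, rng):
        fs, n = 2000.0, 2 ** 18
        x = pink_noise(n, fs, 1.0, 1.0, rng, hp_corner_hz=0.5)
        freqs = np.fft.rfftfreq(n, 1 / fs)
        psd = np.abs(np.fft.rfft(x)) ** 2
        sel_lo = (freqs > 2) & (freqs < 20)
        sel_hi = (freqs > 20) & (freqs < 200)
        ratio = psd[sel_lo].mean() / psd[sel_hi].mean()
        assert ratio > 3  # strongly red spectrum above the corner

    def test_rms_normalization(self, rng):
        x = pink_noise(2 ** 14, 2000.0, 3e-5, 1.0, rng)
        assert np.sqrt(np.mean(x ** 2)) == pytest.approx(3e-5, rel=1e-9)
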