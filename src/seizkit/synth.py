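"""Seeded synthetic kindling-EEG sessions and cohorts with ground truth.

The generator emulates the statistical structure a kindling analysis chain
assumes, without any biophysical modelling:

* background EEG = pink (1/f^alpha) noise at a configurable RMS;
* paired-pulse evoked deflections (alpha-function kernels) every 10 s during
  the two baseline periods, plus per-pulse responses during 50-Hz induction
  bouts;
* at most one electrographic seizure per session, whose occurrence
  probability follows a logistic curve in session number while onset latency
  shrinks and duration grows linearly with session number;
* seizure morphology = a ripple-band (80-250 Hz) noise burst whose Gaussian
  envelope peaks ``hfo_lead_s`` seconds *before* the envelope of a ~5-Hz
  spike-wave (sawtooth) phase, the whole event gated to its interval;
* broadband postictal suppression: background amplitude scaled by
  sqrt(1 - postictal_fraction) for ``postictal_dur_s`` after seizure end;
* a half-integer Racine-style behavioural score that grows linearly (plus
  noise) with session number, clipped to [0, 6].

Everything is driven by one integer seed; identical ``(seed, animal,
session)`` reproduces sessions bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import signal

from .protocol import StimProtocol, build_protocol
from .recording import EEGRecording

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ConfigError",
    "build_protocol",
    "pink_noise",
    "evoked_kernel",
    "simulate_session",
    "simulate_cohort",
    "iter_cohort_sessions",
    "draw_session_truth",
    "generate_racine",
    "COHORT_GROUPS",
]

COHORT_GROUPS = ("stim-ChR2", "no-stim-ChR2", "stim-no-ChR2")


class ConfigError(ValueError):
    """Raised for invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """All tunable generator parameters (SI units: volts, seconds, Hz)."""

    fs_hz: float = 2000.0
    # background: 1/f^alpha above the amplifier's AC-coupling corner;
    # a first-order high-pass below it (EEG rigs do not pass near-DC)
    noise_exponent: float = 1.0
    noise_rms: float = 50e-6
    noise_hp_corner_hz: float = 0.5
    # paired-pulse evoked responses
    evoked_amp1: float = 100e-6
    evoked_amp2: float = 120e-6
    evoked_latency_s: float = 0.008
    evoked_tau_s: float = 0.005
    # steady-state amplitude of per-pulse responses inside 50-Hz bouts,
    # relative to the isolated-pulse response: synaptic transmission
    # depresses strongly under sustained 50-Hz drive, so the tetanic
    # response settles well below the paired-pulse amplitude
    induction_evoked_scale: float = 0.3
    potentiation_factor2: float = 1.4
    a2_drift_per_session: float = 0.0
    # seizure occurrence: P(seizure | session s) = 1/(1+exp(-k (s - s0)))
    seizure_prob_midpoint: float = 10.0
    seizure_prob_slope: float = 2.0
    # onset latency from induction start: L0 + L1 * s (+ noise), clipped
    latency_intercept_s: float = 160.0
    latency_slope_s: float = -5.0
    latency_min_s: float = 5.0
    latency_noise_sd_s: float = 5.0
    # duration: d0 + d1 * s (+ noise), clipped
    duration_intercept_s: float = 5.0
    duration_slope_s: float = 1.0
    duration_min_s: float = 5.0
    duration_max_s: float = 120.0
    duration_noise_sd_s: float = 2.0
    # seizure morphology
    hfo_lead_s: float = 6.4
    seizure_hfo_amp: float = 250e-6
    seizure_sw_amp: float = 300e-6
    sw_freq_hz: float = 5.0
    # postictal suppression (power fraction) and its duration
    postictal_fraction: float = 0.34
    postictal_dur_s: float = 90.0
    # behavioural score: r0 + r1 * s (+ noise), rounded to halves, clipped 0..6
    racine_intercept: float = 0.5
    racine_slope: float = 0.18
    racine_noise_sd: float = 0.5
    racine_seizure_bonus: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.postictal_fraction < 1.0):
            raise ConfigError("postictal_fraction must be in [0, 1)")
        if self.hfo_lead_s < 0:
            raise ConfigError("hfo_lead_s must be >= 0")
        if self.fs_hz <= 2 * 500.0:
            raise ConfigError(
                "fs_hz must exceed 1000 Hz to carry fast-ripple content")
        if self.noise_rms <= 0:
            raise ConfigError("noise_rms must be positive")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """Per-session ground truth written by the generator."""

    seizure_intervals: list[tuple[float, float]] = field(default_factory=list)
    racine_score: float = 0.0
    pulse_amplitudes: pd.DataFrame | None = None  # columns: t_s, period, a1, a2
    postictal_intervals: list[tuple[float, float]] = field(default_factory=list)
    hfo_peak_times: list[float] = field(default_factory=list)
    sw_peak_times: list[float] = field(default_factory=list)
    latency_s: float | None = None

    def __post_init__(self) -> None:
        iv = sorted(self.seizure_intervals)
        for (a, b) in iv:
            if b <= a:
                raise ValueError("degenerate seizure interval")
        for (_, b), (c, _) in zip(iv[:-1], iv[1:]):
            if c < b:
                raise ValueError("overlapping seizure intervals")
        self.seizure_intervals = iv
        if round(self.racine_score * 2) != self.racine_score * 2:
            raise ValueError("racine_score must be a multiple of 0.5")


# ---------------------------------------------------------------------------
# primitives

def pink_noise(n: int, fs: float, rms: float, exponent: float,
               rng: np.random.Generator, hp_corner_hz: float = 0.5,
               ) -> np.ndarray:
    """1/f^exponent Gaussian noise normalized to ``rms``.

    A first-order high-pass at ``hp_corner_hz`` emulates the AC coupling of
    an EEG amplifier; without it the 1/f spectrum puts roughly half the
    power below 0.5 Hz, which no recording rig passes.
    """
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    if hp_corner_hz > 0:
        r = freqs[1:] / hp_corner_hz
        amp[1:] *= r / np.sqrt(1.0 + r ** 2)
    spec = amp * (rng.standard_normal(freqs.size)
                  + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spec, n)
    x *= rms / np.sqrt(np.mean(x ** 2))
    return x


def evoked_kernel(fs: float, tau_s: float = 0.005, latency_s: float = 0.008,
                  width_s: float = 0.060) -> np.ndarray:
    """Unit-peak alpha-function deflection with onset latency (negative-going)."""
    n_lat = int(round(latency_s * fs))
    t = np.arange(0.0, width_s, 1.0 / fs)
    k = (t / tau_s) * np.exp(1.0 - t / tau_s)
    return -np.concatenate([np.zeros(n_lat), k])


def _add_kernel(x: np.ndarray, fs: float, t0: float, kernel: np.ndarray,
                amp: float) -> None:
    i0 = int(round(t0 * fs))
    if i0 >= x.size:
        return
    i1 = min(i0 + kernel.size, x.size)
    x[i0:i1] += amp * kernel[: i1 - i0]


def _gauss(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _seizure_waveform(n: int, fs: float, t0: float, t1: float,
                      hfo_peak: float, sw_peak: float, cfg: SimConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Additive seizure signal, exactly zero outside [t0, t1]."""
    i0, i1 = int(round(t0 * fs)), min(int(round(t1 * fs)), n)
    m = i1 - i0
    t = (np.arange(m) + i0) / fs
    dur = t1 - t0
    # tonic-plus-phasic envelopes: a low sustained plateau keeps the whole
    # event electrographically active (abrupt onset/offset through the
    # gate), while the phasic Gaussian bumps place the ripple peak early
    # and the spike-wave peak late, separated by the programmed lead
    sigma_h = min(2.0, dur / 6.0)
    sigma_sw = min(2.5, dur / 6.0)
    env_h = 0.25 + 0.75 * _gauss(t, hfo_peak, sigma_h)
    env_sw = 0.35 + 0.65 * _gauss(t, sw_peak, sigma_sw)
    sos = signal.butter(4, [80.0, 250.0], btype="bandpass", fs=fs, output="sos")
    hfo = signal.sosfiltfilt(sos, rng.standard_normal(m))
    hfo /= np.sqrt(np.mean(hfo ** 2))
    sw = signal.sawtooth(2.0 * np.pi * cfg.sw_freq_hz * (t - t0), width=0.9)
    seg = (cfg.seizure_hfo_amp * env_h * hfo
           + cfg.seizure_sw_amp * env_sw * sw)
    seg *= signal.windows.tukey(m, alpha=min(0.2, 2.0 / max(dur, 1.0)))
    out = np.zeros(n)
    out[i0:i1] = seg
    return out


# ---------------------------------------------------------------------------
# session-level truth (cheap, no sample synthesis)

def _seizure_probability(cfg: SimConfig, session_index: int) -> float:
    from scipy.special import expit
    z = cfg.seizure_prob_slope * (session_index - cfg.seizure_prob_midpoint)
    return float(np.clip(expit(z), 0.0, 1.0))


def generate_racine(cfg: SimConfig, session_index: int, had_seizure: bool,
                    rng: np.random.Generator) -> float:
    """Half-integer behavioural severity score in [0, 6].

    Score = clip(round-to-half(r0 + r1*session + noise [+ bonus]), 0, 6);
    the optional bonus applies only to seizure sessions.
    """
    if session_index < 1:
        raise ValueError("session_index must be >= 1")
    raw = (cfg.racine_intercept + cfg.racine_slope * session_index
           + (rng.normal(0.0, cfg.racine_noise_sd) if cfg.racine_noise_sd > 0
              else 0.0))
    if had_seizure:
        raw += cfg.racine_seizure_bonus
    return float(np.clip(np.round(raw * 2.0) / 2.0, 0.0, 6.0))


def draw_session_truth(cfg: SimConfig, protocol: StimProtocol,
                       session_index: int, rng: np.random.Generator,
                       seizures_enabled: bool = True) -> GroundTruth:
    """Draw the ground-truth event structure of one session.

    Consumes a fixed number of draws from ``rng`` regardless of outcome so
    that downstream draws stay aligned across conditions.
    """
    if session_index < 1:
        raise ValueError("session_index must be >= 1")
    u = rng.random()
    lat_noise = rng.normal(0.0, 1.0)
    dur_noise = rng.normal(0.0, 1.0)
    p = _seizure_probability(cfg, session_index) if seizures_enabled else 0.0
    truth = GroundTruth()
    if u < p:
        s = session_index
        duration = float(np.clip(
            cfg.duration_intercept_s + cfg.duration_slope_s * s
            + cfg.duration_noise_sd_s * dur_noise,
            cfg.duration_min_s, cfg.duration_max_s))
        post_room = protocol.induction_s + protocol.baseline_post_s
        lat_hi = max(cfg.latency_min_s, post_room - duration - 2.0)
        latency = float(np.clip(
            cfg.latency_intercept_s + cfg.latency_slope_s * s
            + cfg.latency_noise_sd_s * lat_noise,
            cfg.latency_min_s, lat_hi))
        t0 = protocol.induction_start_s + latency
        t1 = min(t0 + duration, protocol.total_s - 1.0)
        duration = t1 - t0
        # envelope peaks: the ripple burst sits near onset and leads the
        # spike-wave peak by hfo_lead_s
        tau = min(cfg.hfo_lead_s, max(duration - 2.0, 0.0))
        hfo_peak = t0 + min(2.5, max(1.0, 0.1 * duration))
        sw_peak = min(hfo_peak + tau, t1 - 1.0)
        hfo_peak = sw_peak - tau
        truth.seizure_intervals = [(t0, t1)]
        truth.latency_s = latency
        truth.hfo_peak_times = [hfo_peak]
        truth.sw_peak_times = [sw_peak]
        truth.postictal_intervals = [
            (t1, min(t1 + cfg.postictal_dur_s, protocol.total_s))]
    truth.racine_score = generate_racine(
        cfg, session_index, bool(truth.seizure_intervals), rng)
    return truth


# ---------------------------------------------------------------------------
# full synthesis

def _session_rng(cfg: SimConfig, animal_index: int,
                 session_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=cfg.seed,
                                spawn_key=(animal_index, session_index))
    return np.random.default_rng(ss)


def simulate_session(cfg: SimConfig, protocol: StimProtocol,
                     session_index: int, *, animal_index: int = 0,
                     with_evoked: bool = True, with_induction: bool = True,
                     seizures_enabled: bool = True,
                     clock_h: float | None = None,
                     ) -> tuple[EEGRecording, GroundTruth]:
    """Synthesize one annotated session.

    The rng is derived deterministically from ``(cfg.seed, animal_index,
    session_index)``: identical inputs give bit-identical output.
    """
    rng = _session_rng(cfg, animal_index, session_index)
    truth = draw_session_truth(cfg, protocol, session_index, rng,
                               seizures_enabled=seizures_enabled
                               and with_induction)
    fs = cfg.fs_hz
    n = int(round(protocol.total_s * fs))
    x = pink_noise(n, fs, cfg.noise_rms, cfg.noise_exponent, rng,
                   cfg.noise_hp_corner_hz)

    # postictal suppression of the background
    for (a, b) in truth.postictal_intervals:
        i0, i1 = int(round(a * fs)), min(int(round(b * fs)), n)
        x[i0:i1] *= np.sqrt(1.0 - cfg.postictal_fraction)

    kern = evoked_kernel(fs, cfg.evoked_tau_s, cfg.evoked_latency_s)
    pulse_rows = []
    if with_evoked:
        drift = 1.0 + cfg.a2_drift_per_session * (session_index - 1)
        a2_base = cfg.evoked_amp2 * drift
        for period in ("pre", "post"):
            a1 = cfg.evoked_amp1
            a2 = a2_base
            if period == "post" and with_induction:
                a2 *= cfg.potentiation_factor2
            for t in protocol.pulse_pair_times(period):
                _add_kernel(x, fs, t, kern, a1)
                _add_kernel(x, fs, t + protocol.pp_ipi_s, kern, a2)
                pulse_rows.append((t, period, a1, a2))
        if with_induction and cfg.induction_evoked_scale > 0:
            amp = cfg.evoked_amp1 * cfg.induction_evoked_scale
            for t in protocol.induction_pulse_times():
                _add_kernel(x, fs, t, kern, amp)

    for (t0, t1), hp, sp in zip(truth.seizure_intervals,
                                truth.hfo_peak_times, truth.sw_peak_times):
        x += _seizure_waveform(n, fs, t0, t1, hp, sp, cfg, rng)

    truth.pulse_amplitudes = pd.DataFrame(
        pulse_rows, columns=["t_s", "period", "a1", "a2"])
    if clock_h is None:
        clock_h = float(rng.uniform(0.0, 24.0))
    annotations = {
        "pp_pulse": protocol.pulse_pair_times("all") if with_evoked
        else np.empty(0),
        "bout": protocol.bout_onsets() if with_induction else np.empty(0),
    }
    rec = EEGRecording(data=x, fs=fs, channels=["EEG1"],
                       annotations=annotations, start_clock_h=clock_h)
    return rec, truth


def _group_flags(group: str) -> dict[str, bool]:
    if group not in COHORT_GROUPS:
        raise ConfigError(f"unknown group {group!r}; expected one of "
                          f"{COHORT_GROUPS}")
    return {
        "with_evoked": group != "stim-no-ChR2",
        "with_induction": group != "no-stim-ChR2",
        "seizures_enabled": group == "stim-ChR2",
    }


def iter_cohort_sessions(cfg: SimConfig, n_animals: int, n_sessions: int,
                         group: str = "stim-ChR2",
                         protocol: StimProtocol | None = None,
                         ) -> Iterator[tuple[str, int, EEGRecording, GroundTruth]]:
    """Yield ``(animal_id, session, recording, truth)`` one at a time.

    Streaming access for cohort-scale analyses that must not hold every
    recording in memory.
    """
    protocol = protocol or StimProtocol()
    flags = _group_flags(group)
    for a in range(n_animals):
        animal_id = f"{group}-a{a + 1:02d}"
        for s in range(1, n_sessions + 1):
            rec, truth = simulate_session(cfg, protocol, s, animal_index=a,
                                          **flags)
            yield animal_id, s, rec, truth


def simulate_cohort(cfg: SimConfig, n_animals: int, n_sessions: int,
                    group: str = "stim-ChR2",
                    protocol: StimProtocol | None = None,
                    out_dir=None, synthesize: bool = False,
                    ) -> tuple[pd.DataFrame, list[dict]]:
    """Simulate a cohort timeline and a recordings manifest.

    By default only the (cheap) ground-truth timeline is drawn; full sample
    synthesis happens when ``synthesize`` is set or ``out_dir`` is given, in
    which case each session is written as an HDF5 bundle under ``out_dir``.

    Returns ``(timeline, manifest)`` where ``timeline`` has one row per
    (animal, session) and ``manifest`` one entry per recording.
    """
    if n_animals < 1 or n_sessions < 1:
        raise ConfigError("n_animals and n_sessions must be >= 1")
    protocol = protocol or StimProtocol()
    flags = _group_flags(group)
    rows, manifest = [], []
    write = out_dir is not None
    if write:
        from . import io as _io
        import os
        os.makedirs(out_dir, exist_ok=True)
    for a in range(n_animals):
        animal_id = f"{group}-a{a + 1:02d}"
        for s in range(1, n_sessions + 1):
            if synthesize or write:
                rec, truth = simulate_session(cfg, protocol, s,
                                              animal_index=a, **flags)
                clock_h = rec.start_clock_h
            else:
                rng = _session_rng(cfg, a, s)
                truth = draw_session_truth(
                    cfg, protocol, s, rng,
                    seizures_enabled=flags["seizures_enabled"]
                    and flags["with_induction"])
                clock_h = float(rng.uniform(0.0, 24.0))
            had = bool(truth.seizure_intervals)
            t0, t1 = (truth.seizure_intervals[0] if had else (np.nan, np.nan))
            rows.append({
                "animal_id": animal_id, "group": group, "session": s,
                "clock_h": clock_h, "had_seizure": had,
                "start_s": t0, "end_s": t1,
                "duration_s": (t1 - t0) if had else np.nan,
                "latency_s": truth.latency_s if had else np.nan,
                "racine": truth.racine_score,
            })
            entry = {"animal_id": animal_id, "group": group, "session": s,
                     "clock_h": clock_h, "racine": truth.racine_score,
                     "recording_path": None}
            if write:
                import os
                path = os.path.join(out_dir, f"{animal_id}_s{s:03d}.h5")
                _io.save_recording(rec, path)
                entry["recording_path"] = path
            manifest.append(entry)
    return pd.DataFrame(rows), manifest
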