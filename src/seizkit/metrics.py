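"""Per-seizure and per-session metrics: onset latency, duration, ripple-vs-
spike-wave peak lag, and postictal broadband suppression."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import SeizureEvent
from .protocol import StimProtocol
from .recording import EEGRecording
from .spectral import (ONSET_HIGH_BAND, ONSET_LOW_BAND, BandDefinition,
                       band_power, compute_spectrogram)

__all__ = ["SessionMetrics", "seizure_latency", "band_peak_lag",
           "postictal_depression", "session_metrics", "cohort_metrics_table"]


@dataclass
class SessionMetrics:
    n_seizures: int
    durations_s: list[float] = field(default_factory=list)
    latency_s: float | None = None
    peak_lag_s: list[float] = field(default_factory=list)
    postictal_fraction: list[float] = field(default_factory=list)
    racine: float | None = None

    def to_dict(self) -> dict:
        return {
            "n_seizures": self.n_seizures,
            "durations_s": list(self.durations_s),
            "latency_s": self.latency_s,
            "peak_lag_s": list(self.peak_lag_s),
            "postictal_fraction": list(self.postictal_fraction),
            "racine": self.racine,
        }


def seizure_latency(event: SeizureEvent, protocol: StimProtocol) -> float:
    """Seconds from induction start to seizure onset (the seizure-threshold
    proxy).  Events starting before induction are flagged, not rejected."""
    latency = event.start_s - protocol.induction_start_s
    if latency < 0:
        warnings.warn("event starts before induction onset "
                      "(no spontaneous seizures are expected)", stacklevel=2)
    return float(latency)


def _smoothed(x: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return x
    kernel = np.ones(n) / n
    return np.convolve(x, kernel, mode="same")


def band_peak_lag(recording: EEGRecording, event: SeizureEvent, *,
                  low_band: BandDefinition = ONSET_LOW_BAND,
                  high_band: BandDefinition = ONSET_HIGH_BAND,
                  smooth_s: float = 1.0, pad_s: float = 5.0,
                  window_s: float = 1.0, step_s: float = 0.25,
                  channel: int = 0) -> float:
    """t_peak(low band) - t_peak(high band) inside the padded event window.

    Positive values mean the high-frequency (ripple) envelope peaked first.
    Peaks are argmaxes of the smoothed band-power traces; since z-scoring a
    band is an affine map, peaks of power and of z coincide.
    """
    t0 = max(0.0, event.start_s - pad_s)
    t1 = min(recording.duration_s, event.end_s + pad_s)
    fs = recording.fs
    seg = recording.channel(channel)[int(round(t0 * fs)):int(round(t1 * fs))]
    spec = compute_spectrogram(seg, fs, window_s=window_s, step_s=step_s)
    n_smooth = max(1, int(round(smooth_s / step_s)))
    lags = {}
    for key, band in (("low", low_band), ("high", high_band)):
        p = _smoothed(band_power(spec, band), n_smooth)
        peak = p.max()
        ties = np.flatnonzero(p >= peak * (1 - 1e-9))
        if ties.size > 1 and (ties[-1] - ties[0]) > n_smooth:
            warnings.warn(f"flat {key}-band power trace; tie broken to the "
                          "earliest peak", stacklevel=2)
        lags[key] = _refined_peak_time(spec.window_centers, p, ties[0]) + t0
    return float(lags["low"] - lags["high"])


def _refined_peak_time(times: np.ndarray, p: np.ndarray, k: int) -> float:
    """Half-maximum centroid around the argmax: the peak time is the
    power-weighted centroid of the contiguous region above half the peak,
    which is far less jittery than the raw argmax for noisy envelopes and
    unbiased when the envelope is symmetric."""
    thr = 0.5 * p[k]
    i = k
    while i > 0 and p[i - 1] >= thr:
        i -= 1
    j = k
    while j + 1 < p.size and p[j + 1] >= thr:
        j += 1
    w = p[i:j + 1] - thr
    return float(np.sum(times[i:j + 1] * w) / np.sum(w))


def _mean_power(recording: EEGRecording, a: float, b: float,
                excise: list[tuple[float, float]], *, f_max: float = 500.0,
                channel: int = 0) -> float:
    """Mean broadband (0..f_max Hz) power over [a, b], excising stimulus
    windows."""
    fs = recording.fs
    a, b = max(a, 0.0), min(b, recording.duration_s)
    if b - a < 1.0:
        raise ValueError("power window shorter than one second")
    seg = recording.channel(channel)[int(round(a * fs)):int(round(b * fs))]
    spec = compute_spectrogram(seg, fs, window_s=1.0, step_s=1.0)
    centers = spec.window_centers + a
    keep = np.ones(centers.size, dtype=bool)
    for (u, v) in excise:
        keep &= (centers + 0.5 <= u) | (centers - 0.5 >= v)
    if not keep.any():
        raise ValueError("no unexcised windows in power interval")
    broad = BandDefinition("broadband", 0.0, f_max)
    return float(band_power(spec, broad)[keep].mean())


def postictal_depression(recording: EEGRecording, event: SeizureEvent,
                         protocol: StimProtocol, *, pre_window_s: float = 60.0,
                         post_window_s: float = 60.0, gap_s: float = 1.0,
                         excise_s: float = 0.2, channel: int = 0) -> float:
    """1 - (postictal broadband power / preictal broadband power).

    Positive fractions mean the EEG is suppressed after the seizure; the
    value is bounded above by 1.  Stimulus-evoked windows are excised from
    both sides.
    """
    excise = [(t, t + excise_s) for t in protocol.all_stimulus_times()]
    pre = _mean_power(recording, event.start_s - gap_s - pre_window_s,
                      event.start_s - gap_s, excise, channel=channel)
    if pre <= 0:
        raise ValueError("preictal power is zero; fraction undefined")
    post = _mean_power(recording, event.end_s + gap_s,
                       event.end_s + gap_s + post_window_s, excise,
                       channel=channel)
    return float(1.0 - post / pre)


def session_metrics(events: list[SeizureEvent], recording: EEGRecording,
                    protocol: StimProtocol, racine: float | None = None,
                    *, compute_lags: bool = True,
                    compute_postictal: bool = True) -> SessionMetrics:
    """Aggregate per-session quantities from detected events."""
    m = SessionMetrics(n_seizures=len(events), racine=racine)
    if not events:
        return m
    m.durations_s = [e.duration_s for e in events]
    m.latency_s = seizure_latency(events[0], protocol)
    for e in events:
        if compute_lags:
            try:
                m.peak_lag_s.append(band_peak_lag(recording, e))
            except ValueError:
                m.peak_lag_s.append(float("nan"))
        if compute_postictal:
            try:
                m.postictal_fraction.append(
                    postictal_depression(recording, e, protocol))
            except ValueError:
                m.postictal_fraction.append(float("nan"))
    return m


def cohort_metrics_table(rows: list[dict]) -> pd.DataFrame:
    """Long-form cohort table (one row per animal-session) from dicts
    containing animal_id, session plus a SessionMetrics."""
    out = []
    for r in rows:
        m: SessionMetrics = r["metrics"]
        out.append({
            "animal_id": r["animal_id"],
            "session": r["session"],
            "n_seizures": m.n_seizures,
            "latency_s": m.latency_s if m.latency_s is not None else np.nan,
            "mean_duration_s": (float(np.mean(m.durations_s))
                                if m.durations_s else np.nan),
            "mean_peak_lag_s": (float(np.nanmean(m.peak_lag_s))
                                if m.peak_lag_s else np.nan),
            "mean_postictal_fraction": (float(np.nanmean(m.postictal_fraction))
                                        if m.postictal_fraction else np.nan),
            "racine": m.racine,
        })
    return pd.DataFrame(out)
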