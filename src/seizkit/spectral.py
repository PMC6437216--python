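"""Windowed spectral power, band aggregation, baseline z-scoring, and
Wigner-Ville time-frequency transforms.

Power convention: each analysis window contributes a one-sided power
spectral density normalized so that summing ``power * df`` over frequency
returns the mean square (volts^2) of the tapered window — i.e. Parseval
holds per window up to taper leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import signal

from .protocol import StimProtocol
from .recording import EEGRecording

__all__ = [
    "BandDefinition", "Spectrogram", "BaselineStats", "BandZSeries",
    "BAND_TABLE", "ONSET_LOW_BAND", "ONSET_HIGH_BAND",
    "compute_spectrogram", "band_power", "compute_baseline_stats",
    "zscore_bands", "wigner_transform", "DegenerateBaselineError",
]


class DegenerateBaselineError(ValueError):
    """Baseline variance is zero for a band used in z-scoring."""


@dataclass(frozen=True)
class BandDefinition:
    """Half-open frequency band [f_low, f_high), Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_low < self.f_high):
            raise ValueError("require 0 <= f_low < f_high")


#: The canonical seven-band EEG partition tiling [0, 500) Hz.
BAND_TABLE: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("gamma", 30.0, 80.0),
    BandDefinition("ripple", 80.0, 250.0),
    BandDefinition("fast_ripple", 250.0, 500.0),
)

#: Bands used for seizure-onset dynamics: some workers label 4-8 Hz "delta"
#: in onset figures; the spike-wave fundamental (~5 Hz) lives there.
ONSET_LOW_BAND = BandDefinition("delta_fig", 4.0, 8.0)
ONSET_HIGH_BAND = BandDefinition("ripple", 80.0, 250.0)


@dataclass
class Spectrogram:
    window_centers: np.ndarray  # seconds
    frequencies: np.ndarray     # Hz
    power: np.ndarray           # (n_times, n_freqs), V^2/Hz
    window_s: float
    step_s: float
    taper: str

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


@dataclass
class BaselineStats:
    bands: tuple[BandDefinition, ...]
    mean: np.ndarray   # per band; V^2/Hz, or log10 thereof
    sd: np.ndarray     # per band
    interval_s: tuple[float, float]
    excised: list[tuple[float, float]]
    transform: str = "log"   # "log" | "linear" power scale for z-scoring


@dataclass
class BandZSeries:
    band: BandDefinition
    times: np.ndarray
    z: np.ndarray


def _as_samples(x, fs=None, channel: int = 0) -> tuple[np.ndarray, float]:
    if isinstance(x, EEGRecording):
        return x.channel(channel), x.fs
    if fs is None:
        raise ValueError("fs must be given for a plain array")
    return np.asarray(x, dtype=float), float(fs)


def compute_spectrogram(recording, fs: float | None = None, *,
                        window_s: float = 1.0, step_s: float = 0.25,
                        taper: str = "hann", channel: int = 0) -> Spectrogram:
    """Short-time power spectrum over sliding windows.

    ``recording`` may be an :class:`EEGRecording` or a plain array with
    ``fs``.  Returns one-sided PSD (V^2/Hz) per window.
    """
    x, fs = _as_samples(recording, fs, channel)
    nper = int(round(window_s * fs))
    if nper < 2:
        raise ValueError("window too short: need >= 2 samples")
    if step_s > window_s:
        raise ValueError("step_s must not exceed window_s")
    if x.size < nper:
        raise ValueError("recording shorter than one analysis window")
    step = int(round(step_s * fs))
    win = signal.get_window(taper, nper)
    freqs, t, sxx = signal.spectrogram(
        x, fs=fs, window=win, nperseg=nper, noverlap=nper - step,
        detrend=False, scaling="density", mode="psd")
    return Spectrogram(window_centers=t, frequencies=freqs, power=sxx.T,
                       window_s=window_s, step_s=step_s, taper=taper)


def _band_bins(spec: Spectrogram, band: BandDefinition) -> np.ndarray:
    sel = (spec.frequencies >= band.f_low) & (spec.frequencies < band.f_high)
    if not sel.any():
        raise ValueError(f"band {band.name} contains no frequency bins")
    return sel


def band_power(spec: Spectrogram, band: BandDefinition) -> np.ndarray:
    """Mean PSD over the band's bins at each window (mean, not sum, so
    z-scores are comparable across unequal band widths)."""
    return spec.power[:, _band_bins(spec, band)].mean(axis=1)


def _excision_intervals(protocol: StimProtocol,
                        excise_s: float) -> list[tuple[float, float]]:
    return [(t, t + excise_s) for t in protocol.all_stimulus_times()]


def _window_mask(spec: Spectrogram,
                 intervals: Iterable[tuple[float, float]]) -> np.ndarray:
    """True for windows whose support overlaps none of ``intervals``."""
    half = spec.window_s / 2.0
    lo = spec.window_centers - half
    hi = spec.window_centers + half
    keep = np.ones(spec.window_centers.size, dtype=bool)
    for (a, b) in intervals:
        keep &= (hi <= a) | (lo >= b)
    return keep


def _apply_transform(p: np.ndarray, transform: str) -> np.ndarray:
    if transform == "log":
        return np.log10(np.maximum(p, 1e-300))
    if transform == "linear":
        return p
    raise ValueError("transform must be 'log' or 'linear'")


def compute_baseline_stats(spec: Spectrogram, protocol: StimProtocol,
                           bands: Sequence[BandDefinition] = BAND_TABLE, *,
                           excise_s: float = 0.2,
                           transform: str = "log") -> BaselineStats:
    """Per-band mean/SD of band power over the pre-induction baseline.

    Windows overlapping the 200 ms after any stimulus pulse are excised so
    evoked deflections do not inflate the baseline statistics.  With the
    default ``transform="log"`` statistics are taken on log10 band power,
    whose baseline distribution is close to Gaussian (raw band power is
    right-skewed, which makes linear z-scores heavy-tailed); z-scores are
    then exactly invariant to recording gain.
    """
    if protocol.baseline_pre_s < 2 * spec.window_s:
        raise ValueError("no usable pre-induction baseline interval")
    intervals = [iv for iv in _excision_intervals(protocol, excise_s)
                 if iv[0] < protocol.baseline_pre_s]
    keep = _window_mask(spec, intervals)
    half = spec.window_s / 2.0
    keep &= (spec.window_centers - half >= 0)
    keep &= (spec.window_centers + half <= protocol.baseline_pre_s)
    if keep.sum() < 10:
        raise ValueError("baseline interval leaves too few windows")
    mu, sd = [], []
    for band in bands:
        p = _apply_transform(band_power(spec, band)[keep], transform)
        mu.append(p.mean())
        sd.append(p.std(ddof=1))
    mu, sd = np.asarray(mu), np.asarray(sd)
    if np.any(sd <= 0):
        raise DegenerateBaselineError("zero baseline variance in some band")
    return BaselineStats(bands=tuple(bands), mean=mu, sd=sd,
                         interval_s=(0.0, protocol.baseline_pre_s),
                         excised=intervals, transform=transform)


def zscore_bands(spec: Spectrogram, baseline: BaselineStats,
                 ) -> list[BandZSeries]:
    """z(t) = (P_b(t) - mu_b) / sigma_b on the baseline's power scale."""
    out = []
    for band, mu, sd in zip(baseline.bands, baseline.mean, baseline.sd):
        if sd <= 0:
            raise DegenerateBaselineError(f"sigma = 0 for band {band.name}")
        p = _apply_transform(band_power(spec, band), baseline.transform)
        z = (p - mu) / sd
        out.append(BandZSeries(band=band, times=spec.window_centers, z=z))
    return out


# ---------------------------------------------------------------------------
# Wigner-Ville

def wigner_transform(segment, fs: float, mode: str = "smoothed-pseudo", *,
                     max_lag: int | None = None, time_sigma_s: float = 0.05,
                     lag_sigma_s: float = 0.05) -> tuple[np.ndarray,
                                                         np.ndarray,
                                                         np.ndarray]:
    """Discrete Wigner-Ville distribution of a real segment.

    Returns ``(times, frequencies, W)`` with ``W`` of shape (n, n_freq).
    ``mode="plain"`` satisfies the time marginal exactly: summing W over
    frequency returns |analytic signal|^2 at each instant.
    ``mode="smoothed-pseudo"`` applies independent Gaussian smoothing in
    time and lag, attenuating cross terms at the cost of exact marginals.
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 64:
        raise ValueError("segment must contain at least 64 samples")
    if mode not in ("plain", "smoothed-pseudo"):
        raise ValueError(f"unknown Wigner mode {mode!r}")
    z = signal.hilbert(x)
    n = z.size
    m_max = max_lag if max_lag is not None else min(256, (n - 1) // 2)
    lags = np.arange(-m_max, m_max + 1)
    # instantaneous autocorrelation K[t, m] = z[t+m] z*[t-m]
    idx = np.arange(n)
    ip = np.clip(idx[:, None] + lags[None, :], 0, n - 1)
    im = np.clip(idx[:, None] - lags[None, :], 0, n - 1)
    valid = ((idx[:, None] + lags[None, :] >= 0)
             & (idx[:, None] + lags[None, :] < n)
             & (idx[:, None] - lags[None, :] >= 0)
             & (idx[:, None] - lags[None, :] < n))
    K = np.where(valid, z[ip] * np.conj(z[im]), 0.0)
    if mode == "smoothed-pseudo":
        g = np.exp(-0.5 * (lags / (lag_sigma_s * fs)) ** 2)
        K = K * g[None, :]
        ts = max(1.0, time_sigma_s * fs)
        kt = np.exp(-0.5 * (np.arange(-int(3 * ts), int(3 * ts) + 1) / ts) ** 2)
        kt /= kt.sum()
        K = np.apply_along_axis(
            lambda c: np.convolve(c, kt, mode="same"), 0, K)
    nf = 2 * m_max + 1
    # frequency axis: lag step of 1 sample at double angle -> f_k = k fs / (2 nf)
    phase = np.exp(-2j * np.pi * np.outer(lags, np.arange(nf)) / nf)
    W = (K @ phase).real / nf
    freqs = np.arange(nf) * fs / (2.0 * nf)
    half = freqs <= fs / 2.0
    times = idx / fs
    return times, freqs[half], W[:, half]
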