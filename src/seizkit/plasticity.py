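"""Paired-pulse evoked EEG responses and their plasticity.

Each baseline period delivers pairs of laser pulses ~33.3 ms apart every
10 s.  Trials are epoched at the first pulse, locally baseline-subtracted,
and averaged; response amplitudes are the peak absolute deflection in a
(3, 30) ms window after each pulse.  Within-session plasticity is the
post/pre ratio of each response; cross-session series are normalized to the
mean of the first two sessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import StimProtocol
from .recording import EEGRecording

__all__ = ["EvokedPair", "PlasticityResult", "extract_evoked",
           "session_plasticity", "cross_session_normalize"]

_AMP_WIN = (0.003, 0.030)       # amplitude search window after pulse onset
_EPOCH = (-0.050, 0.100)        # epoch bounds around the first pulse
_BASELINE_S = 0.050             # pre-pulse interval for local baseline


@dataclass
class EvokedPair:
    times: np.ndarray           # seconds relative to first pulse
    trace: np.ndarray           # averaged, baseline-subtracted, volts
    sem: np.ndarray
    a1: float                   # first-response amplitude, volts
    a2: float                   # second-response amplitude, volts
    n_trials: int
    period: str                 # "pre" | "post"


@dataclass
class PlasticityResult:
    r1: float                   # A1_post / A1_pre
    r2: float                   # A2_post / A2_pre


def _peak_amp(times: np.ndarray, trace: np.ndarray, onset: float) -> float:
    sel = (times >= onset + _AMP_WIN[0]) & (times <= onset + _AMP_WIN[1])
    return float(np.max(np.abs(trace[sel])))


def extract_evoked(recording: EEGRecording, protocol: StimProtocol,
                   period: str, *,
                   exclude_intervals: list[tuple[float, float]] | None = None,
                   subtract_first_kernel: bool = False,
                   channel: int = 0) -> EvokedPair:
    """Average paired-pulse trials of one baseline period.

    ``exclude_intervals`` (e.g. detected seizures plus a postictal guard)
    removes any trial whose epoch overlaps them.  With
    ``subtract_first_kernel`` the average first response, extrapolated with
    an alpha-function decay, is subtracted before measuring the second
    response (the 30-Hz pairing makes the two windows nearly abut).
    """
    if period not in ("pre", "post"):
        raise ValueError("period must be 'pre' or 'post'")
    exclude_intervals = exclude_intervals or []
    fs = recording.fs
    x = recording.channel(channel)
    i_lo = int(round(_EPOCH[0] * fs))
    i_hi = int(round(_EPOCH[1] * fs))
    epochs = []
    for t in protocol.pulse_pair_times(period):
        if any(t + _EPOCH[0] < b and a < t + _EPOCH[1]
               for a, b in exclude_intervals):
            continue
        i0 = int(round(t * fs))
        if i0 + i_lo < 0 or i0 + i_hi > x.size:
            continue
        ep = x[i0 + i_lo: i0 + i_hi].copy()
        ep -= ep[: -i_lo].mean()           # mean of the 50 ms before pulse
        epochs.append(ep)
    if not epochs:
        raise ValueError(f"no usable paired-pulse trials in period {period!r}")
    arr = np.asarray(epochs)
    mean = arr.mean(axis=0)
    sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]) if arr.shape[0] > 1 \
        else np.zeros_like(mean)
    times = (np.arange(i_lo, i_hi)) / fs
    a1 = _peak_amp(times, mean, 0.0)
    trace2 = mean
    if subtract_first_kernel:
        trace2 = mean - _first_response_model(times, mean)
    a2 = _peak_amp(times, trace2, protocol.pp_ipi_s)
    return EvokedPair(times=times, trace=mean, sem=sem, a1=a1, a2=a2,
                      n_trials=arr.shape[0], period=period)


def _first_response_model(times: np.ndarray, trace: np.ndarray,
                          tau_s: float = 0.005) -> np.ndarray:
    """Least-squares alpha-kernel fit to the first response, for removing
    its residual tail from the second-response window."""
    sel_fit = (times >= 0.0) & (times <= 0.025)
    t_pk = times[sel_fit][np.argmax(np.abs(trace[sel_fit]))]
    onset = t_pk - tau_s
    tt = np.clip(times - onset, 0.0, None)
    shape = (tt / tau_s) * np.exp(1.0 - tt / tau_s)
    scale = float(trace[sel_fit] @ shape[sel_fit]
                  / max(shape[sel_fit] @ shape[sel_fit], 1e-30))
    return scale * shape


def session_plasticity(pre: EvokedPair, post: EvokedPair) -> PlasticityResult:
    """Post/pre amplitude ratios; R ~ 1 means no change."""
    if pre.a1 <= 0 or pre.a2 <= 0:
        raise ValueError("pre-induction amplitude is ~0; ratio undefined")
    return PlasticityResult(r1=post.a1 / pre.a1, r2=post.a2 / pre.a2)


def cross_session_normalize(series) -> np.ndarray:
    """Divide a per-session amplitude series by the mean of sessions 1-2."""
    arr = np.asarray(series, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two sessions to normalize")
    ref = arr[:2].mean()
    if ref == 0:
        raise ValueError("first-two-session mean is zero")
    return arr / ref
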