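"""Session stimulation protocol: baselines, paired pulses, and induction bouts.

A session is an initial quiet-stimulation baseline, a high-frequency
induction epoch, and a second baseline.  During both baselines, pairs of
brief laser pulses (30-Hz pairs, i.e. ~33.3 ms apart) are delivered every
``pp_interval_s`` seconds to probe the evoked EEG response.  The induction
consists of ``sweeps`` sweeps, one per ``sweep_period_s``, each containing
``bouts_per_sweep`` bouts of ``bout_on_s`` seconds of ``induction_rate_hz``
stimulation separated by ``bout_off_s`` seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Mapping

import numpy as np

__all__ = ["StimProtocol", "build_protocol", "ProtocolError"]


class ProtocolError(ValueError):
    """Raised for inconsistent or unknown protocol parameters."""


@dataclass(frozen=True)
class StimProtocol:
    """Timing of one stimulation session (defaults: ~33-minute session)."""

    baseline_pre_s: float = 600.0
    induction_s: float = 180.0
    baseline_post_s: float = 1200.0
    pp_interval_s: float = 10.0
    pp_ipi_s: float = 1.0 / 30.0
    pulse_width_s: float = 0.010
    bout_on_s: float = 3.0
    bout_off_s: float = 3.0
    bouts_per_sweep: int = 5
    sweeps: int = 3
    sweep_period_s: float = 60.0
    induction_rate_hz: float = 50.0

    def __post_init__(self) -> None:
        for name in ("induction_s", "baseline_post_s", "pp_interval_s",
                     "pp_ipi_s", "pulse_width_s", "bout_on_s", "sweep_period_s",
                     "induction_rate_hz"):
            if getattr(self, name) <= 0:
                raise ProtocolError(f"{name} must be > 0")
        if self.baseline_pre_s < 0 or self.bout_off_s < 0:
            raise ProtocolError("baseline_pre_s and bout_off_s must be >= 0")
        if self.bouts_per_sweep < 1 or self.sweeps < 1:
            raise ProtocolError("need at least one bout and one sweep")
        cycle = self.bout_on_s + self.bout_off_s
        if self.bouts_per_sweep * cycle - self.bout_off_s > self.sweep_period_s:
            raise ProtocolError("bouts do not fit inside one sweep period")
        if self.sweeps * self.sweep_period_s > self.induction_s + 1e-9:
            raise ProtocolError("sweeps do not fit inside the induction epoch")

    # -- derived timing ----------------------------------------------------
    @property
    def total_s(self) -> float:
        return self.baseline_pre_s + self.induction_s + self.baseline_post_s

    @property
    def induction_start_s(self) -> float:
        return self.baseline_pre_s

    @property
    def induction_end_s(self) -> float:
        return self.baseline_pre_s + self.induction_s

    def bout_onsets(self) -> np.ndarray:
        """Onset time of every induction bout, seconds from session start."""
        cycle = self.bout_on_s + self.bout_off_s
        onsets = [
            self.induction_start_s + j * self.sweep_period_s + i * cycle
            for j in range(self.sweeps)
            for i in range(self.bouts_per_sweep)
        ]
        return np.asarray(onsets)

    def induction_pulse_times(self) -> np.ndarray:
        """Onset of every laser pulse inside the induction bouts."""
        period = 1.0 / self.induction_rate_hz
        n_per_bout = int(round(self.bout_on_s * self.induction_rate_hz))
        offsets = np.arange(n_per_bout) * period
        return (self.bout_onsets()[:, None] + offsets[None, :]).ravel()

    def pulse_pair_times(self, period: str = "all") -> np.ndarray:
        """First-pulse onsets of the paired-pulse probes.

        Pairs are delivered every ``pp_interval_s`` during the baselines,
        starting half an interval into each baseline.  ``period`` selects
        ``"pre"``, ``"post"`` or ``"all"``.
        """
        start_off = self.pp_interval_s / 2.0
        pre = np.arange(start_off, self.baseline_pre_s - 0.5,
                        self.pp_interval_s) if self.baseline_pre_s > start_off else np.empty(0)
        post = self.induction_end_s + np.arange(
            start_off, self.baseline_post_s - 0.5, self.pp_interval_s)
        if period == "pre":
            return pre
        if period == "post":
            return post
        if period == "all":
            return np.concatenate([pre, post])
        raise ProtocolError(f"unknown period {period!r}")

    def all_stimulus_times(self) -> np.ndarray:
        """Every pulse onset in the session (paired-pulse + induction)."""
        pairs = self.pulse_pair_times("all")
        both = np.concatenate([pairs, pairs + self.pp_ipi_s,
                               self.induction_pulse_times()])
        return np.sort(both)


def build_protocol(overrides: Mapping[str, float] | None = None) -> StimProtocol:
    """Build a :class:`StimProtocol`, overriding only known field names."""
    overrides = dict(overrides or {})
    known = {f.name for f in fields(StimProtocol)}
    unknown = set(overrides) - known
    if unknown:
        raise ProtocolError(f"unknown protocol field(s): {sorted(unknown)}")
    return StimProtocol(**overrides)
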