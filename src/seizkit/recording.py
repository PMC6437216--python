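"""In-memory EEG recording container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EEGRecording"]


@dataclass
class EEGRecording:
    """Sampled EEG trace(s) with aligned event markers.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)``, volts.  A 1-D array is
        promoted to a single channel.
    fs
        Sampling rate, Hz.
    channels
        Channel labels.
    annotations
        Mapping from marker name (e.g. ``"pp_pulse"``, ``"bout"``) to onset
        times in seconds from recording start.
    start_clock_h
        Clock time-of-day at recording start, hours in [0, 24).
    """

    data: np.ndarray
    fs: float
    channels: list[str] = field(default_factory=lambda: ["EEG1"])
    annotations: dict[str, np.ndarray] = field(default_factory=dict)
    start_clock_h: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channels) != self.data.shape[0]:
            self.channels = [f"EEG{i + 1}" for i in range(self.data.shape[0])]
        self.annotations = {k: np.asarray(v, dtype=float)
                            for k, v in self.annotations.items()}

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, index: int = 0) -> np.ndarray:
        return self.data[index]
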