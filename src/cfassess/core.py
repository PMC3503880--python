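"""Core data containers shared by all pipeline stages.

Conventions
-----------
* Continuous data are stored as ``(n_channels, n_samples)`` arrays in microvolts.
* Epoched data are ``(n_trials, n_channels, n_samples)`` arrays in microvolts.
* Epoch time axes are expressed in seconds relative to the *offset* of the
  spoken instruction: the instruction occupies ``[-2, 0)`` s and the response
  window extends to ``+4`` s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: The nine recording electrodes, anterior to posterior, left to right.
CHANNELS_9 = ["FC3", "FCz", "FC4", "C3", "Cz", "C4", "CP3", "CPz", "CP4"]

#: Left- and right-hemisphere (non-midline) electrodes.
LEFT_CHANNELS = ["FC3", "C3", "CP3"]
RIGHT_CHANNELS = ["FC4", "C4", "CP4"]

#: Task conditions.
CONDITIONS = ("left", "right", "rest")

#: Default epoch geometry (seconds relative to instruction offset).
EPOCH_TMIN = -2.0
EPOCH_TMAX = 4.0
EPOCH_LENGTH = EPOCH_TMAX - EPOCH_TMIN  # 6 s


def events_frame(onsets, conditions) -> pd.DataFrame:
    """Build a validated event table from parallel sequences."""
    onsets = np.asarray(onsets, dtype=np.int64)
    conditions = np.asarray(conditions, dtype=object)
    if onsets.shape != conditions.shape:
        raise ValueError("onsets and conditions must have equal length")
    return pd.DataFrame({"onset_sample": onsets, "condition": conditions})


@dataclass
class RawRecording:
    """Continuous multichannel EEG with an instruction event table.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    sfreq : float
        Sampling rate in Hz.
    ch_names : list of str
        Channel labels, one per row of ``data``.
    events : DataFrame
        Columns ``onset_sample`` (int) and ``condition`` (str); onsets must
        lie inside the recording.
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    events: pd.DataFrame = field(default_factory=lambda: events_frame([], []))

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError(
                f"{self.data.shape[0]} data rows but {len(self.ch_names)} channel labels"
            )
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.events):
            onsets = self.events["onset_sample"].to_numpy()
            if onsets.min() < 0 or onsets.max() >= self.n_samples:
                raise ValueError("event onsets outside recording bounds")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sfreq

    def copy(self) -> "RawRecording":
        return RawRecording(
            self.data.copy(), self.sfreq, list(self.ch_names), self.events.copy()
        )

    def pick(self, ch_names: list[str]) -> "RawRecording":
        """Return a recording restricted to ``ch_names`` (label-based)."""
        idx = [self.ch_names.index(c) for c in ch_names]
        return RawRecording(self.data[idx], self.sfreq, list(ch_names), self.events.copy())


@dataclass
class Epochs:
    """Segmented trials with condition labels.

    ``times`` runs from ``tmin`` in steps of ``1/sfreq``; with the default
    geometry a 100 Hz epoch holds exactly 600 samples spanning ``[-2, +4)`` s
    relative to instruction offset.
    """

    data: np.ndarray  # (n_trials, n_channels, n_samples)
    sfreq: float
    ch_names: list[str]
    conditions: np.ndarray
    tmin: float = EPOCH_TMIN
    montage: str = "monopolar"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (trials, channels, samples)")
        self.conditions = np.asarray(self.conditions, dtype=object)
        if self.data.shape[0] != len(self.conditions):
            raise ValueError("one condition label per trial required")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("one channel label per data row required")
        if self.montage not in ("monopolar", "bipolar"):
            raise ValueError(f"unknown montage tag {self.montage!r}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_samples) / self.sfreq

    def select_trials(self, idx) -> "Epochs":
        idx = np.asarray(idx)
        return replace(self, data=self.data[idx], conditions=self.conditions[idx])

    def select_condition(self, condition: str) -> "Epochs":
        return self.select_trials(np.flatnonzero(self.conditions == condition))

    def condition_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.conditions.astype(str), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def copy(self) -> "Epochs":
        return replace(self, data=self.data.copy(), conditions=self.conditions.copy())
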