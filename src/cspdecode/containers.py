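"""Core data containers: continuous recordings and epoched trials.

The unit of analysis throughout the package is the :class:`EpochSet`:
a ``trials x channels x samples`` array of band-passed EEG cut around task
cues, with one binary label (+1 / -1) per trial.  Continuous multichannel
recordings with event markers are held in :class:`RawRecording` until they
are epoched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

__all__ = ["RawRecording", "EpochSet"]


@dataclass
class RawRecording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    samples
        ``channels x time`` array in microvolts.
    fs
        Sampling rate in Hz.
    channel_names
        One name per channel.
    events
        Sequence of ``(onset_sample, label)`` pairs; labels are +1 or -1.
    """

    samples: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    events: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] < 1:
            raise DataError("samples must be a channels x time matrix with >= 1 channel")
        if self.fs <= 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1}" for i in range(self.samples.shape[0])]
        if len(self.channel_names) != self.samples.shape[0]:
            raise DataError("channel_names length does not match channel count")
        n_time = self.samples.shape[1]
        for onset, label in self.events:
            if not 0 <= onset < n_time:
                raise DataError(f"event onset {onset} outside recording of length {n_time}")
            if label not in (-1, 1):
                raise DataError(f"event label must be +1 or -1, got {label}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Epoched two-class trials: ``trials x channels x samples`` plus labels.

    ``window`` records the epoch extent in seconds relative to the task cue
    (0 s = cue onset); the sample count is ``round((t_end - t_start) * fs)``.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    window: tuple[float, float] = (0.0, 0.0)
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise DataError("epoch data must be trials x channels x samples")
        if self.labels.shape != (self.data.shape[0],):
            raise DataError("labels must be one per trial")
        if not np.all(np.isin(self.labels, (-1, 1))):
            raise DataError("labels must be +1 or -1")
        if self.fs <= 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise DataError("channel_names length does not match channel count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def class_counts(self) -> tuple[int, int]:
        """Trial counts ``(N_1, N_2)`` for labels +1 and -1."""
        return int(np.sum(self.labels == 1)), int(np.sum(self.labels == -1))

    def class_trials(self, label: int) -> np.ndarray:
        """All trials of one class, ``n_k x channels x samples``."""
        return self.data[self.labels == label]
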