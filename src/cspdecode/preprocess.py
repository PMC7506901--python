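"""Band-pass filtering and single-trial epoch extraction.

Motor imagery modulates band power of the sensorimotor mu (8-12 Hz) and
beta (18-26 Hz) rhythms, so the conventional front end is a 6th-order
Butterworth band-pass at 8-30 Hz followed by cutting a fixed time window
around each task cue.  Zero-phase (forward-backward) application is the
default so that the filter's group delay does not shift activity relative
to the fixed window; a causal mode is available for online-style use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import EpochSet, RawRecording
from .errors import DataError, EpochingError, InvalidBandError

__all__ = ["BandPassSpec", "bandpass_filter", "bandpass_epochs", "extract_epochs"]


@dataclass(frozen=True)
class BandPassSpec:
    """Butterworth band-pass specification.

    ``order`` is the order of the underlying analog prototype; with
    ``phase_mode='zero_phase'`` the effective magnitude response is squared
    by the forward-backward pass.
    """

    low_hz: float
    high_hz: float
    order: int = 6
    family: str = "butterworth"
    phase_mode: str = "zero_phase"

    def __post_init__(self) -> None:
        if self.family != "butterworth":
            raise InvalidBandError(f"unsupported filter family {self.family!r}")
        if not 0 < self.low_hz < self.high_hz:
            raise InvalidBandError(
                f"band edges must satisfy 0 < low < high, got ({self.low_hz}, {self.high_hz})"
            )
        if self.order < 1:
            raise InvalidBandError(f"filter order must be >= 1, got {self.order}")
        if self.phase_mode not in ("zero_phase", "causal"):
            raise InvalidBandError(f"unknown phase_mode {self.phase_mode!r}")

    def sos(self, fs: float) -> np.ndarray:
        """Second-order sections for sampling rate ``fs``; validates Nyquist."""
        nyq = fs / 2.0
        if self.high_hz >= nyq:
            raise InvalidBandError(
                f"band edge {self.high_hz} Hz not below Nyquist {nyq} Hz (fs={fs})"
            )
        return signal.butter(
            self.order, [self.low_hz, self.high_hz], btype="bandpass", fs=fs, output="sos"
        )


def _apply_sos(sos: np.ndarray, data: np.ndarray, phase_mode: str) -> np.ndarray:
    """Filter along the last axis; zero-phase doubles the effective order."""
    if phase_mode == "zero_phase":
        return signal.sosfiltfilt(sos, data, axis=-1)
    return signal.sosfilt(sos, data, axis=-1)


def bandpass_filter(rec: RawRecording, spec: BandPassSpec) -> RawRecording:
    """Band-pass filter each channel of a continuous recording.

    Returns a new :class:`RawRecording` with the same shape, sampling rate,
    channel names and events.
    """
    if not np.all(np.isfinite(rec.samples)):
        raise DataError("recording contains non-finite samples")
    min_len = 3 * (spec.order + 1)
    if rec.n_samples <= min_len:
        raise DataError(
            f"recording length {rec.n_samples} too short for order-{spec.order} filtering"
        )
    sos = spec.sos(rec.fs)
    filtered = _apply_sos(sos, rec.samples, spec.phase_mode)
    return RawRecording(
        samples=filtered,
        fs=rec.fs,
        channel_names=list(rec.channel_names),
        events=list(rec.events),
    )


def bandpass_epochs(epochs: EpochSet, spec: BandPassSpec) -> EpochSet:
    """Band-pass filter every trial of an already-epoched set.

    Convenience for pipelines whose input arrives pre-epoched; each
    trial x channel series is filtered independently along time.
    """
    if not np.all(np.isfinite(epochs.data)):
        raise DataError("epoch data contains non-finite samples")
    sos = spec.sos(epochs.fs)
    return EpochSet(
        data=_apply_sos(sos, epochs.data, spec.phase_mode),
        labels=epochs.labels.copy(),
        fs=epochs.fs,
        window=epochs.window,
        channel_names=list(epochs.channel_names),
    )


def extract_epochs(rec: RawRecording, window: tuple[float, float]) -> EpochSet:
    """Cut one epoch per event from a continuous recording.

    ``window = (t_start, t_end)`` is in seconds relative to each event onset
    (0 s = cue).  Samples are taken half-open as
    ``[onset + round(t_start*fs), onset + round(t_start*fs) + K)`` with
    ``K = round((t_end - t_start) * fs)``, so every trial has exactly K
    samples.

    Raises
    ------
    EpochingError
        If any event's window falls outside the recording; the message
        lists every offending event.
    """
    t_start, t_end = window
    if t_end <= t_start:
        raise EpochingError(f"empty window {window}")
    if not rec.events:
        raise EpochingError("recording has no events to epoch")
    k = int(round((t_end - t_start) * rec.fs))
    offset = int(round(t_start * rec.fs))
    bad: list[tuple[int, int]] = []
    starts = []
    for onset, _label in rec.events:
        start = onset + offset
        if start < 0 or start + k > rec.n_samples:
            bad.append((onset, _label))
        starts.append(start)
    if bad:
        raise EpochingError(
            f"window {window} exceeds recording bounds for events {bad}"
        )
    data = np.stack([rec.samples[:, s : s + k] for s in starts])
    labels = np.array([label for _onset, label in rec.events], dtype=int)
    return EpochSet(
        data=data,
        labels=labels,
        fs=rec.fs,
        window=(t_start, t_end),
        channel_names=list(rec.channel_names),
    )
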