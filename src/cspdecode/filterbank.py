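"""Filter-bank log-variance features of CSP-projected signals (CSP-FB).

Each projected channel is filtered into a bank of overlapping Butterworth
band-passes (by default ten 4 Hz bands stepping by 2 Hz across 8-30 Hz) and
the natural log of the variance of each band-limited signal is the feature.
Layout is band-major: all 2m channels of band 1, then band 2, ... so
P = 2m * B.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .csp import ProjectedTrials
from .errors import DegenerateFeatureError, InvalidBandError
from .features import FeatureMatrix

__all__ = ["FilterBankSpec", "make_filter_bank", "extract_csp_fb"]


@dataclass(frozen=True)
class FilterBankSpec:
    """Ordered equal-width band-pass bank with a common Butterworth order."""

    bands: tuple[tuple[float, float], ...]
    order: int = 6

    def __post_init__(self) -> None:
        if not self.bands:
            raise InvalidBandError("filter bank has no bands")
        widths = [hi - lo for lo, hi in self.bands]
        if any(w <= 0 for w in widths):
            raise InvalidBandError(f"non-positive band width in {self.bands}")
        if max(widths) - min(widths) > 1e-9:
            raise InvalidBandError("bands must share a common width")
        lows = [lo for lo, _ in self.bands]
        if any(b - a <= 0 for a, b in zip(lows[:-1], lows[1:])):
            raise InvalidBandError("band low edges must be strictly increasing")
        steps = np.diff(lows)
        if steps.size and np.ptp(steps) > 1e-9:
            raise InvalidBandError("band low edges must be equally spaced")

    @property
    def n_bands(self) -> int:
        return len(self.bands)


def make_filter_bank(
    low_hz: float, high_hz: float, width_hz: float, step_hz: float, order: int = 6
) -> FilterBankSpec:
    """Tile ``[low, high]`` with bands ``[low + i*step, low + i*step + width]``.

    Bands are emitted while the upper edge stays within ``high_hz``, giving
    ``floor((high - low - width) / step) + 1`` bands; e.g. (8, 30, 4, 2)
    yields the ten bands 8-12, 10-14, ..., 26-30 Hz.
    """
    if step_hz <= 0:
        raise InvalidBandError(f"step must be positive, got {step_hz}")
    if width_hz <= 0 or width_hz > high_hz - low_hz:
        raise InvalidBandError(
            f"width {width_hz} does not fit the range ({low_hz}, {high_hz})"
        )
    bands = []
    i = 0
    while low_hz + i * step_hz + width_hz <= high_hz + 1e-9:
        lo = low_hz + i * step_hz
        bands.append((lo, lo + width_hz))
        i += 1
    return FilterBankSpec(bands=tuple(bands), order=order)


def extract_csp_fb(
    proj: ProjectedTrials,
    bank: FilterBankSpec,
    phase_mode: str = "zero_phase",
) -> FeatureMatrix:
    """Log-variance of each projected channel in each bank band.

    Variance uses the population convention; log is natural.  Filtering is
    zero-phase by default (matching the preprocessing front end).
    """
    nyq = proj.fs / 2.0
    for lo, hi in bank.bands:
        if hi >= nyq:
            raise InvalidBandError(
                f"band ({lo}, {hi}) Hz exceeds Nyquist {nyq} Hz at fs={proj.fs}"
            )
    n_trials, n_chan, _ = proj.data.shape
    values = np.empty((n_trials, bank.n_bands * n_chan))
    for b, (lo, hi) in enumerate(bank.bands):
        sos = signal.butter(bank.order, [lo, hi], btype="bandpass", fs=proj.fs, output="sos")
        if phase_mode == "zero_phase":
            filt = signal.sosfiltfilt(sos, proj.data, axis=-1)
        else:
            filt = signal.sosfilt(sos, proj.data, axis=-1)
        variances = np.var(filt, axis=2)  # trials x channels
        if np.any(variances <= 0.0):
            raise DegenerateFeatureError(
                f"zero variance after filtering band ({lo}, {hi}) Hz"
            )
        values[:, b * n_chan : (b + 1) * n_chan] = np.log(variances)
    names = [
        f"{lo:g}-{hi:g}Hz|csp{c + 1}|logvar"
        for lo, hi in bank.bands
        for c in range(n_chan)
    ]
    return FeatureMatrix(values=values, feature_names=names, labels=proj.labels)
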