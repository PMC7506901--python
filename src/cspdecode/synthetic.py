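"""Synthetic two-class EEG with ERD/ERS-style band-power differences.

The generator emulates the physical premise of motor-imagery decoding:
cortical sources are band-limited oscillations (mu ~8-12 Hz, beta
~18-26 Hz) that mix linearly into scalp channels, and the two task classes
differ only in the variance of one source within its rhythm band
(event-related desynchronization / synchronization).  Concretely,

    trial = mixing @ sources + sensor_noise

where each source is white Gaussian noise band-pass filtered to its band
and rescaled to an exact target standard deviation per trial; the ERD
source's variance is multiplied by ``variance_ratio`` for class +1 only.
Because per-trial source variances are exact (not just in expectation),
the expected channel covariance is exactly
``mixing @ diag(source variances) @ mixing' + noise_sd^2 * I``.

Defaults mirror a typical 250 Hz / 2 s motor-imagery setup with 8 channels,
a mu and a beta source plus two broadband (8-30 Hz) background sources,
a 4x mu-power ratio between classes and light sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import EpochSet
from .csp import SpatialFilterBank
from .errors import ConfigError
from .preprocess import BandPassSpec, _apply_sos

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_epochs",
    "generate_train_test",
    "ground_truth_alignment",
]


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults define the standard study condition."""

    n_channels: int = 8
    n_sources: int = 4
    fs: float = 250.0
    n_trials_per_class: int = 100
    trial_seconds: float = 2.0
    source_bands: tuple[tuple[float, float], ...] = (
        (8.0, 12.0),   # mu — the discriminative (ERD) source
        (18.0, 26.0),  # beta
        (8.0, 30.0),   # broadband background
        (8.0, 30.0),   # broadband background
    )
    erd_source_index: int = 0
    erd_band: tuple[float, float] = (8.0, 12.0)
    variance_ratio: float = 4.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variance_ratio <= 0:
            raise ConfigError("variance_ratio must be positive")
        if len(self.source_bands) != self.n_sources:
            raise ConfigError("one band per source required")
        if not 0 <= self.erd_source_index < self.n_sources:
            raise ConfigError("erd_source_index out of range")
        nyq = self.fs / 2.0
        for lo, hi in self.source_bands:
            if not 0 < lo < hi < nyq:
                raise ConfigError(f"source band ({lo}, {hi}) outside (0, Nyquist)")
        if self.n_channels < self.n_sources:
            raise ConfigError("need at least as many channels as sources")


@dataclass
class GroundTruth:
    """What the generator actually drew: mixing and per-class source variances."""

    mixing: np.ndarray
    erd_source_index: int
    erd_band: tuple[float, float]
    source_variances: dict[int, np.ndarray] = field(default_factory=dict)

    def unmixing_row(self) -> np.ndarray:
        """The ERD source's row of the mixing pseudo-inverse (its spatial filter)."""
        return np.linalg.pinv(self.mixing)[self.erd_source_index]


def _band_limited_noise(rng, sos, n_samples: int, pad: int) -> np.ndarray:
    """White noise, band-filtered zero-phase, center-cropped past transients."""
    raw = rng.standard_normal(n_samples + 2 * pad)
    filtered = _apply_sos(sos, raw, "zero_phase")
    return filtered[pad : pad + n_samples]


def generate_epochs(
    cfg: SyntheticConfig, mixing: np.ndarray | None = None
) -> tuple[EpochSet, GroundTruth]:
    """Draw a full two-class epoch set, reproducible from ``cfg.seed``.

    Class +1 trials come first, then class -1.  ``mixing`` may be supplied
    (channels x sources, full column rank) to pin the forward model;
    otherwise a random Gaussian matrix is drawn from the same seed.
    """
    rng = np.random.default_rng(cfg.seed)
    k = int(round(cfg.trial_seconds * cfg.fs))
    if mixing is None:
        mixing = rng.standard_normal((cfg.n_channels, cfg.n_sources))
    else:
        mixing = np.asarray(mixing, dtype=float)
        if mixing.shape != (cfg.n_channels, cfg.n_sources):
            raise ConfigError(
                f"mixing must be {cfg.n_channels} x {cfg.n_sources}, got {mixing.shape}"
            )
    if np.linalg.matrix_rank(mixing) < cfg.n_sources:
        raise ConfigError("mixing matrix is rank deficient")

    sos_per_source = [
        BandPassSpec(lo, hi, order=4).sos(cfg.fs) for lo, hi in cfg.source_bands
    ]
    pad = int(2 * cfg.fs)
    base_sd = np.ones(cfg.n_sources)
    class_sd = {1: base_sd.copy(), -1: base_sd.copy()}
    class_sd[1][cfg.erd_source_index] = np.sqrt(cfg.variance_ratio)

    n = cfg.n_trials_per_class
    data = np.empty((2 * n, cfg.n_channels, k))
    labels = np.concatenate([np.ones(n, dtype=int), -np.ones(n, dtype=int)])
    for t, label in enumerate(labels):
        sources = np.empty((cfg.n_sources, k))
        for s in range(cfg.n_sources):
            sig = _band_limited_noise(rng, sos_per_source[s], k, pad)
            sig = sig - sig.mean()
            sig *= class_sd[label][s] / sig.std()
            sources[s] = sig
        data[t] = mixing @ sources + cfg.noise_sd * rng.standard_normal(
            (cfg.n_channels, k)
        )
    epochs = EpochSet(
        data=data, labels=labels, fs=cfg.fs, window=(0.0, cfg.trial_seconds)
    )
    truth = GroundTruth(
        mixing=mixing,
        erd_source_index=cfg.erd_source_index,
        erd_band=cfg.erd_band,
        source_variances={c: sd**2 for c, sd in class_sd.items()},
    )
    return epochs, truth


def generate_train_test(
    cfg: SyntheticConfig, test_seed: int | None = None
) -> tuple[EpochSet, EpochSet, GroundTruth]:
    """A session-style train/test pair sharing one mixing matrix.

    Both sets come from the same forward model (the same simulated subject)
    but independent source and noise draws; ``test_seed`` defaults to
    ``cfg.seed + 10_000``.
    """
    import dataclasses

    train, truth = generate_epochs(cfg)
    test_cfg = dataclasses.replace(
        cfg, seed=cfg.seed + 10_000 if test_seed is None else test_seed
    )
    test, _ = generate_epochs(test_cfg, mixing=truth.mixing)
    return train, test, truth


def ground_truth_alignment(filters: SpatialFilterBank, truth: GroundTruth) -> float:
    """How purely the top CSP filter extracts the planted ERD source.

    The filter w is mapped through the mixing geometry into source space:
    ``g = mixing' w`` gives the gain of w on each source, and the score is
    the absolute cosine ``|g_erd| / ||g||``.  Components of w outside the
    mixing column space carry no source signal and are ignored (they are
    not identifiable from variance when sensor noise is small).  A score of
    1 means w listens to the discriminative source only; random filters
    score well below 1.
    """
    w = filters.W[:, 0]
    if w.shape[0] != truth.mixing.shape[0]:
        raise ConfigError("filter and mixing dimensions do not match")
    gains = truth.mixing.T @ w
    norm = np.linalg.norm(gains)
    if norm == 0.0:
        return 0.0
    return float(abs(gains[truth.erd_source_index]) / norm)
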