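"""Common spatial pattern (CSP) filtering for two-class EEG.

CSP seeks channel-weight vectors w maximizing the Rayleigh quotient

    J(w) = (w' C1 w) / (w' C2 w)

of the two class-average covariance matrices.  Its stationary points are
the generalized eigenvectors of the pair (C1, C2); filters at the two ends
of the eigenvalue spectrum give signals whose variance best discriminates
the classes.  Per convention the m first and m last eigenvectors (sorted by
descending eigenvalue) form the projection matrix W with 2m columns.

The eigenproblem is solved in symmetric-definite form (scipy's ``eigh`` on
the pair) rather than via C2^{-1} C1, which keeps the computation symmetric
and the eigenvectors C2-orthogonal.  A tiny ridge is loaded onto C2 before
solving to guard against rank deficiency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .containers import EpochSet
from .errors import (
    DataError,
    DegenerateFeatureError,
    DegenerateTrialError,
    SingularCovarianceError,
)
from .features import FeatureMatrix

__all__ = [
    "ClassCovariances",
    "SpatialFilterBank",
    "ProjectedTrials",
    "compute_class_covariances",
    "solve_csp",
    "project",
    "logvar_features",
]

#: ridge scale relative to trace(cov2)/C loaded before the eigensolve
RIDGE_SCALE = 1e-10


@dataclass
class ClassCovariances:
    """Class-average spatial covariances ``cov1`` (label +1), ``cov2`` (label -1).

    With ``trace_normalized=True`` each per-trial covariance D D' was divided
    by its trace before averaging, so both matrices have unit trace.
    """

    cov1: np.ndarray
    cov2: np.ndarray
    trace_normalized: bool = True

    def __post_init__(self) -> None:
        self.cov1 = np.asarray(self.cov1, dtype=float)
        self.cov2 = np.asarray(self.cov2, dtype=float)
        for name, c in (("cov1", self.cov1), ("cov2", self.cov2)):
            if c.ndim != 2 or c.shape[0] != c.shape[1]:
                raise DataError(f"{name} must be square")
        if self.cov1.shape != self.cov2.shape:
            raise DataError("cov1 and cov2 must have identical shapes")

    @property
    def n_channels(self) -> int:
        return self.cov1.shape[0]


@dataclass
class SpatialFilterBank:
    """CSP projection matrix ``W`` (C x 2m) with its generalized eigenvalues.

    ``eigvals`` holds the 2m retained eigenvalues in descending order
    (the first m and last m entries of ``full_eigvals``).
    """

    W: np.ndarray
    m: int
    eigvals: np.ndarray
    full_eigvals: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]

    @property
    def n_filters(self) -> int:
        return self.W.shape[1]

    def to_csv(self, path, channel_names: list[str] | None = None) -> None:
        """Export filters as a CSV matrix, one column per spatial filter."""
        import pandas as pd

        names = channel_names or [f"ch{i + 1}" for i in range(self.n_channels)]
        cols = [f"csp{j + 1}" for j in range(self.n_filters)]
        pd.DataFrame(self.W, index=names, columns=cols).to_csv(path)


@dataclass
class ProjectedTrials:
    """Spatially filtered trials ``Z = W' D``: ``trials x 2m x samples``."""

    data: np.ndarray
    fs: float
    labels: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_filters(self) -> int:
        return self.data.shape[1]


def compute_class_covariances(
    epochs: EpochSet, trace_normalize: bool = True
) -> ClassCovariances:
    """Average per-trial spatial covariances within each class.

    Each trial D (channels x samples) contributes D D' divided by its trace;
    the per-class mean of these unit-trace matrices is returned.  Label +1
    maps to ``cov1`` and label -1 to ``cov2``.

    ``trace_normalize=False`` skips the per-trial trace division (averaging
    raw D D' / K instead), which preserves absolute variance ratios between
    the classes; useful for diagnostics such as eigenvalue-recovery checks.
    """
    n1, n2 = epochs.class_counts()
    if n1 < 1 or n2 < 1:
        raise DataError(f"both classes need >= 1 trial, got counts ({n1}, {n2})")
    covs = {}
    for label in (1, -1):
        trials = epochs.class_trials(label)
        acc = np.zeros((epochs.n_channels, epochs.n_channels))
        for idx, d in enumerate(trials):
            s = d @ d.T
            tr = np.trace(s)
            if tr <= 0.0:
                raise DegenerateTrialError(
                    f"trial {idx} of class {label:+d} has zero energy"
                )
            acc += s / tr if trace_normalize else s / d.shape[1]
        covs[label] = acc / len(trials)
    return ClassCovariances(
        cov1=covs[1], cov2=covs[-1], trace_normalized=trace_normalize
    )


def solve_csp(covs: ClassCovariances, m: int = 3) -> SpatialFilterBank:
    """Solve the CSP generalized eigenproblem and keep the 2m extremal filters.

    Eigenvalues come back sorted descending; ``W`` holds the eigenvectors of
    the m largest followed by the m smallest eigenvalues.  Each eigenvector's
    sign is fixed so that its largest-magnitude component is positive
    (generalized eigenvector signs are otherwise arbitrary).
    """
    c = covs.n_channels
    if m < 1 or 2 * m > c:
        raise DataError(f"need 1 <= 2m <= C, got m={m}, C={c}")
    ridge = RIDGE_SCALE * np.trace(covs.cov2) / c
    b = covs.cov2 + ridge * np.eye(c)
    try:
        eigvals, eigvecs = linalg.eigh(covs.cov1, b)
    except linalg.LinAlgError as exc:
        raise SingularCovarianceError(
            f"cov2 numerically singular beyond ridge loading: {exc}"
        ) from exc
    if not np.all(np.isfinite(eigvals)):
        raise SingularCovarianceError("non-finite generalized eigenvalues")
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    keep = np.concatenate([np.arange(m), np.arange(c - m, c)])
    w = eigvecs[:, keep].copy()
    for j in range(w.shape[1]):
        pivot = np.argmax(np.abs(w[:, j]))
        if w[pivot, j] < 0:
            w[:, j] = -w[:, j]
    return SpatialFilterBank(
        W=w, m=m, eigvals=eigvals[keep], full_eigvals=eigvals
    )


def project(epochs: EpochSet, filters: SpatialFilterBank) -> ProjectedTrials:
    """Apply ``Z = W' D`` to every trial."""
    if epochs.n_channels != filters.n_channels:
        raise DataError(
            f"epochs have {epochs.n_channels} channels but W has "
            f"{filters.n_channels} rows"
        )
    z = np.einsum("cf,nck->nfk", filters.W, epochs.data)
    return ProjectedTrials(data=z, fs=epochs.fs, labels=epochs.labels.copy())


def logvar_features(proj: ProjectedTrials) -> FeatureMatrix:
    """Classic CSP features: normalized log-variance of each projected channel.

    Per trial, f_p = log( var(Z_p) / sum_i var(Z_i) ) for p = 1..2m, so that
    sum_p exp(f_p) = 1.  Variance uses the population convention (divide by
    the sample count); the normalized ratio is insensitive to that choice.
    """
    variances = np.var(proj.data, axis=2)  # trials x 2m
    if np.any(variances <= 0.0):
        bad = np.argwhere(variances <= 0.0)
        raise DegenerateFeatureError(
            f"zero-variance projected channel(s) at (trial, channel) {bad.tolist()}"
        )
    feats = np.log(variances / variances.sum(axis=1, keepdims=True))
    names = [f"csp{p + 1}:logvar" for p in range(proj.n_filters)]
    return FeatureMatrix(values=feats, feature_names=names, labels=proj.labels)
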