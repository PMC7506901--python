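"""Feature matrix container with per-column provenance.

Every extractor in the package returns a :class:`FeatureMatrix`: an
``N x P`` array of per-trial features whose column names encode where each
number came from (projected CSP channel, frequency sub-band, statistic).
The container round-trips losslessly through CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["FeatureMatrix"]

_LABEL_COLUMN = "label"


@dataclass
class FeatureMatrix:
    """``N x P`` features with provenance-encoded column names."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("feature values must be a 2-D N x P array")
        if len(self.feature_names) != self.values.shape[1]:
            raise DataError(
                f"{len(self.feature_names)} names for {self.values.shape[1]} columns"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise DataError("feature names must be unique")
        if _LABEL_COLUMN in self.feature_names:
            raise DataError(f"{_LABEL_COLUMN!r} is reserved for the label column")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.values.shape[0],):
                raise DataError("labels must be one per row")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select(self, indices: np.ndarray) -> "FeatureMatrix":
        """Column subset preserving provenance names and labels."""
        idx = np.asarray(indices, dtype=int)
        return FeatureMatrix(
            values=self.values[:, idx],
            feature_names=[self.feature_names[i] for i in idx],
            labels=None if self.labels is None else self.labels.copy(),
        )

    def to_csv(self, path) -> None:
        """Write header + one row per trial; label column appended if present."""
        df = pd.DataFrame(self.values, columns=self.feature_names)
        if self.labels is not None:
            df[_LABEL_COLUMN] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        if df.columns.size == 0:
            raise DataError(f"no columns found in {path}")
        labels = None
        if _LABEL_COLUMN in df.columns:
            labels = df.pop(_LABEL_COLUMN).to_numpy(dtype=int)
        bad = [c for c in df.columns if df[c].dtype.kind not in "fiu"]
        if bad:
            raise DataError(f"non-numeric feature columns: {bad}")
        return cls(
            values=df.to_numpy(dtype=float),
            feature_names=list(df.columns),
            labels=labels,
        )
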