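"""Fisher linear discriminant analysis for two classes.

The projection direction maximizes between-class over within-class scatter;
with pooled within-class scatter S_w and class means mu+, mu- it is

    d = (S_w + ridge * I)^{-1} (mu+ - mu-)

and the decision boundary sits at the midpoint of the projected means.
A small ridge (1e-8 * trace(S_w)/P by default) keeps the solve stable when
features outnumber trials.  Points exactly on the boundary are assigned +1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, FitError

__all__ = ["FldaModel", "flda_fit", "flda_predict"]

RIDGE_SCALE = 1e-8


@dataclass
class FldaModel:
    """Fitted discriminant: projection direction, midpoint bias, ridge used."""

    direction: np.ndarray
    bias: float
    ridge: float
    class_order: tuple[int, int] = (1, -1)  # (positive side, negative side)

    @property
    def n_features(self) -> int:
        return self.direction.size


def flda_fit(x: np.ndarray, y: np.ndarray, ridge_scale: float = RIDGE_SCALE) -> FldaModel:
    """Fit on ``N x P'`` training features with +/-1 labels."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=int)
    if x.shape[0] != y.size:
        raise DataError("one label per training row required")
    if x.shape[1] == 0:
        raise FitError("empty feature subset")
    pos, neg = x[y == 1], x[y == -1]
    if len(pos) == 0 or len(neg) == 0:
        raise FitError("both classes must be present in training data")
    mu_p, mu_n = pos.mean(axis=0), neg.mean(axis=0)
    cp, cn = pos - mu_p, neg - mu_n
    sw = cp.T @ cp + cn.T @ cn
    p = x.shape[1]
    trace = float(np.trace(sw))
    ridge = ridge_scale * (trace / p if trace > 0 else 1.0)
    direction = np.linalg.solve(sw + ridge * np.eye(p), mu_p - mu_n)
    if not np.any(direction):
        raise FitError("degenerate training data produced a zero direction")
    bias = float(direction @ (mu_p + mu_n) / 2.0)
    return FldaModel(direction=direction, bias=bias, ridge=ridge)


def flda_predict(model: FldaModel, x: np.ndarray) -> np.ndarray:
    """Predict +/-1 labels; boundary points go to the positive class."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.n_features:
        raise DataError(
            f"test data has {x.shape[1]} features, model expects {model.n_features}"
        )
    scores = x @ model.direction - model.bias
    pos, neg = model.class_order
    return np.where(scores >= 0.0, pos, neg)
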