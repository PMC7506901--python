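"""Secondary feature selection by weight thresholding and an FLDA ensemble.

After sparse selection produces a weight vector w, a grid of thresholds
tau in {0, 0.1, ..., 0.8} defines nested feature subsets { i : |w_i| > tau }
and one Fisher discriminant is fitted per non-empty subset.  At test time
every member model is scored and the *maximum* accuracy over the grid is
reported (an empty subset scores 0).  Note this max rule consults test
labels when picking the best member; a label-blind alternative that chooses
the threshold by inner cross-validation on the training set is provided as
:func:`evaluate_ensemble_cv`.

Thresholds compare against raw |w_i| by default; ``normalize=True``
rescales |w| by its maximum first, making the grid scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .flda import FldaModel, flda_fit, flda_predict
from .sparse import WeightVector

__all__ = [
    "DEFAULT_THRESHOLDS",
    "ThresholdEnsemble",
    "EvaluationReport",
    "build_ensemble",
    "evaluate_ensemble_max",
    "evaluate_ensemble_cv",
]

DEFAULT_THRESHOLDS: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(9))


@dataclass
class ThresholdEnsemble:
    """Per-threshold feature subsets and fitted models (None where empty)."""

    thresholds: tuple[float, ...]
    subsets: list[np.ndarray]
    models: list[FldaModel | None]
    source_weights: WeightVector
    normalized: bool = False

    def subset_sizes(self) -> list[int]:
        return [s.size for s in self.subsets]


@dataclass
class EvaluationReport:
    """Per-threshold test accuracies and the final (max-rule) accuracy."""

    thresholds: tuple[float, ...]
    accuracies: np.ndarray
    final_accuracy: float
    chosen_threshold: float
    subset_sizes: list[int] = field(default_factory=list)
    rule: str = "max"

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "final_accuracy": self.final_accuracy,
            "chosen_threshold": self.chosen_threshold,
            "per_threshold": [
                {"threshold": t, "subset_size": s, "accuracy": float(a)}
                for t, s, a in zip(self.thresholds, self.subset_sizes, self.accuracies)
            ],
        }

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "threshold": self.thresholds,
                "subset_size": self.subset_sizes,
                "accuracy": self.accuracies,
            }
        ).to_csv(path, index=False)


def build_ensemble(
    weights: WeightVector,
    x_train: np.ndarray,
    y_train: np.ndarray,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    normalize: bool = False,
) -> ThresholdEnsemble:
    """Fit one FLDA per threshold on the features with ``|w_i| > tau``.

    Empty subsets are recorded with no model; they are legal states and
    score 0 at evaluation time.
    """
    x_train = np.asarray(x_train, dtype=float)
    if x_train.shape[1] != weights.w.size:
        raise DataError(
            f"training data has {x_train.shape[1]} features but weights have "
            f"{weights.w.size}"
        )
    if any(b <= a for a, b in zip(thresholds[:-1], thresholds[1:])):
        raise DataError("thresholds must be strictly increasing")
    wabs = np.abs(weights.w)
    if normalize and wabs.max() > 0:
        wabs = wabs / wabs.max()
    subsets, models = [], []
    for tau in thresholds:
        sub = np.flatnonzero(wabs > tau)
        subsets.append(sub)
        if sub.size == 0:
            models.append(None)
        else:
            models.append(flda_fit(x_train[:, sub], y_train))
    return ThresholdEnsemble(
        thresholds=tuple(thresholds),
        subsets=subsets,
        models=models,
        source_weights=weights,
        normalized=normalize,
    )


def _member_accuracies(
    ens: ThresholdEnsemble, x_test: np.ndarray, y_test: np.ndarray
) -> np.ndarray:
    accs = np.zeros(len(ens.thresholds))
    for i, (sub, model) in enumerate(zip(ens.subsets, ens.models)):
        if model is None:
            continue
        pred = flda_predict(model, x_test[:, sub])
        accs[i] = float(np.mean(pred == y_test))
    return accs


def evaluate_ensemble_max(
    ens: ThresholdEnsemble, x_test: np.ndarray, y_test: np.ndarray
) -> EvaluationReport:
    """Score every member and report the maximum accuracy over the grid.

    Ties break toward the smallest threshold.  Empty subsets score 0; if
    every subset is empty the final accuracy is 0.
    """
    x_test = np.asarray(x_test, dtype=float)
    y_test = np.asarray(y_test, dtype=int)
    if y_test.size == 0:
        raise DataError("empty test set")
    accs = _member_accuracies(ens, x_test, y_test)
    best = int(np.argmax(accs))  # argmax returns the first (smallest) tie
    return EvaluationReport(
        thresholds=ens.thresholds,
        accuracies=accs,
        final_accuracy=float(accs[best]),
        chosen_threshold=ens.thresholds[best],
        subset_sizes=ens.subset_sizes(),
        rule="max",
    )


def evaluate_ensemble_cv(
    weights: WeightVector,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    y_test: np.ndarray,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    folds: int = 5,
    seed: int = 0,
    normalize: bool = False,
) -> EvaluationReport:
    """Label-blind alternative: pick the threshold by inner CV, score once.

    Stratified ``folds``-fold CV on the training data estimates each
    threshold's accuracy (empty subsets score 0); the best threshold (ties
    to the smallest) is refitted on the full training set and its single
    test accuracy reported.
    """
    from sklearn.model_selection import StratifiedKFold

    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    x_test = np.asarray(x_test, dtype=float)
    y_test = np.asarray(y_test, dtype=int)
    if y_test.size == 0:
        raise DataError("empty test set")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    cv_accs = np.zeros(len(thresholds))
    for tr, te in skf.split(x_train, y_train):
        fold_ens = build_ensemble(
            weights, x_train[tr], y_train[tr], thresholds, normalize=normalize
        )
        cv_accs += _member_accuracies(fold_ens, x_train[te], y_train[te])
    cv_accs /= folds
    best = int(np.argmax(cv_accs))
    full_ens = build_ensemble(weights, x_train, y_train, thresholds, normalize=normalize)
    sub, model = full_ens.subsets[best], full_ens.models[best]
    if model is None:
        final = 0.0
    else:
        final = float(np.mean(flda_predict(model, x_test[:, sub]) == y_test))
    return EvaluationReport(
        thresholds=tuple(thresholds),
        accuracies=cv_accs,
        final_accuracy=final,
        chosen_threshold=thresholds[best],
        subset_sizes=full_ens.subset_sizes(),
        rule="cv",
    )
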