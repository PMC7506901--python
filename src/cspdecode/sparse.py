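"""Sparse feature-weight estimation: LASSO and the non-convex LOG penalty.

Both selectors regress the +/-1 labels y on the standardized feature matrix
X and keep features with nonzero weight:

* **LASSO**:  min_w  1/2 ||y - Xw||^2 + lam * ||w||_1
* **LOG**:    min_w  1/2 ||y - Xw||^2 + lam * sum_i log(1 + |w_i| / a)

The log penalty is concave in |w_i|, which shrinks large weights far less
than the l1 norm (debiasing) while thresholding small ones harder.  Both
are solved by proximal gradient descent ("iterative thresholding"): a
gradient step on the quadratic with step 1/gamma, gamma = ||X'X||_2, then
the penalty's elementwise shrinkage operator.

For the log penalty the shrinkage has a closed form,

    w = sign(v)/2 * ( |v| - a + sqrt( (a - |v|)^2 + 4*max(a|v| - lam/gamma, 0) ) )

(`closed_form` mode, the default).  The clamp makes the square
root collapse for small inputs so the output is exactly zero.  This formula
returns the larger stationary point of the scalar prox objective whenever
one exists but does not compare its objective value against zero, so in a
narrow regime it can return a nonzero point with a worse objective than 0;
`exact` mode performs that comparison and returns the true global
minimizer.  The two agree except on that boundary set.

The penalty is treated as the separable sum over coordinates (the form
consistent with an elementwise shrinkage operator); the non-separable
variant  lam * log(1 + ||w||_1 / a)  is additionally evaluated on the final
iterate for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .flda import flda_fit, flda_predict

__all__ = [
    "SparseProblem",
    "SolverConfig",
    "WeightVector",
    "ColumnStandardizer",
    "soft_threshold",
    "prox_log",
    "ista_lasso",
    "ista_log",
    "spectral_step_constant",
    "default_lambda_grid",
    "cv_select_lambda",
]

#: default log-penalty scale
DEFAULT_A = 0.001


def default_lambda_grid() -> np.ndarray:
    """The 51-point regularization grid 2^-5, 2^-4.8, ..., 2^5."""
    return 2.0 ** np.linspace(-5.0, 5.0, 51)


def spectral_step_constant(x: np.ndarray, tol: float = 1e-10, max_iter: int = 5000) -> float:
    """gamma = ||X'X||_2 by power iteration with a deterministic start."""
    x = np.asarray(x, dtype=float)
    p = x.shape[1]
    v = np.ones(p) / np.sqrt(p)
    lam = 0.0
    for _ in range(max_iter):
        w = x.T @ (x @ v)
        norm = np.linalg.norm(w)
        if norm == 0.0:
            return 0.0
        v_new = w / norm
        lam_new = float(v_new @ (x.T @ (x @ v_new)))
        if abs(lam_new - lam) <= tol * max(1.0, abs(lam_new)):
            return lam_new
        lam, v = lam_new, v_new
    return lam


@dataclass
class SparseProblem:
    """One regression-form selection problem; gamma is derived from X."""

    X: np.ndarray
    y: np.ndarray
    lam: float
    a: float = DEFAULT_A
    gamma: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or self.y.shape != (self.X.shape[0],):
            raise DataError("X must be N x P with y of length N")
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.y)):
            raise DataError("X and y must be finite")
        if self.lam <= 0 or self.a <= 0:
            raise DataError("lam and a must be positive")
        if self.gamma == 0.0:
            self.gamma = spectral_step_constant(self.X)
        if self.gamma <= 0.0:
            raise DataError("step constant gamma must be positive (X must be nonzero)")


@dataclass(frozen=True)
class SolverConfig:
    """Iteration budget, stopping rule and shrinkage-operator mode."""

    max_iter: int = 1000
    tol: float = 1e-6
    mode: str = "closed_form"  # "closed_form" | "exact"

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise DataError("max_iter must be >= 1")
        if self.tol <= 0:
            raise DataError("tol must be positive")
        if self.mode not in ("closed_form", "exact"):
            raise DataError(f"unknown prox mode {self.mode!r}")


@dataclass
class WeightVector:
    """Solver output: weights plus the per-iteration objective trace."""

    w: np.ndarray
    iterations: int
    objective_trace: np.ndarray
    converged: bool
    mode: str
    lam: float
    objective_nonseparable: float | None = None

    def support(self, threshold: float = 0.0) -> np.ndarray:
        """Indices with ``|w_i| > threshold``."""
        return np.flatnonzero(np.abs(self.w) > threshold)

    def to_csv(self, path, feature_names: list[str] | None = None,
               thresholds: tuple[float, ...] = ()) -> None:
        import pandas as pd

        names = feature_names or [f"f{i + 1}" for i in range(self.w.size)]
        df = pd.DataFrame({"feature": names, "weight": self.w, "abs_weight": np.abs(self.w)})
        for t in thresholds:
            df[f"selected@{t:g}"] = np.abs(self.w) > t
        df.to_csv(path, index=False)


def soft_threshold(v: np.ndarray, t: float) -> np.ndarray:
    """Elementwise ``sign(v) * max(|v| - t, 0)`` — the l1 shrinkage operator."""
    if t < 0:
        raise DataError(f"threshold must be >= 0, got {t}")
    v = np.asarray(v, dtype=float)
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def _prox_log_formula(v: np.ndarray, t: float, a: float) -> np.ndarray:
    u = np.abs(v)
    inner = (a - u) ** 2 + 4.0 * np.maximum(a * u - t, 0.0)
    return np.sign(v) * 0.5 * (u - a + np.sqrt(inner))


def prox_log(v: np.ndarray, lam_over_gamma: float, a: float,
             mode: str = "closed_form") -> np.ndarray:
    """Shrinkage operator of the scaled log penalty.

    Minimizes (per element)  t * log(1 + |x|/a) + 1/2 (x - v)^2  with
    t = lam/gamma.  ``closed_form`` applies the closed-form expression with
    the max-clamp directly; ``exact`` compares the formula's stationary
    point against 0 and returns the global minimizer.
    """
    if lam_over_gamma <= 0 or a <= 0:
        raise DataError("lam_over_gamma and a must be positive")
    v = np.asarray(v, dtype=float)
    if mode == "closed_form":
        return _prox_log_formula(v, lam_over_gamma, a)
    if mode != "exact":
        raise DataError(f"unknown prox mode {mode!r}")
    t = lam_over_gamma
    u = np.abs(v)
    # stationary points of t*log(1+x/a) + (x-u)^2/2 on x >= 0 solve
    # x^2 + (a-u)x + (t - a*u) = 0; the larger root (if real, positive) is
    # the candidate local minimum, compared against the boundary x = 0.
    disc = (u - a) ** 2 - 4.0 * (t - a * u)
    safe = np.maximum(disc, 0.0)
    root = 0.5 * (u - a + np.sqrt(safe))
    candidate = np.where((disc >= 0.0) & (root > 0.0), root, 0.0)
    obj_cand = t * np.log1p(candidate / a) + 0.5 * (candidate - u) ** 2
    obj_zero = 0.5 * u**2
    x = np.where(obj_cand < obj_zero, candidate, 0.0)
    return np.sign(v) * x


def _lasso_penalty(prob: SparseProblem, w: np.ndarray) -> float:
    return prob.lam * float(np.sum(np.abs(w)))


def _log_penalty(prob: SparseProblem, w: np.ndarray) -> float:
    return prob.lam * float(np.sum(np.log1p(np.abs(w) / prob.a)))


def _iterate(prob: SparseProblem, cfg: SolverConfig, shrink, penalty) -> WeightVector:
    # precomputing the Gram matrix makes each iteration O(P^2) instead of
    # O(NP); the iterates are identical to the X'(Xw - y) form
    gram = prob.X.T @ prob.X
    xty = prob.X.T @ prob.y
    yty = float(prob.y @ prob.y)
    w = np.zeros(prob.X.shape[1])
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        v = w - (gram @ w - xty) / prob.gamma
        w_new = shrink(v)
        quad = 0.5 * (yty - 2.0 * float(w_new @ xty) + float(w_new @ (gram @ w_new)))
        trace.append(quad + penalty(prob, w_new))
        rel = np.linalg.norm(w_new - w) / max(np.linalg.norm(w), 1e-12)
        w = w_new
        if rel <= cfg.tol:
            converged = True
            break
    return WeightVector(
        w=w,
        iterations=it,
        objective_trace=np.asarray(trace),
        converged=converged,
        mode=cfg.mode,
        lam=prob.lam,
    )


def ista_lasso(prob: SparseProblem, cfg: SolverConfig = SolverConfig()) -> WeightVector:
    """Proximal-gradient LASSO: gradient step then soft thresholding.

    Non-convergence within ``max_iter`` is reported via ``converged=False``,
    not raised.
    """
    t = prob.lam / prob.gamma
    return _iterate(prob, cfg, lambda v: soft_threshold(v, t), _lasso_penalty)


def ista_log(prob: SparseProblem, cfg: SolverConfig = SolverConfig()) -> WeightVector:
    """Iterative log thresholding for the non-convex LOG penalty.

    Records the separable objective per iteration; the
    non-separable form ``lam * log(1 + ||w||_1 / a)`` is evaluated on the
    final iterate and stored in ``objective_nonseparable``.
    """
    t = prob.lam / prob.gamma
    result = _iterate(
        prob, cfg, lambda v: prox_log(v, t, prob.a, mode=cfg.mode), _log_penalty
    )
    r = prob.y - prob.X @ result.w
    result.objective_nonseparable = 0.5 * float(r @ r) + prob.lam * float(
        np.log1p(np.sum(np.abs(result.w)) / prob.a)
    )
    return result


class ColumnStandardizer:
    """Column-wise mean/variance standardization fitted on training data.

    Zero-variance columns are left unscaled (divisor 1) so constant
    features pass through as zeros instead of NaN.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, x: np.ndarray) -> "ColumnStandardizer":
        x = np.asarray(x, dtype=float)
        self.mean_ = x.mean(axis=0)
        std = x.std(axis=0)
        self.scale_ = np.where(std > 0, std, 1.0)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise DataError("standardizer not fitted")
        return (np.asarray(x, dtype=float) - self.mean_) / self.scale_

    def fit_transform(self, x: np.ndarray) -> np.ndarray:
        return self.fit(x).transform(x)


def _solve(selector: str, x, y, lam, a, cfg) -> WeightVector:
    prob = SparseProblem(X=x, y=y, lam=lam, a=a)
    if selector == "lasso":
        return ista_lasso(prob, cfg)
    if selector == "log":
        return ista_log(prob, cfg)
    raise DataError(f"unknown selector {selector!r}")


def cv_select_lambda(
    x: np.ndarray,
    y: np.ndarray,
    selector: str = "log",
    folds: int = 10,
    grid: np.ndarray | None = None,
    a: float = DEFAULT_A,
    cfg: SolverConfig = SolverConfig(),
    seed: int = 0,
    scoring: str = "flda_accuracy",
):
    """Pick the regularization weight by stratified K-fold grid search.

    For every lambda and fold the selector is fitted on the training folds,
    the nonzero-weight features are kept, a Fisher discriminant is fitted on
    them, and held-out accuracy is scored (an empty support scores 0).  The
    lambda with the best mean score wins; ties break toward the larger
    lambda (the sparser model).  ``scoring='neg_mse'`` scores the regression
    fit itself instead of the downstream classifier.

    Returns ``(lam_star, table)`` where ``table`` is a DataFrame with one
    row per lambda: mean score and mean support size.
    """
    import pandas as pd
    from sklearn.model_selection import StratifiedKFold

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n < folds:
        raise DataError(f"{n} samples cannot be split into {folds} folds")
    if grid is None:
        grid = default_lambda_grid()
    grid = np.asarray(grid, dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(x, y))
    scores = np.zeros((grid.size, folds))
    supports = np.zeros((grid.size, folds))
    for gi, lam in enumerate(grid):
        for fi, (tr, te) in enumerate(splits):
            wv = _solve(selector, x[tr], y[tr], lam, a, cfg)
            sup = wv.support()
            supports[gi, fi] = sup.size
            if scoring == "neg_mse":
                resid = y[te] - x[te] @ wv.w
                scores[gi, fi] = -float(np.mean(resid**2))
                continue
            if sup.size == 0:
                scores[gi, fi] = 0.0
                continue
            try:
                model = flda_fit(x[tr][:, sup], y[tr].astype(int))
            except Exception:
                scores[gi, fi] = 0.0
                continue
            pred = flda_predict(model, x[te][:, sup])
            scores[gi, fi] = float(np.mean(pred == y[te].astype(int)))
    mean_scores = scores.mean(axis=1)
    best = mean_scores.max()
    lam_star = float(grid[np.flatnonzero(mean_scores == best).max()])
    table = pd.DataFrame(
        {
            "lambda": grid,
            "mean_score": mean_scores,
            "mean_support": supports.mean(axis=1),
        }
    )
    return lam_star, table
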