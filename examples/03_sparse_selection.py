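"""Compare LASSO and the non-convex LOG penalty on a known sparse problem.

Builds a regression problem whose targets depend on 3 of 60 standardized
features, then fits both selectors at the same regularization weight.  The
log penalty shrinks the surviving weights less (debiasing) while both
should locate the informative columns; the printed support sizes and
weight magnitudes make the difference visible.
"""

import numpy as np

from cspdecode import ColumnStandardizer, SolverConfig, SparseProblem, ista_lasso, ista_log

rng = np.random.default_rng(0)
n, p = 80, 60
w_true = np.zeros(p)
w_true[:3] = [1.5, -1.0, 0.8]
x = rng.standard_normal((n, p))
y = x @ w_true + 0.2 * rng.standard_normal(n)
x = ColumnStandardizer().fit_transform(x)

lam = 4.0
lasso = ista_lasso(SparseProblem(X=x, y=y, lam=lam), SolverConfig(tol=1e-8))
log = ista_log(SparseProblem(X=x, y=y, lam=lam), SolverConfig(tol=1e-8))

print(f"true support: {np.flatnonzero(w_true).tolist()}, lam = {lam}")
for name, wv in (("LASSO", lasso), ("LOG  ", log)):
    sup = wv.support()
    print(f"{name}: support size {sup.size:2d}, contains true support: "
          f"{set(range(3)) <= set(sup.tolist())}, "
          f"weights on true support {np.round(wv.w[:3], 3).tolist()} "
          f"({wv.iterations} iterations, converged={wv.converged})")
print("the LOG weights are shrunk less toward zero than the LASSO weights "
      f"(true values {w_true[:3].tolist()}), at the cost of a larger support.")
print(f"final LOG objective (separable form): {log.objective_trace[-1]:.4f}; "
      f"non-separable form: {log.objective_nonseparable:.4f}")
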