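"""Reference-based blood cell-type deconvolution (Houseman-style projection).

Each sample's beta profile over a reference probe panel is projected onto
the cell-type reference profiles by constrained least squares:

    minimize  || beta_s - R w ||^2   s.t.  w >= 0,  sum(w) <= 1

(optionally sum(w) == 1). The problem is a small convex QP (one weight per
cell type); it is solved with SLSQP to a 1e-8 constraint tolerance, which
meets the optimality contract checked against grid search in the tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numpy.linalg import matrix_rank
from scipy.optimize import minimize

from .errors import InputError

_CONSTRAINT_TOL = 1e-8


def estimate_proportions(
    beta: pd.DataFrame,
    reference: pd.DataFrame,
    sum_to_one: bool = False,
) -> pd.DataFrame:
    """Estimate per-sample cell-type proportions.

    Parameters
    ----------
    beta
        Probes x samples beta matrix; must contain every reference probe.
    reference
        Reference probes x cell types, mean beta per cell type.
    sum_to_one
        Force the proportions to sum exactly to 1 instead of at most 1.

    Returns
    -------
    DataFrame samples x cell types, non-negative, rows summing to <= 1
    (== 1 under ``sum_to_one``).
    """
    missing = reference.index.difference(beta.index)
    if len(missing) > 0:
        raise InputError(
            f"reference probes absent from beta matrix: {list(missing[:5])}"
        )
    R = reference.to_numpy(float)
    if matrix_rank(R) < R.shape[1]:
        corr = np.corrcoef(R.T)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise InputError(
            "reference is rank-deficient; most collinear cell types: "
            f"{reference.columns[i]} ~ {reference.columns[j]}"
        )

    X = beta.loc[reference.index].to_numpy(float)
    T = R.shape[1]
    RtR = R.T @ R

    if sum_to_one:
        constraints = [{"type": "eq", "fun": lambda w: w.sum() - 1.0}]
    else:
        constraints = [{"type": "ineq", "fun": lambda w: 1.0 - w.sum()}]
    bounds = [(0.0, 1.0)] * T
    w0 = np.full(T, 1.0 / T)

    out = np.empty((X.shape[1], T))
    for s in range(X.shape[1]):
        y = X[:, s]
        Rty = R.T @ y

        def objective(w, RtR=RtR, Rty=Rty):
            return w @ RtR @ w - 2.0 * (Rty @ w)

        def gradient(w, RtR=RtR, Rty=Rty):
            return 2.0 * (RtR @ w - Rty)

        res = minimize(
            objective, w0, jac=gradient, bounds=bounds, constraints=constraints,
            method="SLSQP", options={"maxiter": 500, "ftol": 1e-14},
        )
        w = np.clip(res.x, 0.0, None)
        total = w.sum()
        if total > 1.0 + _CONSTRAINT_TOL:
            w = w / total
        if sum_to_one and total > 0:
            w = w / total
        out[s] = w

    return pd.DataFrame(out, index=beta.columns, columns=reference.columns)
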