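"""Independent reference implementations used only to check the package.

Each oracle is deliberately written by a different route than the
implementation it checks: quadratic programming for the SVM, explicit
normal equations for the weighted fit, pairwise enumeration for AUC, and
a literal step-up scan for Benjamini–Hochberg.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def svm_primal_qp(X: np.ndarray, y: np.ndarray, c: float) -> float:
    """Optimal soft-margin primal objective via an SLSQP-solved QP.

    Variables (w, b, xi) with constraints y_i(w.x_i + b) >= 1 - xi_i,
    xi >= 0.  Suitable for n <= 50, M <= 5.
    """
    n, M = X.shape

    def fun(z):
        return 0.5 * np.dot(z[:M], z[:M]) + c * np.sum(z[M + 1:])

    def jac(z):
        g = np.zeros_like(z)
        g[:M] = z[:M]
        g[M + 1:] = c
        return g

    cons_jac = np.hstack([y[:, None] * X, y[:, None], np.eye(n)])
    cons = [
        {
            "type": "ineq",
            "fun": lambda z: y * (X @ z[:M] + z[M]) - 1 + z[M + 1:],
            "jac": lambda z: cons_jac,
        }
    ]
    bounds = [(None, None)] * (M + 1) + [(0, None)] * n
    z0 = np.zeros(M + 1 + n)
    z0[M + 1:] = 1.0
    res = minimize(
        fun, z0, jac=jac, constraints=cons, bounds=bounds,
        method="SLSQP", options={"maxiter": 1000, "ftol": 1e-14},
    )
    return float(res.fun)


def wls_normal_equations(x: np.ndarray, r: np.ndarray, exponent: float):
    """(slope, intercept) of weighted least squares by explicit 2×2 solve."""
    w = np.ones_like(x) if exponent == 0 else x ** (-float(exponent))
    sw = w.sum()
    sx = (w * x).sum()
    sxx = (w * x * x).sum()
    sr = (w * r).sum()
    sxr = (w * x * r).sum()
    det = sw * sxx - sx * sx
    slope = (sw * sxr - sx * sr) / det
    intercept = (sxx * sr - sx * sxr) / det
    return slope, intercept


def auc_pairwise(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by enumerating all positive/negative pairs, ties counted 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == -1]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def bh_rejections(pvalues: np.ndarray, q: float) -> np.ndarray:
    """BH rejection set by the literal rule: largest k with p_(k) <= k q/m."""
    m = len(pvalues)
    order = np.argsort(pvalues, kind="stable")
    sorted_p = pvalues[order]
    k_star = 0
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= k * q / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject
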