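"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's factorized code paths: dense covariance
matrices, explicit inverses and log-determinants, exhaustive grids.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def dense_restricted_loglik(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> float:
    """Textbook REML log-likelihood with dense linear algebra."""
    n = len(y)
    p = X.shape[1] if X.size else 0
    _, ld_v = np.linalg.slogdet(V)
    Vi = np.linalg.inv(V)
    if p:
        A = X.T @ Vi @ X
        _, ld_a = np.linalg.slogdet(A)
        b = X.T @ Vi @ y
        quad = float(y @ Vi @ y - b @ np.linalg.solve(A, b))
    else:
        ld_a = 0.0
        quad = float(y @ Vi @ y)
    return -0.5 * (ld_v + ld_a + quad + (n - p) * np.log(2 * np.pi))


def build_dense_V(Z, W, d, theta, lam2, sig2):
    Sigma = np.linalg.inv(np.diag(d) - theta * W)
    return lam2 * Z @ Sigma @ Z.T + sig2 * np.eye(Z.shape[0])


def grid_reml_oracle(y, X, Z, W, d, theta_grid=None):
    """Exhaustive (theta, lambda^2, sigma_e^2) grid search followed by a
    Nelder-Mead polish of (lambda^2, sigma_e^2) at the best theta."""
    if theta_grid is None:
        theta_grid = np.arange(0.0, 1.0, 0.05)
    best, arg = -np.inf, None
    for th in theta_grid:
        for l2 in np.logspace(-5, 2, 36):
            for s2 in np.logspace(-3, 2, 26):
                ll = dense_restricted_loglik(y, X, build_dense_V(Z, W, d, th, l2, s2))
                if ll > best:
                    best, arg = ll, (th, l2, s2)
    th = arg[0]
    res = minimize(
        lambda v: -dense_restricted_loglik(
            y, X, build_dense_V(Z, W, d, th, np.exp(v[0]), np.exp(v[1]))
        ),
        np.log(arg[1:]),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    # also polish with lambda^2 pinned to the boundary
    ll_boundary = -np.inf
    from scipy.optimize import minimize_scalar

    rb = minimize_scalar(
        lambda v: -dense_restricted_loglik(
            y, X, build_dense_V(Z, W, d, th, 0.0, np.exp(v))
        ),
        bounds=(-8, 5), method="bounded", options={"xatol": 1e-12},
    )
    ll_boundary = -rb.fun
    return max(-res.fun, ll_boundary), arg


def naive_gls_excluding_state(y, design, weights, vc, state: int):
    """Per-state GLS through explicit dense matrix inversion, removing the
    state's cells from the random-effect covariance (marginal sub-block)."""
    Pinv = np.linalg.inv(np.diag(weights.d) - vc.theta * weights.W)
    Sigma = vc.lambda2 * Pinv
    keep = np.ones(design.k_cells, dtype=bool)
    keep[design.state_members[state]] = False
    Zr = design.Z[:, keep]
    Vi_mat = Zr @ Sigma[np.ix_(keep, keep)] @ Zr.T + vc.sigma_e2 * np.eye(design.n_genes)
    Vinv = np.linalg.inv(Vi_mat)
    G = np.column_stack([design.X[:, state], design.C])
    return np.linalg.solve(G.T @ Vinv @ G, G.T @ Vinv @ y)[0]
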