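"""Mixed-model core: REML fit of the null covariance, GLS plug-in estimation of
per-state abundances, boundary likelihood-ratio test of the random effect, and
smoothing/normalization of the abundance profile.

Model per bulk sample, for focal state i:

    y = x_i beta_i + C gamma + Z alpha + e,
    alpha ~ N(0, (D - theta W)^-1 lambda^2),   e ~ N(0, I sigma_e^2),

so y ~ N(x_i beta_i + C gamma, V) with V = Z (D - theta W)^-1 lambda^2 Z' + I sigma_e^2.
The conditional-autoregressive structure (D - theta W) couples the per-cell random
effects along the trajectory.  Estimating V for every focal state is wasteful; the
variance components are estimated once under the null (all focal cells random,
no focal fixed effect) and the resulting V-hat is plugged into GLS for each state.

In the per-state (alternative) model the random effects are the *remaining* focal
cells: the focal state's own cells move from the random term into the fixed
profile x_i.  The per-state covariance therefore drops state i's rows/columns of
Sigma — a rank-2c correction (c = cells in the state) to the null V, handled by a
Woodbury identity so the big factorization is still computed only once.

Numerics: for each theta on the profiling grid, K(theta) = Z (D - theta W)^-1 Z' is
eigendecomposed once (via an SVD of Z L^-T with L the Cholesky factor of the
precision), so V = lambda^2 K + sigma_e^2 I is diagonal in that basis.  All
restricted-likelihood evaluations and all per-state GLS solves reuse the
factorization; the dense inverse of V is never formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .reference import StateDesign, TrajectoryWeights

__all__ = [
    "VarianceComponents",
    "AbundanceMatrix",
    "NullModelWorkspace",
    "fit_null_reml",
    "estimate_state_abundances",
    "estimate_state_abundances_exact",
    "test_random_effect",
    "smooth_abundances",
    "normalize_abundances",
    "default_theta_grid",
    "restricted_loglik",
]

_LOG2PI = np.log(2.0 * np.pi)


def default_theta_grid() -> np.ndarray:
    """Profiling grid {0, 0.05, ..., 0.95} for the CAR dependence parameter."""
    return np.arange(0.0, 1.0, 0.05)


@dataclass
class VarianceComponents:
    """REML estimates (theta, lambda^2, sigma_e^2) and the implied covariance.

    ``loglik_no_random`` is the restricted log-likelihood at the lambda^2 = 0
    boundary (needed for the mixture LRT).  The eigen-representation of
    K(theta-hat) is kept so GLS solves never form V^-1 densely.
    """

    theta: float
    lambda2: float
    sigma_e2: float
    loglik_reml: float
    loglik_no_random: float
    n_genes: int
    _U: np.ndarray = field(repr=False)
    _s: np.ndarray = field(repr=False)

    @property
    def V(self) -> np.ndarray:
        """Dense n x n covariance Z (D - theta W)^-1 lambda^2 Z' + I sigma_e^2."""
        K = (self._U * self._s) @ self._U.T
        return self.lambda2 * K + self.sigma_e2 * np.eye(self.n_genes)

    def vinv_apply(self, A: np.ndarray) -> np.ndarray:
        """Apply V^-1 to a vector/matrix through the eigen factorization."""
        w = self.lambda2 * self._s + self.sigma_e2
        c = self.lambda2 * self._s / w
        UA = self._U.T @ A
        return (A - self._U @ (c[..., None] * UA if A.ndim > 1 else c * UA)) / self.sigma_e2


@dataclass
class AbundanceMatrix:
    """Per-state abundance estimates for one bulk sample: raw GLS estimates with
    standard errors, the smoothed profile, and the rescaled (0..1, sum-to-one)
    fractions.  Raw estimates are unconstrained by design."""

    raw: np.ndarray
    se: np.ndarray
    smoothed: np.ndarray
    normalized: np.ndarray
    state_pseudotime: np.ndarray
    gamma_hat: np.ndarray


def _profiled_negloglik(
    delta: float,
    uy: np.ndarray,
    yy: float,
    UX: np.ndarray,
    Xy: np.ndarray,
    XX: np.ndarray,
    s: np.ndarray,
    n: int,
    p: int,
) -> tuple[float, float]:
    """Negative restricted log-likelihood profiled over sigma^2 at variance ratio
    delta = lambda^2 / sigma_e^2.  Returns (negloglik, sigma2_hat)."""
    w1 = 1.0 + delta * s
    c = delta * s / w1
    ld_v1 = float(np.log(w1).sum())
    y_v1_y = yy - float(uy @ (c * uy))
    if p:
        A = XX - UX.T @ (c[:, None] * UX)
        b = Xy - UX.T @ (c * uy)
        sign, ld_A = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf, np.nan
        try:
            q = y_v1_y - float(b @ np.linalg.solve(A, b))
        except np.linalg.LinAlgError:
            return np.inf, np.nan
    else:
        ld_A = 0.0
        q = y_v1_y
    if q <= 0:
        return np.inf, np.nan
    sigma2 = q / (n - p)
    ll = -0.5 * ((n - p) * (np.log(sigma2) + 1.0 + _LOG2PI) + ld_v1 + ld_A)
    return -ll, sigma2


def restricted_loglik(
    y: np.ndarray,
    X: np.ndarray,
    V: np.ndarray,
) -> float:
    """Restricted log-likelihood of y ~ N(X b, V) for arbitrary dense V.

    Reference formula used for cross-checks; the fitting path never calls it.
    """
    n = len(y)
    p = X.shape[1] if X.size else 0
    L = cholesky(V, lower=True)
    yi = solve_triangular(L, y, lower=True)
    ld_v = 2.0 * float(np.log(np.diag(L)).sum())
    if p:
        Xi = solve_triangular(L, X, lower=True)
        A = Xi.T @ Xi
        sign, ld_A = np.linalg.slogdet(A)
        b = Xi.T @ yi
        quad = float(yi @ yi) - float(b @ np.linalg.solve(A, b))
    else:
        ld_A = 0.0
        quad = float(yi @ yi)
    return -0.5 * (ld_v + ld_A + quad + (n - p) * _LOG2PI)


class NullModelWorkspace:
    """Per-(design, weights) cache of the theta-grid eigendecompositions.

    Building the workspace costs one Cholesky + SVD per grid point; every
    subsequent REML fit (any bulk vector, any permutation of it) reuses them.
    """

    def __init__(
        self,
        design: StateDesign,
        weights: TrajectoryWeights,
        theta_grid: np.ndarray | None = None,
        inner_xatol: float = 1e-7,
    ) -> None:
        self.design = design
        self.C = design.C
        self.theta_grid = (
            default_theta_grid() if theta_grid is None else np.asarray(theta_grid, float)
        )
        self.inner_xatol = float(inner_xatol)
        self.n = design.n_genes
        self.p = design.C.shape[1]
        self._decomps: list[tuple[float, np.ndarray, np.ndarray, np.ndarray]] = []
        self._chol: dict[float, np.ndarray] = {}
        self._pinv_cache: dict[float, np.ndarray] = {}
        Z = design.Z
        for theta in self.theta_grid:
            P = weights.precision(float(theta))
            try:
                L = cholesky(P, lower=True)
            except np.linalg.LinAlgError:
                warnings.warn(f"(D - theta W) not PD at theta={theta}; grid point skipped")
                continue
            B = solve_triangular(L, Z.T, lower=True).T
            U, sv, _ = np.linalg.svd(B, full_matrices=False)
            s = sv**2
            UC = U.T @ self.C if self.p else np.empty((U.shape[1], 0))
            self._decomps.append((float(theta), U, s, UC))
            self._chol[float(theta)] = L
        if not self._decomps:
            raise RuntimeError("no positive-definite (D - theta W) on the theta grid")
        self._XX = self.C.T @ self.C if self.p else np.empty((0, 0))

    def car_inverse(self, theta: float) -> np.ndarray:
        """(D - theta W)^-1, cached per grid point (scale-free part of Sigma)."""
        if theta not in self._pinv_cache:
            L = self._chol[theta]
            eye = np.eye(L.shape[0])
            Li = solve_triangular(L, eye, lower=True)
            self._pinv_cache[theta] = Li.T @ Li
        return self._pinv_cache[theta]

    def fit(self, y: np.ndarray) -> VarianceComponents:
        """REML fit of (theta, lambda^2, sigma_e^2) for one bulk vector.

        theta is profiled over the grid; at each grid point the variance ratio
        delta = lambda^2 / sigma_e^2 is optimized by bounded scalar search on the
        log scale with sigma^2 concentrated out analytically.  The lambda^2 = 0
        boundary is always evaluated explicitly.
        """
        y = np.asarray(y, dtype=float)
        if len(y) != self.n:
            raise ValueError("bulk vector length does not match design genes")
        yy = float(y @ y)
        Xy = self.C.T @ y if self.p else np.empty(0)

        # lambda^2 = 0 boundary: theta drops out of the model entirely.
        theta0, U0, s0, UC0 = self._decomps[0]
        uy0 = U0.T @ y
        nll0, sig0 = _profiled_negloglik(
            0.0, uy0, yy, UC0, Xy, self._XX, s0, self.n, self.p
        )
        if not np.isfinite(nll0):
            raise RuntimeError("restricted likelihood undefined at lambda^2 = 0")
        loglik_no_random = -nll0

        best = (loglik_no_random, theta0, 0.0, sig0, U0, s0)
        for theta, U, s, UC in self._decomps:
            uy = U.T @ y

            def obj(log_delta: float) -> float:
                return _profiled_negloglik(
                    np.exp(log_delta), uy, yy, UC, Xy, self._XX, s, self.n, self.p
                )[0]

            res = minimize_scalar(
                obj, bounds=(-14.0, 14.0), method="bounded",
                options={"xatol": self.inner_xatol},
            )
            if not np.isfinite(res.fun):
                continue
            delta = float(np.exp(res.x))
            nll, sig2 = _profiled_negloglik(
                delta, uy, yy, UC, Xy, self._XX, s, self.n, self.p
            )
            if -nll > best[0]:
                best = (-nll, theta, delta, sig2, U, s)

        loglik, theta_hat, delta_hat, sig2_hat, U, s = best
        return VarianceComponents(
            theta=theta_hat,
            lambda2=delta_hat * sig2_hat,
            sigma_e2=sig2_hat,
            loglik_reml=loglik,
            loglik_no_random=loglik_no_random,
            n_genes=self.n,
            _U=U,
            _s=s,
        )

    def fit_alternative(self, y: np.ndarray, X: np.ndarray) -> VarianceComponents:
        """Full REML refit with an arbitrary fixed-effect design ``X`` (slow path;
        used to validate the null-V plug-in approximation)."""
        y = np.asarray(y, dtype=float)
        X = np.atleast_2d(X)
        p = X.shape[1]
        yy = float(y @ y)
        Xy = X.T @ y
        XX = X.T @ X
        best = None
        loglik_no_random = None
        for theta, U, s, _ in self._decomps:
            uy = U.T @ y
            UX = U.T @ X

            def obj(log_delta: float) -> float:
                return _profiled_negloglik(
                    np.exp(log_delta), uy, yy, UX, Xy, XX, s, self.n, p
                )[0]

            nll0, sig0 = _profiled_negloglik(0.0, uy, yy, UX, Xy, XX, s, self.n, p)
            if loglik_no_random is None and np.isfinite(nll0):
                loglik_no_random = -nll0
                best = (-nll0, theta, 0.0, sig0, U, s)
            res = minimize_scalar(
                obj, bounds=(-14.0, 14.0), method="bounded",
                options={"xatol": self.inner_xatol},
            )
            delta = float(np.exp(res.x))
            nll, sig2 = _profiled_negloglik(delta, uy, yy, UX, Xy, XX, s, self.n, p)
            if np.isfinite(nll) and (best is None or -nll > best[0]):
                best = (-nll, theta, delta, sig2, U, s)
        if best is None:
            raise RuntimeError("REML failed at every theta grid point")
        loglik, theta_hat, delta_hat, sig2_hat, U, s = best
        return VarianceComponents(
            theta=theta_hat,
            lambda2=delta_hat * sig2_hat,
            sigma_e2=sig2_hat,
            loglik_reml=loglik,
            loglik_no_random=loglik_no_random if loglik_no_random is not None else np.nan,
            n_genes=self.n,
            _U=U,
            _s=s,
        )


def fit_null_reml(
    y: np.ndarray,
    design: StateDesign,
    weights: TrajectoryWeights,
    theta_grid: np.ndarray | None = None,
) -> VarianceComponents:
    """Fit the null model y ~ N(C gamma, Z Sigma Z' + I sigma_e^2) by REML.

    Convenience wrapper building a single-use :class:`NullModelWorkspace`; batch
    callers should build the workspace once and call its ``fit`` repeatedly.
    """
    return NullModelWorkspace(design, weights, theta_grid=theta_grid).fit(y)


def estimate_state_abundances(
    y: np.ndarray,
    design: StateDesign,
    vc: VarianceComponents,
    workspace: "NullModelWorkspace | None" = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """GLS estimates of every focal-state abundance with V-hat held fixed.

    For each state i the fixed design is [x_i, C] and
    beta-hat = ([x_i C]' V^-1 [x_i C])^-1 [x_i C]' V^-1 y with the variance
    parameters (theta, lambda^2, sigma_e^2) frozen at the null fit.  When
    ``workspace`` is given, state i's cells are removed from the random term (they
    are represented by the fixed profile x_i); the removal is a rank-2c Woodbury
    correction to the cached null factorization, never a refactorization.  Without
    a workspace the null V is used unchanged for every state.

    V^-1 products are computed once through the eigen factorization and shared
    across the m solves.  A state whose normal matrix is singular yields NaN with
    a warning rather than failing the whole profile.  Returns (raw, se, gamma_hat)
    where gamma_hat is the null-model GLS estimate of the other-cell-type effects.
    """
    y = np.asarray(y, dtype=float)
    X = design.X
    C = design.C
    Z = design.Z
    m = X.shape[1]
    p = C.shape[1]

    ViX = vc.vinv_apply(X)
    Viy = vc.vinv_apply(y)
    xx = np.einsum("ij,ij->j", X, ViX)
    xy = X.T @ Viy
    if p:
        ViC = vc.vinv_apply(C)
        xC = X.T @ ViC
        CC = C.T @ ViC
        Cy = C.T @ Viy
        gamma = np.linalg.solve(CC, Cy)
    else:
        ViC = np.empty((len(y), 0))
        xC = np.empty((m, 0))
        CC = np.empty((0, 0))
        Cy = np.empty(0)
        gamma = np.empty(0)

    pinv = workspace.car_inverse(vc.theta) if workspace is not None else None

    raw = np.full(m, np.nan)
    se = np.full(m, np.nan)
    n_failed = 0
    for i in range(m):
        G = np.empty((1 + p, 1 + p))
        G[0, 0] = xx[i]
        if p:
            G[0, 1:] = xC[i]
            G[1:, 0] = xC[i]
            G[1:, 1:] = CC
        rhs = np.concatenate(([xy[i]], Cy))

        if pinv is not None:
            # Woodbury: V_i = V - F S F' with F = [Z_J, Z Sigma[:, J]] spanning the
            # covariance contribution of state i's cells (J), c = |J|.
            J = design.state_members[i]
            c = len(J)
            sig_cols = vc.lambda2 * pinv[:, J]
            M = Z @ sig_cols
            sig_JJ = sig_cols[J, :]
            F = np.hstack([Z[:, J], M])
            ViF = vc.vinv_apply(F)
            S_inv = np.block(
                [[np.zeros((c, c)), np.eye(c)], [np.eye(c), sig_JJ]]
            )
            mid = S_inv - F.T @ ViF
            GtViF = np.vstack([ViX[:, i] @ F, ViC.T @ F]) if p else (ViX[:, i] @ F)[None, :]
            ytViF = Viy @ F
            try:
                sol = np.linalg.solve(mid, np.column_stack([GtViF.T, ytViF]))
            except np.linalg.LinAlgError:
                n_failed += 1
                continue
            G = G + GtViF @ sol[:, :-1]
            rhs = rhs + GtViF @ sol[:, -1]

        try:
            cov = np.linalg.inv(G)
        except np.linalg.LinAlgError:
            n_failed += 1
            continue
        if cov[0, 0] <= 0 or not np.isfinite(cov[0, 0]):
            n_failed += 1
            continue
        est = cov @ rhs
        raw[i] = est[0]
        se[i] = np.sqrt(cov[0, 0])
    if n_failed:
        warnings.warn(f"GLS normal matrix singular for {n_failed} state(s); set to NaN")
    return raw, se, gamma


def estimate_state_abundances_exact(
    y: np.ndarray,
    design: StateDesign,
    workspace: NullModelWorkspace,
) -> np.ndarray:
    """Slow reference path: refit the variance components for every focal state
    with [x_i, C] as the fixed design and the remaining cells as random effects,
    then solve that state's GLS.  Exists to quantify the accuracy of the null-V
    plug-in approximation; quadratic in m, use on small instances only."""
    y = np.asarray(y, dtype=float)
    m = design.m_states
    n = design.n_genes
    raw = np.full(m, np.nan)
    for i in range(m):
        Xi = np.column_stack([design.X[:, i], design.C])
        p = Xi.shape[1]
        keep = np.ones(design.k_cells, dtype=bool)
        keep[design.state_members[i]] = False
        Zr = design.Z[:, keep]
        yy = float(y @ y)
        Xy = Xi.T @ y
        XX = Xi.T @ Xi
        best = None
        for theta, _, _, _ in workspace._decomps:
            sig_rr = workspace.car_inverse(theta)[np.ix_(keep, keep)]
            B = Zr @ np.linalg.cholesky(sig_rr)
            U, sv, _ = np.linalg.svd(B, full_matrices=False)
            s = sv**2
            uy = U.T @ y
            UX = U.T @ Xi

            def obj(log_delta: float) -> float:
                return _profiled_negloglik(
                    np.exp(log_delta), uy, yy, UX, Xy, XX, s, n, p
                )[0]

            nll0, sig20 = _profiled_negloglik(0.0, uy, yy, UX, Xy, XX, s, n, p)
            if np.isfinite(nll0) and (best is None or -nll0 > best[0]):
                best = (-nll0, 0.0, sig20, U, s)
            res = minimize_scalar(
                obj, bounds=(-14.0, 14.0), method="bounded",
                options={"xatol": workspace.inner_xatol},
            )
            delta = float(np.exp(res.x))
            nll, sig2 = _profiled_negloglik(delta, uy, yy, UX, Xy, XX, s, n, p)
            if np.isfinite(nll) and (best is None or -nll > best[0]):
                best = (-nll, delta, sig2, U, s)
        if best is None:
            continue
        _, delta, sig2, U, s = best
        lam2 = delta * sig2
        w = lam2 * s + sig2
        cfac = lam2 * s / w
        ViX = (Xi - U @ (cfac[:, None] * (U.T @ Xi))) / sig2
        G = Xi.T @ ViX
        try:
            raw[i] = np.linalg.solve(G, ViX.T @ y)[0]
        except np.linalg.LinAlgError:
            pass
    return raw


def test_random_effect(vc: VarianceComponents) -> float:
    """Boundary likelihood-ratio test of lambda^2 = 0 against lambda^2 > 0.

    The LRT statistic is referred to a 50:50 mixture of chi2_0 and chi2_1 (the
    parameter sits on the boundary under the null), i.e. p = 0.5 * P(chi2_1 >= LRT),
    which equals 0.5 when the statistic is exactly zero.
    """
    lrt = max(0.0, 2.0 * (vc.loglik_reml - vc.loglik_no_random))
    return float(0.5 * chi2.sf(lrt, df=1))


def smooth_abundances(
    raw: np.ndarray,
    state_pseudotime: np.ndarray,
    method: str = "loess",
    span: float = 0.35,
    q: int | None = None,
) -> np.ndarray:
    """Smooth a per-state abundance profile along the trajectory.

    ``loess``: local quadratic regression with tricube weights over the nearest
    ``span`` fraction of states.  ``knn``: symmetric average of the q nearest
    states; the default window is a fixed 15% fraction of the trajectory,
    q = max(3, round(0.15 m)), comparable in effective width to the loess span.
    ``none``: identity.  NaN states are ignored in the local fits.
    """
    raw = np.asarray(raw, dtype=float)
    t = np.asarray(state_pseudotime, dtype=float)
    m = len(raw)
    if method == "none":
        return raw.copy()
    valid = np.isfinite(raw)
    if method == "knn":
        if q is None:
            q = max(3, round(0.15 * m))
        if not 1 <= q <= m:
            raise ValueError(f"q must be in [1, {m}], got {q}")
        out = np.empty(m)
        for i in range(m):
            nearest = np.argsort(np.abs(t - t[i]), kind="stable")[:q]
            vals = raw[nearest][valid[nearest]]
            out[i] = vals.mean() if len(vals) else np.nan
        return out
    if method != "loess":
        raise ValueError(f"unknown smoothing method {method!r}")
    if not 0.0 < span <= 1.0:
        raise ValueError(f"span must be in (0, 1], got {span}")
    k = max(4, int(np.ceil(span * m)))
    out = np.empty(m)
    for i in range(m):
        nearest = np.argsort(np.abs(t - t[i]), kind="stable")[:k]
        nearest = nearest[valid[nearest]]
        if len(nearest) == 0:
            out[i] = np.nan
            continue
        dt = t[nearest] - t[i]
        h = np.max(np.abs(dt))
        w = (1.0 - np.minimum(np.abs(dt) / h, 1.0) ** 3) ** 3 if h > 0 else np.ones_like(dt)
        w = np.maximum(w, 1e-8)
        deg = 2 if len(nearest) >= 4 else min(1, len(nearest) - 1)
        A = np.vander(dt, deg + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(A * sw[:, None], raw[nearest] * sw, rcond=None)
        out[i] = coef[0]
    return out


def normalize_abundances(raw: np.ndarray) -> np.ndarray:
    """Rescale raw estimates to [0, 1] summing to one: negatives are truncated at
    zero, then the profile is divided by its sum."""
    v = np.clip(np.asarray(raw, dtype=float), 0.0, None)
    v = np.where(np.isfinite(v), v, 0.0)
    total = v.sum()
    if total <= 0:
        raise ValueError("degenerate abundance profile: no positive values to rescale")
    return v / total
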