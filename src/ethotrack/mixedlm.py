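"""Weighted linear mixed model with independent variance components.

Fits, by REML, the model

    y = X beta + sum_k Z_k u_k + e,   u_k ~ N(0, sigma2_k I),
                                      e ~ N(0, phi W^{-1})

where ``W`` is a diagonal matrix of known weights and the ``Z_k`` are
indicator matrices of crossed grouping factors (plants of either genotype,
trial).  This is the inner engine of both choice models: the log-ratio model
uses it directly with unit weights, and the quasi-binomial logit model calls
it repeatedly on a linearized working response inside the iterative
re-weighted REML (IRREML) loop, where ``phi`` plays the role of the
quasi-likelihood dispersion.

Problem sizes here are small (tens of arenas, a handful of variance
components), so the implementation works with dense n x n covariance matrices
and profiles out ``phi``: with V0(gamma) = W^{-1} + sum_k gamma_k Z_k Z_k',
gamma_k = sigma2_k / phi, the REML criterion

    f(gamma) = log|V0| + log|X' V0^{-1} X| + (n - p) log(y' P0 y)

is minimized over gamma >= 0 and phi is recovered as y' P0 y / (n - p).

Tests and intervals on a scalar contrast c'beta use the Satterthwaite
approximation: with g(theta) = c' (X' V(theta)^{-1} X)^{-1} c and theta the
variance parameters (sigma2_1..sigma2_K, phi),

    df = 2 g^2 / (grad g' A grad g),

where A is the asymptotic covariance of theta_hat, taken as the inverse of
the negative Hessian of the REML log-likelihood at theta_hat (finite
differences).  Components estimated on the zero boundary are held fixed and
dropped from theta for this computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = ["WeightedLMMResult", "fit_weighted_lmm", "satterthwaite_df"]


@dataclass
class WeightedLMMResult:
    beta: np.ndarray
    cov_beta: np.ndarray          # phi * (X' V0^-1 X)^-1
    phi: float                    # residual dispersion
    gamma: np.ndarray             # variance ratios sigma2_k / phi
    sigma2: np.ndarray            # sigma2_k = phi * gamma_k
    blups: list[np.ndarray]       # predicted random effects per component
    fitted_eta: np.ndarray        # X beta + sum Z_k u_k
    loglik: float                 # REML log-likelihood (up to constant)
    n: int
    p: int
    converged: bool
    re_names: list[str] = field(default_factory=list)


def _v0(gamma, winv, ZZ):
    V0 = np.diag(winv).astype(float)
    for g, M in zip(gamma, ZZ):
        if g > 0:
            V0 += g * M
    return V0


def _reml_pieces(V0, X, y):
    """Return (log|V0|, log|X'V0iX|, y'P0y, beta_hat, XtViX_inv, V0inv)."""
    L = np.linalg.cholesky(V0)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    Vi_X = np.linalg.solve(V0, X)
    Vi_y = np.linalg.solve(V0, y)
    XtViX = X.T @ Vi_X
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X not positive definite")
    XtViX_inv = np.linalg.inv(XtViX)
    beta = XtViX_inv @ (X.T @ Vi_y)
    r = y - X @ beta
    quad = float(r @ np.linalg.solve(V0, r))
    return logdet, logdet_x, quad, beta, XtViX_inv


def fit_weighted_lmm(y, X, Z_list, weights=None, re_names=None,
                     gamma0=None) -> WeightedLMMResult:
    """REML fit of the weighted variance-components model.

    Parameters
    ----------
    y : (n,) response.
    X : (n, p) fixed-effect design.
    Z_list : list of (n, q_k) indicator matrices (may be empty).
    weights : (n,) known precision weights; residual variance is phi/w_i.
    gamma0 : optional warm start for the variance ratios (used by the IRREML
        loop, whose successive inner problems barely move).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than fixed effects")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    winv = 1.0 / w
    ZZ = [np.asarray(Z, dtype=float) @ np.asarray(Z, dtype=float).T
          for Z in Z_list]
    K = len(ZZ)

    def crit(gamma):
        V0 = _v0(gamma, winv, ZZ)
        try:
            logdet, logdet_x, quad, _, _ = _reml_pieces(V0, X, y)
        except np.linalg.LinAlgError:
            return 1e12
        if quad <= 0:
            return 1e12
        return logdet + logdet_x + (n - p) * np.log(quad)

    converged = True
    if K == 0:
        gamma = np.zeros(0)
    else:
        if gamma0 is not None:
            starts = [np.clip(np.asarray(gamma0, dtype=float), 0.0, 1e6)]
        else:
            starts = [np.full(K, 0.1), np.full(K, 1.0), np.full(K, 1e-3)]
        best = None
        for start in starts:
            res = optimize.minimize(
                crit, start, method="L-BFGS-B",
                bounds=[(0.0, 1e6)] * K,
                options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-9})
            if best is None or res.fun < best.fun - 1e-10:
                best = res
        gamma = np.clip(best.x, 0.0, None)
        converged = bool(best.success) or best.fun < 1e11

    V0 = _v0(gamma, winv, ZZ)
    logdet, logdet_x, quad, beta, XtViX_inv = _reml_pieces(V0, X, y)
    phi = quad / (n - p)
    cov_beta = phi * XtViX_inv
    # BLUPs: u_k = gamma_k Z_k' V0^-1 (y - X beta)
    r = np.linalg.solve(V0, y - X @ beta)
    blups = [g * np.asarray(Z, dtype=float).T @ r
             for g, Z in zip(gamma, Z_list)]
    eta = X @ beta
    for Z, u in zip(Z_list, blups):
        eta = eta + np.asarray(Z, dtype=float) @ u
    loglik = -0.5 * (logdet + logdet_x
                     + (n - p) * (np.log(max(phi, 1e-300)) + 1.0))
    return WeightedLMMResult(
        beta=beta, cov_beta=cov_beta, phi=float(phi), gamma=gamma,
        sigma2=phi * gamma, blups=blups, fitted_eta=eta,
        loglik=float(loglik), n=n, p=p, converged=converged,
        re_names=list(re_names) if re_names else [f"re{k}" for k in range(K)])


# ---------------------------------------------------------------------------
# Satterthwaite degrees of freedom


def _reml_loglik_theta(theta_free, free_idx, theta_full, winv, ZZ, X, y, n, p):
    """REML log-likelihood in the (sigma2_1..sigma2_K, phi) parameterization,
    with only the components in ``free_idx`` varying."""
    th = theta_full.copy()
    th[free_idx] = theta_free
    phi = th[-1]
    if phi <= 0 or np.any(th[:-1] < 0):
        return -1e12
    V = phi * np.diag(winv).astype(float)
    for s2, M in zip(th[:-1], ZZ):
        if s2 > 0:
            V += s2 * M
    try:
        logdet, logdet_x, quad, _, _ = _reml_pieces(V, X, y)
    except np.linalg.LinAlgError:
        return -1e12
    return -0.5 * (logdet + logdet_x + quad)


def satterthwaite_df(result: WeightedLMMResult, y, X, Z_list, weights=None,
                     contrast=None) -> float:
    """Effective degrees of freedom for the t-test of ``contrast' beta``.

    Components estimated at the zero boundary contribute no curvature
    information and are excluded.  Falls back to ``n - p`` residual df when
    the variance of the variance estimates is degenerate (e.g. no random
    effects at all, where the chi-square result df = n - p is exact).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    winv = 1.0 / w
    ZZ = [np.asarray(Z, dtype=float) @ np.asarray(Z, dtype=float).T
          for Z in Z_list]
    c = np.zeros(p)
    c[0] = 1.0
    if contrast is not None:
        c = np.asarray(contrast, dtype=float)

    theta_full = np.append(result.sigma2, result.phi)
    K = theta_full.size - 1
    tol = 1e-8 * max(result.phi, 1e-12)
    free_idx = [k for k in range(K) if theta_full[k] > tol] + [K]
    nf = len(free_idx)

    def g(theta_free):
        th = theta_full.copy()
        th[free_idx] = theta_free
        phi = th[-1]
        V = phi * np.diag(winv).astype(float)
        for s2, M in zip(th[:-1], ZZ):
            if s2 > 0:
                V += s2 * M
        Vi_X = np.linalg.solve(V, X)
        XtViX_inv = np.linalg.inv(X.T @ Vi_X)
        return float(c @ XtViX_inv @ c)

    th0 = theta_full[free_idx]
    steps = np.maximum(1e-4 * np.abs(th0), 1e-7 * max(result.phi, 1e-12))

    if nf == 1:
        # only phi free: no random effects — the exact chi-square df applies
        return float(n - p)

    # gradient of g
    grad = np.zeros(nf)
    for i in range(nf):
        e = np.zeros(nf)
        e[i] = steps[i]
        lo = np.clip(th0 - e, 0.0, None) if free_idx[i] < K else th0 - e
        grad[i] = (g(th0 + e) - g(lo)) / (th0[i] + e[i] - lo[i])

    # negative Hessian of the REML log-likelihood
    def ll(tf):
        return _reml_loglik_theta(tf, free_idx, theta_full, winv, ZZ, X, y,
                                  n, p)
    H = np.zeros((nf, nf))
    f0 = ll(th0)
    for i in range(nf):
        for j in range(i, nf):
            ei = np.zeros(nf); ei[i] = steps[i]
            ej = np.zeros(nf); ej[j] = steps[j]
            if i == j:
                H[i, i] = (ll(th0 + ei) - 2 * f0 + ll(th0 - ei)) / steps[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    ll(th0 + ei + ej) - ll(th0 + ei - ej)
                    - ll(th0 - ei + ej) + ll(th0 - ei - ej)
                ) / (4 * steps[i] * steps[j])
    A = -H
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return float(n - p)
    gval = g(th0)
    denom = float(grad @ Ainv @ grad)
    if denom <= 0 or not np.isfinite(denom):
        return float(n - p)
    df = 2.0 * gval ** 2 / denom
    if not np.isfinite(df) or df <= 0:
        return float(n - p)
    return float(min(df, n - p))
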