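"""Random-intercept Poisson regression for longitudinal count data.

Model: counts y_it for animal i in cell (group g, time window t) follow

    y_it | b_i ~ Poisson(lambda_it),   log lambda_it = x_it' beta + b_i,
    b_i ~ Normal(0, sigma_b^2),

with the random intercept integrated out of the likelihood by Gauss-Hermite
quadrature and (beta, sigma_b) estimated by marginal maximum likelihood.
Standard errors come from the inverse of a finite-difference Hessian of the
marginal log-likelihood (computed from the analytic gradient).  With
sigma_b = 0 the model reduces exactly to a plain Poisson regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special
from scipy.stats import norm

from .core import ParameterError

__all__ = ["PoissonGLMMResult", "fit_poisson_glmm", "poisson_glm_irls"]


@dataclass
class PoissonGLMMResult:
    beta: np.ndarray
    se: np.ndarray
    sigma_b: float
    sigma_b_se: float
    loglik: float
    cov: np.ndarray
    converged: bool
    n_obs: int
    n_subjects: int
    exog_names: list = field(default_factory=list)
    boundary: bool = False          # sigma_b pinned at 0

    def wald_contrast(self, c: np.ndarray):
        """Estimate, SE, z and two-sided p for the linear combination c'beta."""
        c = np.asarray(c, float)
        est = float(c @ self.beta)
        var = float(c @ self.cov[:c.size, :c.size] @ c)
        se = np.sqrt(max(var, 0.0))
        z = est / se if se > 0 else np.inf * np.sign(est or 1.0)
        p = 2 * norm.sf(abs(z))
        return est, se, z, p


def poisson_glm_irls(y, X, tol=1e-10, max_iter=100):
    """Plain Poisson regression by iteratively reweighted least squares."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(y.mean() + 1e-9)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)
        W = mu
        z = eta + (y - mu) / np.maximum(mu, 1e-12)
        XtW = X.T * W
        new = np.linalg.solve(XtW @ X + 1e-10 * np.eye(X.shape[1]), XtW @ z)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return beta


def _marginal_loglik_and_grad(theta, y, X, groups, n_subj, nodes, weights):
    """Negative marginal log-likelihood and gradient; theta = (beta, sigma)."""
    beta, sigma = theta[:-1], theta[-1]
    eta = X @ beta                                       # (n_obs,)
    zk = np.sqrt(2.0) * sigma * nodes                    # (K,)
    eta_k = np.clip(eta[:, None] + zk[None, :], -30, 30)  # (n_obs, K)
    lam = np.exp(eta_k)
    # per-observation Poisson log-kernel (y! term is constant, kept for loglik)
    ll_obs = y[:, None] * eta_k - lam                    # (n_obs, K)
    ll_subj = np.zeros((n_subj, ll_obs.shape[1]))
    for k in range(ll_obs.shape[1]):
        ll_subj[:, k] = np.bincount(groups, weights=ll_obs[:, k],
                                    minlength=n_subj)
    logw = np.log(weights) - 0.5 * np.log(np.pi)
    a = ll_subj + logw[None, :]
    m = special.logsumexp(a, axis=1)                     # (n_subj,)
    loglik = float(m.sum() - special.gammaln(y + 1.0).sum())

    # posterior node weights per subject
    p = np.exp(a - m[:, None])                           # (n_subj, K)
    resid = y[:, None] - lam                             # (n_obs, K)
    p_obs = p[groups, :]                                 # (n_obs, K)
    w_resid = (p_obs * resid)                            # (n_obs, K)
    g_beta = X.T @ w_resid.sum(axis=1)
    g_sigma = float(np.sum(w_resid * (np.sqrt(2.0) * nodes)[None, :]))
    grad = np.concatenate([g_beta, [g_sigma]])
    return -loglik, -grad


def fit_poisson_glmm(y, X, groups, n_quad: int = 20, sigma_max: float = 5.0,
                     exog_names=None) -> PoissonGLMMResult:
    """Fit the random-intercept Poisson model by marginal maximum likelihood.

    Parameters
    ----------
    y : (n_obs,) nonnegative integer counts
    X : (n_obs, p) fixed-effect design matrix (include the intercept)
    groups : (n_obs,) integer subject codes 0..n_subj-1
    n_quad : Gauss-Hermite node count for the random-intercept integral
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    groups = np.asarray(groups)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ParameterError("counts must be nonnegative integers")
    codes, groups = np.unique(groups, return_inverse=True)
    n_subj = codes.size
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)

    beta0 = poisson_glm_irls(y, X)
    x0 = np.concatenate([beta0, [0.3]])
    bounds = [(None, None)] * X.shape[1] + [(0.0, sigma_max)]
    res = optimize.minimize(
        _marginal_loglik_and_grad, x0, jac=True,
        args=(y, X, groups, n_subj, nodes, weights),
        method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    theta = res.x
    boundary = theta[-1] < 1e-6

    cov = _fd_covariance(theta, (y, X, groups, n_subj, nodes, weights),
                         boundary=boundary)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return PoissonGLMMResult(
        beta=theta[:-1], se=se[:-1], sigma_b=float(theta[-1]),
        sigma_b_se=float(se[-1]), loglik=-float(res.fun), cov=cov,
        converged=bool(res.success), n_obs=y.size, n_subjects=int(n_subj),
        exog_names=list(exog_names or []), boundary=bool(boundary))


def _fd_covariance(theta, args, boundary=False, eps=1e-5):
    """Observed-information covariance via central differences of the
    analytic gradient.  At a sigma=0 boundary the sigma row/column is
    dropped from the inversion and refilled with NaN."""
    p = theta.size
    H = np.zeros((p, p))
    for j in range(p):
        tp = theta.copy(); tp[j] += eps
        tm = theta.copy(); tm[j] = max(tm[j] - eps, 0.0) if j == p - 1 else tm[j] - eps
        step = tp[j] - tm[j]
        _, gp = _marginal_loglik_and_grad(tp, *args)
        _, gm = _marginal_loglik_and_grad(tm, *args)
        H[j] = (gp - gm) / step
    H = 0.5 * (H + H.T)
    cov = np.full((p, p), np.nan)
    idx = np.arange(p - 1) if boundary else np.arange(p)
    try:
        sub = np.linalg.inv(H[np.ix_(idx, idx)])
        cov[np.ix_(idx, idx)] = sub
    except np.linalg.LinAlgError:
        pass
    return cov
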