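"""Random-intercept binomial (logit) mixed model via Gauss-Hermite quadrature.

Maximum-likelihood estimation of

    y_gt ~ Binomial(n_gt, logit^{-1}(x_gt' beta + u_g)),   u_g ~ N(0, sigma^2)

by integrating the random intercept out with (non-adaptive) Gauss-Hermite
quadrature and maximizing the marginal log-likelihood with L-BFGS-B.  The
parameter vector is (beta, log sigma); standard errors come from the inverse
numerical Hessian at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln
from statsmodels.tools.numdiff import approx_hess1


class SeparationError(ValueError):
    """Outcome has no variation (or is perfectly separated) — no finite MLE."""


@dataclass
class GLMMFit:
    params: np.ndarray        # fixed-effect coefficients
    se: np.ndarray
    sigma_u: float            # random-intercept SD
    llf: float
    converged: bool
    cov_params: np.ndarray


def _conditional_modes(eta0, y, n, group_idx, n_groups, sigma):
    """Newton solve for the per-group posterior mode of the random intercept.

    Returns (modes, curvatures): the maximizer of
    sum_t [y eta - n log(1+e^eta)] - u^2/(2 sigma^2) and minus its second
    derivative there.
    """
    u = np.zeros(n_groups)
    inv_var = 1.0 / (sigma * sigma)
    info = np.full(n_groups, inv_var)
    for _ in range(100):
        eta = eta0 + u[group_idx]
        p = 1.0 / (1.0 + np.exp(-eta))
        score = np.bincount(group_idx, weights=y - n * p,
                            minlength=n_groups) - u * inv_var
        info = np.bincount(group_idx, weights=n * p * (1.0 - p),
                           minlength=n_groups) + inv_var
        step = score / info
        u = u + np.clip(step, -2.0, 2.0)
        if np.max(np.abs(step)) < 1e-10:
            break
    return u, info


def _marginal_loglike(theta, X, y, n, group_idx, n_groups, nodes, weights):
    """Adaptive Gauss-Hermite marginal log-likelihood.

    Quadrature nodes are recentered at each group's conditional mode and
    rescaled by the local curvature (as in glmer's adaptive nAGQ), which
    keeps the rule accurate even when the per-group posterior is much
    narrower than the random-effect prior.
    """
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)
    eta0 = X @ beta                                     # (n_obs,)
    u_hat, info = _conditional_modes(eta0, y, n, group_idx, n_groups, sigma)
    tau = 1.0 / np.sqrt(info)                           # posterior scale

    # u = u_hat + sqrt(2) tau x  =>  integral = sqrt(2) tau sum w e^{x^2} g(u)
    z = u_hat[:, None] + np.sqrt(2.0) * tau[:, None] * nodes[None, :]
    eta = eta0[:, None] + z[group_idx, :]
    ll_obs = y[:, None] * eta - n[:, None] * np.logaddexp(0.0, eta)
    ll_group = np.zeros((n_groups, nodes.size))
    np.add.at(ll_group, group_idx, ll_obs)
    log_terms = (
        ll_group
        - 0.5 * (z / sigma) ** 2 - np.log(sigma) - 0.5 * np.log(2.0 * np.pi)
        + nodes[None, :] ** 2 + np.log(weights)[None, :]
        + 0.5 * np.log(2.0) + np.log(tau)[:, None]
    )
    m = log_terms.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.sum(np.exp(log_terms - m), axis=1))
    const = float(np.sum(gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)))
    return float(lse.sum()) + const


def fit_binomial_glmm(
    y: np.ndarray,
    n: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    n_quad: int = 25,
    start: np.ndarray | None = None,
) -> GLMMFit:
    """Fit the random-intercept binomial GLMM by quadrature ML.

    Parameters: successes ``y``, trials ``n``, design ``X`` (with intercept
    column), group labels ``groups``.  Raises SeparationError when the
    outcome is all-successes or all-failures overall.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.sum() == 0 or (n - y).sum() == 0:
        raise SeparationError("outcome has no variation; MLE does not exist")

    labels, group_idx = np.unique(np.asarray(groups), return_inverse=True)
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)

    def negll(theta):
        return -_marginal_loglike(theta, X, y, n, group_idx, labels.size, nodes, weights)

    p = X.shape[1]
    if start is None:
        # moment start: pooled GLM-ish coefficients via IRLS-free heuristic
        phat = np.clip((y + 0.5) / (n + 1.0), 1e-4, 1 - 1e-4)
        beta0, *_ = np.linalg.lstsq(X, np.log(phat / (1 - phat)), rcond=None)
        start = np.concatenate([beta0, [np.log(0.7)]])

    res = minimize(negll, start, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-11})
    theta = res.x
    try:
        H = approx_hess1(theta, negll)
        cov_all = np.linalg.inv(H)
        se_all = np.sqrt(np.clip(np.diag(cov_all), 0.0, None))
    except np.linalg.LinAlgError:
        cov_all = np.full((p + 1, p + 1), np.nan)
        se_all = np.full(p + 1, np.nan)
    return GLMMFit(
        params=theta[:p],
        se=se_all[:p],
        sigma_u=float(np.exp(theta[-1])),
        llf=float(-res.fun),
        converged=bool(res.success),
        cov_params=cov_all[:p, :p],
    )
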