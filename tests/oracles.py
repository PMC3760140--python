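"""Independent oracles used by the test suite.

These deliberately share no code with the implementation paths they
check: the marginal likelihood is integrated by adaptive tensor-product
Gauss-Hermite quadrature, and small logistic fits use a general-purpose
optimizer on the raw log-likelihood.
"""

import numpy as np
from scipy import optimize, special


def gh_marginal_loglik(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    beta: np.ndarray,
    Sigma: np.ndarray,
    n_nodes: int = 9,
) -> float:
    """Adaptive Gauss-Hermite marginal log-likelihood of the 4-dim GLMM.

    For each subject the integrand is centred at its posterior mode and
    scaled by the inverse Hessian; a full tensor grid of probabilists'
    Hermite nodes then integrates the random effect exactly enough to
    serve as a reference for the Laplace approximation.
    """
    q = Sigma.shape[0]
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    logw = np.log(weights)
    grids = np.meshgrid(*([nodes] * q), indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    wgrids = np.meshgrid(*([logw] * q), indexing="ij")
    logws = sum(g.ravel() for g in wgrids)
    Sinv = np.linalg.inv(Sigma)
    _, logdetS = np.linalg.slogdet(Sigma)
    total = 0.0
    for g in np.unique(groups):
        m = groups == g
        Xi, yi = X[m], y[m]
        Zi = Xi[:, :q]
        offset = Xi @ beta

        def neg_posterior(b):
            eta = offset + Zi @ b
            return -(np.sum(yi * eta - np.logaddexp(0, eta)) - 0.5 * b @ Sinv @ b)

        bhat = optimize.minimize(neg_posterior, np.zeros(q), method="BFGS").x
        mu = special.expit(offset + Zi @ bhat)
        H = (Zi * (mu * (1 - mu))[:, None]).T @ Zi + Sinv
        C = np.linalg.cholesky(np.linalg.inv(H))
        bs = bhat[None, :] + pts @ C.T
        eta = offset[None, :] + bs @ Zi.T
        cond = np.sum(yi[None, :] * eta - np.logaddexp(0, eta), axis=1)
        prior = (
            -0.5 * np.einsum("ij,jk,ik->i", bs, Sinv, bs)
            - 0.5 * logdetS
            - 0.5 * q * np.log(2 * np.pi)
        )
        _, logdetC = np.linalg.slogdet(C)
        # change of variables b = bhat + C t against the e^{-t't/2} GH weight
        vals = cond + prior + 0.5 * np.einsum("ij,ij->i", pts, pts) + logws + logdetC
        total += special.logsumexp(vals)
    return float(total)


def logistic_mle(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Unpenalized logistic MLE via a generic optimizer (BFGS on -loglik)."""

    def negll(beta):
        eta = X @ beta
        return -np.sum(y * eta - np.logaddexp(0, eta))

    res = optimize.minimize(negll, np.zeros(X.shape[1]), method="BFGS")
    return res.x
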