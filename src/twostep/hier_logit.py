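"""Per-subject and multilevel logistic regression for stay/switch data.

The within-subject model is the 2x2 factorial logistic regression of the
stay outcome on reward, transition and their interaction (plus intercept).
At the group level each of those four effects carries a per-subject random
deviation with an unstructured 4x4 covariance, and may be interacted with
up to two standardized between-subject moderators — the R formulas

    stay ~ trans * rew * extra + (1 + trans * rew | subID)
    stay ~ trans * rew * extra * engage + (1 + trans * rew | subID)

are reproduced by ``moderators=("extra",)`` and
``moderators=("extra", "engage")``.

Estimation maximizes the Laplace approximation to the marginal likelihood.
The random-effect covariance is parameterized through its Cholesky factor
(relative covariance factor Λ with log-parameterized diagonal). For each
candidate (β, θ) the spherical random effects u (b = Λu) are profiled out
by penalized Newton iterations, and the outer optimizer moves the fixed
effects and the 10 covariance parameters jointly against the full Laplace
criterion — the same formulation as lme4's ``glmer`` at nAGQ = 1 (β must
be part of the outer optimization because the Laplace log-determinant
depends on it). Fixed-effect standard errors come from the Schur
complement of the joint (β, u) Hessian at the optimum, conditional on the
estimated covariance; Wald Z and two-sided normal p-values follow.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "BASE_TERMS",
    "build_design",
    "SubjectFit",
    "fit_subject_logistic",
    "intercept_only_deviance",
    "GlmmFit",
    "fit_multilevel",
    "ContrastResult",
    "wald_contrast",
]

#: Within-subject factorial terms; the first four design columns, and the
#: random-effect design, are always these.
BASE_TERMS = ["Intercept", "trans", "rew", "trans:rew"]

_N_RE = 4
_N_THETA = _N_RE + _N_RE * (_N_RE - 1) // 2  # 4 log-diagonals + 6 off-diagonals


def build_design(
    rows: pd.DataFrame, moderators: tuple[str, ...] = ()
) -> tuple[np.ndarray, list[str]]:
    """Build the fixed-effect design matrix for the factorial model.

    Columns are ordered as the within-subject terms (Intercept, trans,
    rew, trans:rew) repeated for every subset of the moderators in the
    order (), (m1,), (m2,), (m1, m2); each block multiplies the base
    columns by the product of that subset's (standardized) covariate
    columns. Returns ``(X, names)``.
    """
    if len(moderators) > 2:
        raise ValueError("at most two moderators are supported")
    n = len(rows)
    base = {
        "Intercept": np.ones(n),
        "trans": rows["trans"].to_numpy(dtype=float),
        "rew": rows["rew"].to_numpy(dtype=float),
        "trans:rew": (rows["trans"] * rows["rew"]).to_numpy(dtype=float),
    }
    cols: list[np.ndarray] = []
    names: list[str] = []
    subsets = [()] + [
        combo
        for r in range(1, len(moderators) + 1)
        for combo in itertools.combinations(moderators, r)
    ]
    for subset in subsets:
        mod_col = np.ones(n)
        for m in subset:
            if m not in rows.columns:
                raise ValueError(f"moderator column '{m}' missing from rows")
            mod_col = mod_col * rows[m].to_numpy(dtype=float)
        for term in BASE_TERMS:
            cols.append(base[term] * mod_col)
            if subset and term == "Intercept":
                names.append(":".join(subset))
            elif subset:
                names.append(":".join([*term.split(":"), *subset]))
            else:
                names.append(term)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X, names


# ---------------------------------------------------------------------------
# per-subject logistic regression


@dataclass
class SubjectFit:
    """Penalized per-subject logistic fit."""

    coefs: np.ndarray
    deviance: float  # unpenalized -2 log-likelihood at the optimum
    converged: bool
    ridge: float
    n_rows: int


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log p(y|eta) = y*eta - log(1 + exp(eta)), stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_subject_logistic(
    rows: pd.DataFrame,
    ridge: float = 1e-4,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> SubjectFit:
    """Fit the 2x2 factorial logistic model to one subject's rows.

    Maximizes the Bernoulli log-likelihood with an L2 penalty of weight
    ``ridge`` on the non-intercept coefficients (keeping estimates finite
    under separation); the reported deviance is the unpenalized
    -2 log-likelihood at the optimum. Requires at least 8 rows.
    """
    if len(rows) < 8:
        raise ValueError(f"need at least 8 rows, got {len(rows)}")
    X, _ = build_design(rows)
    y = rows["stay"].to_numpy(dtype=float)
    pen = ridge * np.array([0.0, 1.0, 1.0, 1.0])
    beta = np.zeros(4)
    f = _bernoulli_loglik(y, X @ beta) - 0.5 * float(pen @ beta**2)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = special.expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        grad = X.T @ (y - mu) - pen * beta
        hess = (X * w[:, None]).T @ X + np.diag(pen)
        step = np.linalg.solve(hess, grad)
        # step-halving line search on the penalized log-likelihood
        t = 1.0
        for _ in range(50):
            cand = beta + t * step
            f_new = _bernoulli_loglik(y, X @ cand) - 0.5 * float(pen @ cand**2)
            if f_new >= f - 1e-14:
                break
            t *= 0.5
        beta, f_old, f = cand, f, f_new
        if abs(f - f_old) < tol * (1.0 + abs(f)) and np.max(np.abs(grad)) < 1e-6:
            converged = True
            break
    deviance = -2.0 * _bernoulli_loglik(y, X @ beta)
    return SubjectFit(
        coefs=beta, deviance=deviance, converged=converged, ridge=ridge, n_rows=len(rows)
    )


def intercept_only_deviance(stay: np.ndarray) -> float:
    """Deviance of the intercept-only Bernoulli model (closed form)."""
    y = np.asarray(stay, dtype=float)
    n = len(y)
    k = y.sum()
    if k == 0 or k == n:
        return 0.0
    p = k / n
    return -2.0 * (k * np.log(p) + (n - k) * np.log(1.0 - p))


# ---------------------------------------------------------------------------
# multilevel logistic regression (Laplace)


@dataclass
class GlmmFit:
    """Fitted multilevel logistic model."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    cov_beta: np.ndarray
    re_cov: np.ndarray
    theta: np.ndarray
    loglik: float
    deviance: float
    converged: bool
    n_obs: int
    n_subjects: int
    ranef: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> pd.DataFrame:
        """Coefficient table (term, estimate, SE, Z, p)."""
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.beta,
                "se": self.se,
                "z": self.zvalues,
                "p": self.pvalues,
            }
        )

    def __getitem__(self, term: str) -> dict:
        i = self.terms.index(term)
        return {
            "estimate": float(self.beta[i]),
            "se": float(self.se[i]),
            "z": float(self.zvalues[i]),
            "p": float(self.pvalues[i]),
        }


def _theta_to_chol(theta: np.ndarray) -> np.ndarray:
    """Lower-triangular relative covariance factor from the parameter vector.

    The first 4 entries are log-diagonals; the remaining 6 fill the strict
    lower triangle row by row.
    """
    L = np.zeros((_N_RE, _N_RE))
    L[np.diag_indices(_N_RE)] = np.exp(theta[:_N_RE])
    L[np.tril_indices(_N_RE, k=-1)] = theta[_N_RE:]
    return L


def _segment_starts(groups: np.ndarray) -> np.ndarray:
    change = np.empty(len(groups), dtype=bool)
    change[0] = True
    np.not_equal(groups[1:], groups[:-1], out=change[1:])
    return np.flatnonzero(change)


class _LaplaceProblem:
    """Profiled Laplace deviance for one dataset; rows pre-sorted by subject."""

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray):
        order = np.argsort(groups, kind="stable")
        self.X = np.ascontiguousarray(X[order])
        self.y = np.ascontiguousarray(y[order])
        g = groups[order]
        self.starts = _segment_starts(g)
        self.n_groups = len(self.starts)
        self.Z = self.X[:, :_N_RE]
        self.p = X.shape[1]
        self.idx = np.repeat(
            np.arange(self.n_groups), np.diff(np.append(self.starts, len(self.y)))
        )
        self._beta = np.zeros(self.p)
        self._u = np.zeros((self.n_groups, _N_RE))

    def _segsum(self, arr: np.ndarray) -> np.ndarray:
        return np.add.reduceat(arr, self.starts, axis=0)

    def _penalized_loglik(self, eta: np.ndarray, u: np.ndarray) -> float:
        return _bernoulli_loglik(self.y, eta) - 0.5 * float(np.sum(u * u))

    def pirls(
        self, L: np.ndarray, max_iter: int = 80, tol: float = 1e-12
    ) -> tuple[np.ndarray, np.ndarray, float, bool]:
        """Jointly maximize over (beta, u) for a fixed covariance factor."""
        X, y, Z = self.X, self.y, self.Z
        beta = self._beta.copy()
        u = self._u.copy()
        M = Z @ L  # per-row random-effect design in the spherical parameterization
        idx = self.idx
        eta = X @ beta + np.einsum("ij,ij->i", M, u[idx])
        f = self._penalized_loglik(eta, u)
        ok = False
        for _ in range(max_iter):
            mu = special.expit(eta)
            w = np.clip(mu * (1.0 - mu), 1e-12, None)
            r = y - mu
            g_beta = X.T @ r
            g_u = self._segsum(M * r[:, None]) - u
            A = self._segsum(w[:, None, None] * M[:, :, None] * M[:, None, :])
            A[:, np.arange(_N_RE), np.arange(_N_RE)] += 1.0
            C = self._segsum(w[:, None, None] * X[:, :, None] * M[:, None, :])
            B = (X * w[:, None]).T @ X
            Ainv_gu = np.linalg.solve(A, g_u[:, :, None])[:, :, 0]
            Ainv_Ct = np.linalg.solve(A, C.transpose(0, 2, 1))
            S = B - np.einsum("ipk,ikq->pq", C, Ainv_Ct)
            rhs = g_beta - np.einsum("ipk,ik->p", C, Ainv_gu)
            dbeta = np.linalg.solve(S, rhs)
            du = Ainv_gu - np.einsum("ikp,p->ik", Ainv_Ct, dbeta)
            t = 1.0
            for _ in range(60):
                beta_c = beta + t * dbeta
                u_c = u + t * du
                eta_c = X @ beta_c + np.einsum("ij,ij->i", M, u_c[idx])
                f_c = self._penalized_loglik(eta_c, u_c)
                if f_c >= f - 1e-14:
                    break
                t *= 0.5
            beta, u, eta = beta_c, u_c, eta_c
            f_old, f = f, f_c
            if abs(f - f_old) < tol * (1.0 + abs(f)):
                ok = True
                break
        self._beta, self._u = beta.copy(), u.copy()
        return beta, u, f, ok

    def pirls_u(
        self, L: np.ndarray, beta: np.ndarray, max_iter: int = 80, tol: float = 1e-12
    ) -> tuple[np.ndarray, float, bool]:
        """Maximize over u only, for fixed (beta, covariance factor).

        The per-subject problems are strictly concave and solved by batched
        4x4 Newton steps with a shared step-halving line search.
        """
        y, Z = self.y, self.Z
        u = self._u.copy()
        M = Z @ L
        idx = self.idx
        offset = self.X @ beta
        eta = offset + np.einsum("ij,ij->i", M, u[idx])
        f = self._penalized_loglik(eta, u)
        ok = False
        for _ in range(max_iter):
            mu = special.expit(eta)
            w = np.clip(mu * (1.0 - mu), 1e-12, None)
            g_u = self._segsum(M * (y - mu)[:, None]) - u
            A = self._segsum(w[:, None, None] * M[:, :, None] * M[:, None, :])
            A[:, np.arange(_N_RE), np.arange(_N_RE)] += 1.0
            du = np.linalg.solve(A, g_u[:, :, None])[:, :, 0]
            t = 1.0
            for _ in range(60):
                u_c = u + t * du
                eta_c = offset + np.einsum("ij,ij->i", M, u_c[idx])
                f_c = self._penalized_loglik(eta_c, u_c)
                if f_c >= f - 1e-14:
                    break
                t *= 0.5
            u, eta = u_c, eta_c
            f_old, f = f, f_c
            if abs(f - f_old) < tol * (1.0 + abs(f)):
                ok = True
                break
        self._u = u.copy()
        return u, f, ok

    def laplace_deviance(self, params: np.ndarray) -> float:
        """Full Laplace deviance at packed (beta, theta), u profiled out."""
        beta = params[: self.p]
        L = _theta_to_chol(params[self.p :])
        u, f, _ = self.pirls_u(L, beta)
        return -2.0 * (f - 0.5 * self._logdet_term(L, beta, u))

    def _logdet_term(self, L: np.ndarray, beta: np.ndarray, u: np.ndarray) -> float:
        idx = self.idx
        M = self.Z @ L
        eta = self.X @ beta + np.einsum("ij,ij->i", M, u[idx])
        mu = special.expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        A = self._segsum(w[:, None, None] * M[:, :, None] * M[:, None, :])
        A[:, np.arange(_N_RE), np.arange(_N_RE)] += 1.0
        sign, logdet = np.linalg.slogdet(A)
        if (sign <= 0).any():
            raise FloatingPointError("non-PD Laplace Hessian block")
        return float(logdet.sum())

    def fixed_cov(self, L: np.ndarray, beta: np.ndarray, u: np.ndarray) -> np.ndarray:
        """Fixed-effect covariance: Schur complement of the joint Hessian."""
        idx = self.idx
        M = self.Z @ L
        eta = self.X @ beta + np.einsum("ij,ij->i", M, u[idx])
        mu = special.expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        A = self._segsum(w[:, None, None] * M[:, :, None] * M[:, None, :])
        A[:, np.arange(_N_RE), np.arange(_N_RE)] += 1.0
        C = self._segsum(w[:, None, None] * self.X[:, :, None] * M[:, None, :])
        B = (self.X * w[:, None]).T @ self.X
        Ainv_Ct = np.linalg.solve(A, C.transpose(0, 2, 1))
        S = B - np.einsum("ipk,ikq->pq", C, Ainv_Ct)
        return np.linalg.inv(S)


def fit_multilevel(
    rows: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    moderators: tuple[str, ...] = (),
    theta0: np.ndarray | None = None,
    fix_theta: np.ndarray | None = None,
    maxiter: int = 300,
) -> GlmmFit:
    """Fit the multilevel stay/switch logistic model by Laplace approximation.

    Parameters
    ----------
    rows
        Encoded design rows (``encode_trials`` output), all subjects.
    covariates
        Subject covariate table; required when ``moderators`` are given.
        Moderator columns are taken as-is (standardize them first).
    moderators
        0–2 column names to expand factorially against the within-subject
        terms, e.g. ``("extraversion_z",)``.
    theta0
        Optional start for the 10 covariance parameters (4 log-diagonal
        Cholesky entries then 6 off-diagonals).
    fix_theta
        Hold the covariance parameters at this value and optimize only the
        fixed effects (e.g. log-diagonals of -8 for the zero-variance
        limit, where the fit reduces to a pooled logistic regression).

    Returns a :class:`GlmmFit` with Wald statistics for every fixed term,
    the estimated random-effect covariance and the Laplace log-likelihood.
    """
    df = rows
    if moderators:
        if covariates is None:
            raise ValueError("moderators require a covariate table")
        missing = [m for m in moderators if m not in covariates.columns]
        if missing:
            raise ValueError(f"covariate table lacks moderator columns {missing}")
        df = rows.drop(columns=[m for m in moderators if m in rows.columns]).merge(
            covariates[["subject_id", *moderators]], on="subject_id", validate="m:1"
        )
        if len(df) != len(rows):
            raise ValueError("some rows have no covariates for their subject")

    X, names = build_design(df, moderators)
    y = df["stay"].to_numpy(dtype=float)
    groups, subject_index = pd.factorize(df["subject_id"], sort=True)
    prob = _LaplaceProblem(X, y, groups)

    if theta0 is None:
        theta0 = np.concatenate([np.full(_N_RE, np.log(0.3)), np.zeros(_N_THETA - _N_RE)])
    if fix_theta is not None:
        theta0 = np.asarray(fix_theta, dtype=float)
        if theta0.shape != (_N_THETA,):
            raise ValueError(f"fix_theta must have length {_N_THETA}")
    # initial beta: joint penalized fit at the starting covariance
    beta0, _, _, _ = prob.pirls(_theta_to_chol(theta0))
    if fix_theta is not None:
        objective = lambda b: prob.laplace_deviance(np.concatenate([b, theta0]))
        res = optimize.minimize(
            objective,
            beta0,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-11, "eps": 1e-6},
        )
        beta, theta = res.x, theta0
    else:
        x0 = np.concatenate([beta0, theta0])
        bounds = (
            [(None, None)] * prob.p
            + [(-8.0, 3.0)] * _N_RE
            + [(-8.0, 8.0)] * (_N_THETA - _N_RE)
        )
        res = optimize.minimize(
            prob.laplace_deviance,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-11, "eps": 1e-6},
        )
        beta = res.x[: prob.p]
        theta = res.x[prob.p :]
    L = _theta_to_chol(theta)
    u, f, pirls_ok = prob.pirls_u(L, beta)
    deviance = -2.0 * (f - 0.5 * prob._logdet_term(L, beta, u))
    cov_beta = prob.fixed_cov(L, beta, u)
    se = np.sqrt(np.diag(cov_beta))
    zvals = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(zvals))
    ranef = pd.DataFrame(u @ L.T, columns=BASE_TERMS)
    ranef.insert(0, "subject_id", subject_index)
    return GlmmFit(
        terms=names,
        beta=beta,
        se=se,
        zvalues=zvals,
        pvalues=pvals,
        cov_beta=cov_beta,
        re_cov=L @ L.T,
        theta=theta,
        loglik=-deviance / 2.0,
        deviance=deviance,
        converged=bool(res.success and pirls_ok),
        n_obs=len(y),
        n_subjects=prob.n_groups,
        ranef=ranef,
    )


@dataclass
class ContrastResult:
    """Wald test of a linear combination of fixed effects (1 df)."""

    estimate: float
    se: float
    chi_square: float
    df: int
    pvalue: float


def wald_contrast(fit: GlmmFit, c: np.ndarray | dict) -> ContrastResult:
    """Test c'beta = 0 against the fixed-effect covariance.

    ``c`` may be a vector over ``fit.terms`` or a {term: weight} mapping.
    Raises ``ValueError`` for a zero-variance contrast.
    """
    if isinstance(c, dict):
        vec = np.zeros(len(fit.terms))
        for term, weight in c.items():
            vec[fit.terms.index(term)] = weight
    else:
        vec = np.asarray(c, dtype=float)
        if vec.shape != (len(fit.terms),):
            raise ValueError(
                f"contrast length {vec.shape} does not match {len(fit.terms)} terms"
            )
    var = float(vec @ fit.cov_beta @ vec)
    if var <= 0:
        raise ValueError("contrast has zero variance")
    est = float(vec @ fit.beta)
    chi2 = est * est / var
    return ContrastResult(
        estimate=est,
        se=np.sqrt(var),
        chi_square=chi2,
        df=1,
        pvalue=float(stats.chi2.sf(chi2, 1)),
    )
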