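"""Dirichlet regression of the composition on exposure and covariates.

The mediator model assumes M_i | (R_i, X_i) ~ Dirichlet(gamma_1, ..., gamma_J)
with a log link on the concentrations,

    log gamma_j(r, x) = beta_0j + beta_Rj * r + beta_Xj' x,

so the expected log relative abundance of taxon j at (r, x) is the
digamma contrast psi(gamma_j) - psi(sum_m gamma_m).  That contrast is the
exposure-to-mediator half of every disparity formula downstream.

Fitting maximizes the exact Dirichlet log-likelihood by L-BFGS with the
analytic gradient; standard errors come from the observed information
(analytic Hessian).  No precision/overdispersion parameter is used: the
total concentration sum_j gamma_j carries dispersion implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma, gammaln, polygamma

from .datasets import MediationDataset


@dataclass
class DirichletRegressionParams:
    """Per-taxon regression coefficients of the mediator model.

    intercepts: beta_0j, shape (J,)
    exposure_effects: beta_Rj, shape (J,)
    covariate_effects: beta_Xj, shape (J, K)
    """

    intercepts: np.ndarray
    exposure_effects: np.ndarray
    covariate_effects: np.ndarray

    def __post_init__(self):
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.exposure_effects = np.asarray(self.exposure_effects, dtype=float)
        self.covariate_effects = np.atleast_2d(np.asarray(self.covariate_effects, dtype=float))
        if self.covariate_effects.size == 0:
            self.covariate_effects = np.empty((len(self.intercepts), 0))

    @property
    def n_taxa(self) -> int:
        return len(self.intercepts)

    @property
    def n_covariates(self) -> int:
        return self.covariate_effects.shape[1]

    def coef_matrix(self) -> np.ndarray:
        """J x (2 + K) matrix with columns [intercept, exposure, covariates]."""
        return np.column_stack([self.intercepts, self.exposure_effects,
                                self.covariate_effects])

    @classmethod
    def from_coef_matrix(cls, B: np.ndarray) -> "DirichletRegressionParams":
        return cls(intercepts=B[:, 0], exposure_effects=B[:, 1],
                   covariate_effects=B[:, 2:])

    def concentrations(self, r, x) -> np.ndarray:
        """gamma_j(r, x) = exp(beta_0j + beta_Rj r + beta_Xj' x)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        eta = self.intercepts + self.exposure_effects * r
        if self.n_covariates:
            eta = eta + self.covariate_effects @ x
        return np.exp(eta)


@dataclass
class MediatorFitReport:
    params: DirichletRegressionParams
    loglik: float
    converged: bool
    iterations: int
    gradient_norm: float
    cov_params: np.ndarray | None = None  # flattened-B order, row-major

    def standard_errors(self) -> np.ndarray:
        """SEs in the same J x (2+K) layout as ``params.coef_matrix()``."""
        if self.cov_params is None:
            raise ValueError("covariance not available")
        se = np.sqrt(np.diag(self.cov_params))
        return se.reshape(self.params.coef_matrix().shape)


def _design(dataset: MediationDataset) -> np.ndarray:
    frame = dataset.frame
    return np.column_stack([np.ones(frame.n_subjects), frame.exposure,
                            frame.covariates])


def _loglik_and_grad(B: np.ndarray, Z: np.ndarray, logM: np.ndarray):
    """Log-likelihood and gradient w.r.t. the J x (2+K) coefficient matrix."""
    gamma = np.exp(Z @ B.T)                 # n x J
    gsum = gamma.sum(axis=1)
    ll = (gammaln(gsum).sum() - gammaln(gamma).sum()
          + ((gamma - 1.0) * logM).sum())
    # d ll / d gamma_ij
    G = digamma(gsum)[:, None] - digamma(gamma) + logM
    grad = (G * gamma).T @ Z                # J x (2+K)
    return ll, grad


def dirichlet_loglik(params: DirichletRegressionParams,
                     dataset: MediationDataset) -> float:
    """Sum over subjects of the log Dirichlet density at the fitted
    concentrations."""
    M = dataset.composition.values
    if np.any(M <= 0):
        raise ValueError(
            "compositions must be strictly positive; run replace_zeros first")
    Z = _design(dataset)
    ll, _ = _loglik_and_grad(params.coef_matrix(), Z, np.log(M))
    return float(ll)


def _moment_init(dataset: MediationDataset) -> np.ndarray:
    """Method-of-moments start: intercepts from the mean composition and a
    crude total-concentration estimate; exposure/covariate effects zero."""
    M = dataset.composition.values
    mean = M.mean(axis=0)
    var = M.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s_j = mean * (1 - mean) / var - 1.0
    s_j = s_j[np.isfinite(s_j) & (s_j > 0)]
    total = float(np.median(s_j)) if s_j.size else float(M.shape[1])
    total = max(total, 1.0)
    J = M.shape[1]
    K = dataset.frame.n_covariates
    B = np.zeros((J, 2 + K))
    B[:, 0] = np.log(np.clip(mean * total, 1e-8, None))
    return B


def _hessian(B: np.ndarray, Z: np.ndarray, logM: np.ndarray) -> np.ndarray:
    """Analytic Hessian of the log-likelihood w.r.t. vec(B) (row-major)."""
    n, p = Z.shape
    J = B.shape[0]
    gamma = np.exp(Z @ B.T)
    gsum = gamma.sum(axis=1)
    G = digamma(gsum)[:, None] - digamma(gamma) + logM
    psi1_sum = polygamma(1, gsum)           # n
    psi1 = polygamma(1, gamma)              # n x J
    # cross-taxon block: sum_i gamma_ij gamma_ik psi1_sum_i z_i z_i'
    W = gamma * np.sqrt(psi1_sum)[:, None]
    cross = np.einsum("ij,ia,ik,ib->jakb", W, Z, W, Z, optimize=True)
    # diagonal correction: delta_jk * sum_i [gamma_ij G_ij - gamma_ij^2 psi1_ij] z z'
    diag_w = gamma * G - gamma ** 2 * psi1
    diag = np.einsum("ij,ia,ib->jab", diag_w, Z, Z, optimize=True)
    H = cross
    for j in range(J):
        H[j, :, j, :] += diag[j]
    return H.reshape(J * p, J * p)


def fit_dirichlet_regression(dataset: MediationDataset, init: str = "moment_based",
                             tol: float = 1e-6, max_iter: int = 500,
                             start: DirichletRegressionParams | None = None,
                             compute_cov: bool = False) -> MediatorFitReport:
    """Maximum-likelihood Dirichlet regression fit.

    ``start`` overrides ``init`` with explicit warm-start coefficients
    (used heavily by the permutation and bootstrap refits).
    """
    M = dataset.composition.values
    if np.any(M <= 0):
        raise ValueError(
            "compositions must be strictly positive; run replace_zeros first")
    logM = np.log(M)
    Z = _design(dataset)
    J = M.shape[1]
    p = Z.shape[1]
    if start is not None:
        B0 = start.coef_matrix().copy()
    elif init == "zeros":
        B0 = np.zeros((J, p))
    elif init == "moment_based":
        B0 = _moment_init(dataset)
    else:
        raise ValueError(f"unknown init: {init!r}")

    def negloglik(theta):
        ll, grad = _loglik_and_grad(theta.reshape(J, p), Z, logM)
        return -ll, -grad.ravel()

    res = minimize(negloglik, B0.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-12})
    B = res.x.reshape(J, p)
    _, grad = _loglik_and_grad(B, Z, logM)
    gnorm = float(np.max(np.abs(grad)))
    params = DirichletRegressionParams.from_coef_matrix(B)
    cov = None
    if compute_cov:
        H = _hessian(B, Z, logM)
        cov = np.linalg.inv(-H)
    return MediatorFitReport(params=params, loglik=float(-res.fun),
                             converged=bool(res.success or gnorm < 1e-3),
                             iterations=int(res.nit), gradient_norm=gnorm,
                             cov_params=cov)


def expected_log_abundance(params: DirichletRegressionParams, r, x) -> np.ndarray:
    """E[log M_j | R=r, x] = psi(gamma_j) - psi(sum_m gamma_m) per taxon."""
    gamma = params.concentrations(r, x)
    return digamma(gamma) - digamma(gamma.sum())


def predicted_mean_composition(params: DirichletRegressionParams, r, x) -> np.ndarray:
    """E[M_j | R=r, x] = gamma_j / sum_m gamma_m; sums to 1."""
    gamma = params.concentrations(r, x)
    return gamma / gamma.sum()
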