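"""Constrained linear log-contrast regression of the outcome.

The outcome model is

    Y_i = a0 + aR R_i + aX' X_i + aM' log(M_i) + aC' log(M_i) R_i + eps_i,
    eps_i ~ N(0, sigma^2),   subject to  sum_j aMj = 0  and  sum_j aCj = 0.

The two zero-sum constraints make the log-contrast terms invariant to the
simplex closure (rescaling a subject's abundances before closure leaves
the linear predictor unchanged), which is what licenses interpreting aM
and aC compositionally.

Two fits are provided:

* ``fit_constrained_ols`` — least squares with the constraints eliminated
  through an orthonormal basis of the zero-sum subspace, so the solution
  is unique and taxon-order invariant.
* ``fit_penalized`` — adds a group-lasso penalty on each (aMj, aCj) pair
  plus an L1 penalty on the interaction aCj, solved by ADMM with the
  sparse-group proximal operator.  The heredity condition (an interaction
  is admitted only while its main effect is active) is enforced on the
  returned fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import MediationDataset


@dataclass
class OutcomeModelParams:
    intercept: float
    exposure_coef: float
    covariate_coefs: np.ndarray
    taxon_main: np.ndarray          # aM, sums to 0
    taxon_interaction: np.ndarray   # aC, sums to 0
    noise_var: float

    def __post_init__(self):
        self.covariate_coefs = np.asarray(self.covariate_coefs, dtype=float)
        self.taxon_main = np.asarray(self.taxon_main, dtype=float)
        self.taxon_interaction = np.asarray(self.taxon_interaction, dtype=float)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_main)

    def predict(self, dataset: MediationDataset) -> np.ndarray:
        logM = np.log(dataset.composition.values)
        frame = dataset.frame
        eta = (self.intercept + self.exposure_coef * frame.exposure
               + frame.covariates @ self.covariate_coefs
               + logM @ self.taxon_main
               + (logM @ self.taxon_interaction) * frame.exposure)
        return eta


@dataclass
class OlsFitReport:
    params: OutcomeModelParams
    cov_params: np.ndarray   # covariance of the free (reduced) coefficients
    basis: np.ndarray        # J x (J-1) zero-sum basis used
    rss: float
    df_resid: int

    def covariance_full(self) -> np.ndarray:
        """Covariance of (a0, aX, aR, aM, aC) in full coordinates."""
        J = self.basis.shape[0]
        K = len(self.params.covariate_coefs)
        p_fixed = 2 + K
        T = np.zeros((p_fixed + 2 * J, p_fixed + 2 * (J - 1)))
        T[:p_fixed, :p_fixed] = np.eye(p_fixed)
        T[p_fixed:p_fixed + J, p_fixed:p_fixed + J - 1] = self.basis
        T[p_fixed + J:, p_fixed + J - 1:] = self.basis
        return T @ self.cov_params @ T.T


@dataclass
class PenalizedFitReport:
    params: OutcomeModelParams
    lambda_l1: float
    lambda_group: float
    selected_taxa: list
    objective: float
    converged: bool = True
    criterion_value: float = np.nan
    criterion: str | None = None

    @property
    def n_selected(self) -> int:
        return len(self.selected_taxa)


def zero_sum_basis(J: int) -> np.ndarray:
    """Orthonormal basis (J x J-1) of {v : sum(v) = 0} via Helmert contrasts."""
    H = np.zeros((J, J - 1))
    for k in range(1, J):
        H[:k, k - 1] = 1.0
        H[k, k - 1] = -k
        H[:, k - 1] /= np.sqrt(k * (k + 1))
    return H


@dataclass
class DesignInfo:
    """Full design matrix with column blocks and the constraint basis."""
    X_full: np.ndarray       # columns: 1 | covariates | R | logM | R*logM
    y: np.ndarray
    n_taxa: int
    n_covariates: int
    basis: np.ndarray = field(default=None)

    @property
    def slices(self):
        K, J = self.n_covariates, self.n_taxa
        return {
            "intercept": slice(0, 1),
            "covariates": slice(1, 1 + K),
            "exposure": slice(1 + K, 2 + K),
            "main": slice(2 + K, 2 + K + J),
            "interaction": slice(2 + K + J, 2 + K + 2 * J),
        }

    def reduced(self) -> np.ndarray:
        """Design with the zero-sum constraints eliminated: the two log-M
        blocks are rotated into the (J-1)-dimensional zero-sum subspace."""
        s = self.slices
        return np.column_stack([
            self.X_full[:, s["intercept"]],
            self.X_full[:, s["covariates"]],
            self.X_full[:, s["exposure"]],
            self.X_full[:, s["main"]] @ self.basis,
            self.X_full[:, s["interaction"]] @ self.basis,
        ])


def build_design(dataset: MediationDataset) -> DesignInfo:
    M = dataset.composition.values
    if np.any(M <= 0):
        raise ValueError("compositions must be strictly positive; run replace_zeros")
    logM = np.log(M)
    frame = dataset.frame
    X_full = np.column_stack([
        np.ones(frame.n_subjects),
        frame.covariates,
        frame.exposure.astype(float),
        logM,
        logM * frame.exposure[:, None],
    ])
    fixed = np.column_stack([np.ones(frame.n_subjects), frame.covariates])
    rank = np.linalg.matrix_rank(fixed)
    if rank < fixed.shape[1]:
        raise ValueError("collinear covariate columns in the outcome design")
    J = dataset.n_taxa
    return DesignInfo(X_full=X_full, y=frame.outcome, n_taxa=J,
                      n_covariates=frame.n_covariates, basis=zero_sum_basis(J))


def _unpack(theta: np.ndarray, J: int, K: int, basis: np.ndarray,
            reduced: bool, rss: float, df: int) -> OutcomeModelParams:
    if reduced:
        aM = basis @ theta[2 + K:2 + K + J - 1]
        aC = basis @ theta[2 + K + J - 1:]
    else:
        aM = theta[2 + K:2 + K + J]
        aC = theta[2 + K + J:]
    return OutcomeModelParams(
        intercept=float(theta[0]),
        covariate_coefs=theta[1:1 + K],
        exposure_coef=float(theta[1 + K]),
        taxon_main=aM,
        taxon_interaction=aC,
        noise_var=rss / df if df > 0 else np.nan,
    )


def fit_constrained_ols(dataset: MediationDataset,
                        design: DesignInfo | None = None) -> OlsFitReport:
    """Least squares under the two zero-sum constraints.

    sigma^2 = RSS / (n - p_free) with p_free = 2 + K + 2(J-1).
    """
    design = design or build_design(dataset)
    Xr = design.reduced()
    n, p_free = Xr.shape
    if n <= p_free:
        raise ValueError(f"need n > {p_free} free parameters, got n={n}")
    theta, _, rank, _ = np.linalg.lstsq(Xr, design.y, rcond=None)
    if rank < p_free:
        raise ValueError("rank-deficient outcome design")
    resid = design.y - Xr @ theta
    rss = float(resid @ resid)
    df = n - p_free
    params = _unpack(theta, design.n_taxa, design.n_covariates, design.basis,
                     reduced=True, rss=rss, df=df)
    XtX_inv = np.linalg.inv(Xr.T @ Xr)
    return OlsFitReport(params=params, cov_params=params.noise_var * XtX_inv,
                        basis=design.basis, rss=rss, df_resid=df)


# ---------------------------------------------------------------------------
# Sparse-group penalized fit


def sparse_group_prox(v: np.ndarray, lam_group: float, lam_l1: float) -> np.ndarray:
    """Prox of lam_group * ||(vM, vC)||_2 + lam_l1 * |vC| for a 2-vector
    v = (vM, vC): soft-threshold the interaction coordinate, then radially
    shrink the pair."""
    w = v.copy()
    w[1] = np.sign(w[1]) * max(abs(w[1]) - lam_l1, 0.0)
    norm = np.hypot(w[0], w[1])
    if norm <= lam_group:
        return np.zeros(2)
    return w * (1.0 - lam_group / norm)


def _admm_solve(design: DesignInfo, lambda_l1: float, lambda_group: float,
                fixed_zero_interaction: np.ndarray | None = None,
                rho: float = 1.0, max_iter: int = 5000,
                tol: float = 1e-10):
    """ADMM on: min ||y - X theta||^2/(2n) + penalties(S theta)
    s.t. the two zero-sum constraints, with consensus z = S theta carrying
    the exact zeros."""
    X, y = design.X_full, design.y
    n, p = X.shape
    J, K = design.n_taxa, design.n_covariates
    s = design.slices
    # constraint matrix C theta = 0
    C = np.zeros((2, p))
    C[0, s["main"]] = 1.0
    C[1, s["interaction"]] = 1.0
    # selection S: rows pick (aMj, aCj) stacked as 2J
    sel_idx = np.concatenate([np.arange(s["main"].start, s["main"].stop),
                              np.arange(s["interaction"].start, s["interaction"].stop)])
    Q = X.T @ X / n
    q = X.T @ y / n
    A = Q.copy()
    A[sel_idx, sel_idx] += rho
    KKT = np.block([[A, C.T], [C, np.zeros((2, 2))]])
    KKT_inv = np.linalg.inv(KKT)
    z = np.zeros(2 * J)
    u = np.zeros(2 * J)
    fz = (np.zeros(J, dtype=bool) if fixed_zero_interaction is None
          else fixed_zero_interaction)
    theta = np.zeros(p)
    converged = False
    for it in range(max_iter):
        rhs = np.concatenate([q.copy(), np.zeros(2)])
        rhs[sel_idx] += rho * (z - u)
        theta = (KKT_inv @ rhs)[:p]
        w = theta[sel_idx] + u
        z_old = z.copy()
        # vectorized sparse-group prox per taxon pair (vM, vC)
        vM, vC = w[:J].copy(), w[J:].copy()
        vC = np.sign(vC) * np.maximum(np.abs(vC) - lambda_l1 / rho, 0.0)
        vC[fz] = 0.0
        norms = np.hypot(vM, vC)
        scale = np.where(norms > lambda_group / rho,
                         1.0 - (lambda_group / rho) / np.where(norms > 0, norms, 1.0),
                         0.0)
        z[:J] = vM * scale
        z[J:] = vC * scale
        u += theta[sel_idx] - z
        r_primal = np.max(np.abs(theta[sel_idx] - z)) if J else 0.0
        r_dual = rho * (np.max(np.abs(z - z_old)) if J else 0.0)
        if r_primal < tol and r_dual < tol:
            converged = True
            break
    return theta, z, converged


def _finalize_penalized(design: DesignInfo, theta: np.ndarray, z: np.ndarray,
                        taxon_ids, lambda_l1: float, lambda_group: float,
                        converged: bool) -> PenalizedFitReport:
    J, K = design.n_taxa, design.n_covariates
    s = design.slices
    aM = z[:J].copy()
    aC = z[J:].copy()
    # exact zero-sum on the active support (ADMM leaves O(tol) slack)
    for a in (aM, aC):
        nz = a != 0
        if nz.any():
            a[nz] -= a[nz].sum() / nz.sum()
    n = design.X_full.shape[0]
    coefs = theta.copy()
    coefs[s["main"]] = aM
    coefs[s["interaction"]] = aC
    resid = design.y - design.X_full @ coefs
    rss = float(resid @ resid)
    n_active = int(np.sum((aM != 0) | (aC != 0)))
    df = max(n - (2 + K + max(0, int(np.sum(aM != 0)) - 1)
                  + max(0, int(np.sum(aC != 0)) - 1)), 1)
    params = OutcomeModelParams(
        intercept=float(coefs[0]), covariate_coefs=coefs[s["covariates"]],
        exposure_coef=float(coefs[s["exposure"]][0]),
        taxon_main=aM, taxon_interaction=aC, noise_var=rss / df)
    pen = (lambda_group * np.sum(np.hypot(aM, aC))
           + lambda_l1 * np.sum(np.abs(aC)))
    selected = [taxon_ids[j] for j in range(J) if aM[j] != 0 or aC[j] != 0]
    return PenalizedFitReport(params=params, lambda_l1=lambda_l1,
                              lambda_group=lambda_group, selected_taxa=selected,
                              objective=rss / (2 * n) + pen, converged=converged)


def fit_penalized(dataset: MediationDataset, lambda_l1: float,
                  lambda_group: float,
                  design: DesignInfo | None = None) -> PenalizedFitReport:
    """Sparse-group penalized log-contrast fit with heredity.

    Minimizes RSS/(2n) + lambda_group * sum_j ||(aMj, aCj)||_2
    + lambda_l1 * sum_j |aCj| under the zero-sum constraints.  At zero
    penalties this reduces to :func:`fit_constrained_ols`.
    """
    if lambda_l1 < 0 or lambda_group < 0:
        raise ValueError("penalty weights must be non-negative")
    design = design or build_design(dataset)
    taxon_ids = dataset.composition.taxon_ids
    if lambda_l1 == 0 and lambda_group == 0:
        ols = fit_constrained_ols(dataset, design)
        J = design.n_taxa
        aM, aC = ols.params.taxon_main, ols.params.taxon_interaction
        n = design.X_full.shape[0]
        return PenalizedFitReport(
            params=ols.params, lambda_l1=0.0, lambda_group=0.0,
            selected_taxa=[taxon_ids[j] for j in range(J)
                           if aM[j] != 0 or aC[j] != 0],
            objective=ols.rss / (2 * n), converged=True)
    theta, z, conv = _admm_solve(design, lambda_l1, lambda_group)
    J = design.n_taxa
    aM, aC = z[:J], z[J:]
    violating = (aM == 0) & (aC != 0)
    if violating.any():
        # heredity: interactions without a main effect are zeroed and the
        # penalized problem re-solved with those coordinates held at zero
        theta, z, conv = _admm_solve(design, lambda_l1, lambda_group,
                                     fixed_zero_interaction=violating)
        aM, aC = z[:J], z[J:]
        still = (aM == 0) & (aC != 0)
        z[J:][still] = 0.0
    return _finalize_penalized(design, theta, z, taxon_ids,
                               lambda_l1, lambda_group, conv)


def _bic(design: DesignInfo, report: PenalizedFitReport) -> float:
    n = design.X_full.shape[0]
    p = report.params
    coefs = np.concatenate([[p.intercept], p.covariate_coefs, [p.exposure_coef],
                            p.taxon_main, p.taxon_interaction])
    resid = design.y - design.X_full @ coefs
    rss = float(resid @ resid)
    nM = int(np.sum(p.taxon_main != 0))
    nC = int(np.sum(p.taxon_interaction != 0))
    df = 2 + design.n_covariates + max(0, nM - 1) + max(0, nC - 1)
    return n * np.log(max(rss, 1e-300) / n) + np.log(n) * df


def default_lambda_grid(n_group: int = 8, n_l1: int = 4,
                        lam_max: float = 1.0, lam_min_ratio: float = 1e-3):
    """Log-spaced (lambda_group, lambda_l1) grid including the zero-L1 edge."""
    lg = np.geomspace(lam_max * lam_min_ratio, lam_max, n_group)
    l1 = np.concatenate([[0.0], np.geomspace(lam_max * lam_min_ratio * 0.1,
                                             lam_max * 0.1, n_l1 - 1)])
    return [(float(a), float(b)) for a in lg for b in l1]


def select_tuning(dataset: MediationDataset, grid=None, criterion: str = "bic",
                  n_folds: int = 5, seed: int = 0,
                  design: DesignInfo | None = None) -> PenalizedFitReport:
    """Pick (lambda_group, lambda_l1) from a grid by BIC or seeded 5-fold CV.

    Ties break toward the larger total penalty (the sparser model).
    """
    design = design or build_design(dataset)
    if grid is None:
        grid = default_lambda_grid()
    if not grid:
        raise ValueError("empty tuning grid")
    scored = []
    if criterion == "bic":
        for lg, l1 in grid:
            rep = fit_penalized(dataset, lambda_l1=l1, lambda_group=lg,
                                design=design)
            scored.append((_bic(design, rep), lg + l1, (lg, l1), rep))
    elif criterion == "cv5":
        rng = np.random.default_rng(seed)
        n = dataset.n_subjects
        perm = rng.permutation(n)
        folds = np.array_split(perm, n_folds)
        for lg, l1 in grid:
            errs = []
            for f in folds:
                mask = np.ones(n, dtype=bool)
                mask[f] = False
                train = dataset.subset(np.where(mask)[0])
                test = dataset.subset(f)
                try:
                    rep = fit_penalized(train, lambda_l1=l1, lambda_group=lg)
                except ValueError:
                    errs.append(np.inf)
                    continue
                pred = rep.params.predict(test)
                errs.append(float(np.mean((test.frame.outcome - pred) ** 2)))
            rep_full = fit_penalized(dataset, lambda_l1=l1, lambda_group=lg,
                                     design=design)
            scored.append((float(np.mean(errs)), lg + l1, (lg, l1), rep_full))
    else:
        raise ValueError(f"unknown criterion: {criterion!r}")
    # minimize score; among ties prefer larger total penalty
    scored.sort(key=lambda t: (t[0], -t[1]))
    best = scored[0][3]
    best.criterion_value = scored[0][0]
    best.criterion = criterion
    return best
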