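"""Synthetic data generated exactly under the mediation model.

The generator draws, per subject: covariates X (standard normal, with an
optional per-covariate mean shift between exposure groups to induce
confounding), a composition M ~ Dirichlet(gamma(R, X)) with log-linear
concentrations, and a continuous outcome

    Y = a0 + aR R + aX' X + aM' log M + aC' (log M) R + N(0, sigma^2).

Because both halves of the generative model coincide with the fitted
models, the true disparity decomposition is available in closed form
(`true_disparity`) and by direct counterfactual Monte-Carlo simulation
(`mc_disparity`), and the two must agree — the standing end-to-end check
of the whole pipeline.

What the generator does NOT emulate: sequencing count noise (multinomial
sampling), zero inflation, taxonomic correlation structure beyond the
Dirichlet's negative covariance, or longitudinal sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import CompositionMatrix, MediationDataset, StudyFrame
from .dirichlet import DirichletRegressionParams
from .disparity import DisparityEstimates, compute_disparity
from .logcontrast import OutcomeModelParams


@dataclass
class SimulationConfig:
    n_per_group: int
    mediator_params: DirichletRegressionParams
    outcome_params: OutcomeModelParams
    confounding_shift: np.ndarray | float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        op = self.outcome_params
        if abs(op.taxon_main.sum()) > 1e-8 or abs(op.taxon_interaction.sum()) > 1e-8:
            raise ValueError("true outcome coefficients must satisfy the "
                             "zero-sum constraints")
        K = self.mediator_params.n_covariates
        shift = np.broadcast_to(np.asarray(self.confounding_shift, dtype=float),
                                (K,)).copy() if K else np.empty(0)
        self.confounding_shift = shift

    @property
    def n_taxa(self) -> int:
        return self.mediator_params.n_taxa

    @property
    def n_covariates(self) -> int:
        return self.mediator_params.n_covariates


def _zero_sum(v: np.ndarray) -> np.ndarray:
    return v - v.mean()


def default_scenario(n_per_group: int = 150, n_taxa: int = 20,
                     n_covariates: int = 2, n_mediators: int = 3,
                     beta_r: float = 0.8, alpha_m: float = 0.6,
                     alpha_c: float = 0.2, alpha_r: float = 1.0,
                     noise_sd: float = 1.0, confounding_shift: float = 0.0,
                     seed: int = 0) -> SimulationConfig:
    """Reference truth scenario: J taxa of which ``n_mediators`` carry both
    a nonzero exposure effect on the taxon and a nonzero taxon effect on
    the outcome; modest covariate effects on both models."""
    J, K = n_taxa, n_covariates
    rng = np.random.default_rng(seed)
    intercepts = np.log(rng.uniform(0.5, 2.0, size=J) * 30 / J)
    # active-taxon pattern: alternating signs, centered within the active
    # set so aM/aC are exactly zero outside it and zero-sum overall
    spread_zero_sum = n_mediators == 1
    if n_mediators > 1:
        w = (-1.0) ** np.arange(n_mediators)
        w -= w.mean()
        w /= np.max(np.abs(w))
    elif n_mediators == 1:
        # a single active taxon cannot carry a zero-sum block alone; its
        # counterweight is spread uniformly over the remaining taxa
        w = np.ones(1)
    beta_R = np.zeros(J)
    if n_mediators:
        beta_R[:n_mediators] = beta_r * np.sign(w)
    beta_X = rng.normal(0, 0.1, size=(J, K)) if K else np.empty((J, 0))
    mediator = DirichletRegressionParams(intercepts=intercepts,
                                         exposure_effects=beta_R,
                                         covariate_effects=beta_X)
    aM = np.zeros(J)
    aC = np.zeros(J)
    if n_mediators:
        aM[:n_mediators] = alpha_m * w
        aC[:n_mediators] = alpha_c * w
    if spread_zero_sum:
        aM[n_mediators:] = -aM[:n_mediators].sum() / (J - n_mediators)
        aC[n_mediators:] = -aC[:n_mediators].sum() / (J - n_mediators)
    outcome = OutcomeModelParams(intercept=20.0, exposure_coef=alpha_r,
                                 covariate_coefs=rng.normal(0, 0.3, size=K),
                                 taxon_main=aM, taxon_interaction=aC,
                                 noise_var=noise_sd ** 2)
    return SimulationConfig(n_per_group=n_per_group, mediator_params=mediator,
                            outcome_params=outcome,
                            confounding_shift=confounding_shift,
                            noise_sd=noise_sd, seed=seed)


def null_scenario(n_per_group: int = 75, n_taxa: int = 6, n_covariates: int = 1,
                  alpha_m: float = 0.4, alpha_r: float = 0.5,
                  noise_sd: float = 1.0, seed: int = 0) -> SimulationConfig:
    """No-mediation truth: beta_R = 0 and alpha_C = 0, so MDM = 0 while the
    direct disparity alpha_R and taxon main effects remain."""
    cfg = default_scenario(n_per_group=n_per_group, n_taxa=n_taxa,
                           n_covariates=n_covariates, n_mediators=0,
                           alpha_r=alpha_r, noise_sd=noise_sd, seed=seed)
    J = n_taxa
    aM = _zero_sum(np.concatenate([[alpha_m, -alpha_m], np.zeros(J - 2)]))
    cfg.outcome_params.taxon_main = aM
    cfg.mediator_params.exposure_effects = np.zeros(J)
    cfg.outcome_params.taxon_interaction = np.zeros(J)
    return cfg


def generate_dataset(config: SimulationConfig,
                     seed: int | None = None) -> MediationDataset:
    """Draw a dataset from the configured truth; identical config + seed
    gives a bit-identical dataset."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = 2 * config.n_per_group
    J, K = config.n_taxa, config.n_covariates
    R = np.concatenate([np.ones(config.n_per_group, dtype=int),
                        np.zeros(config.n_per_group, dtype=int)])
    X = rng.standard_normal((n, K)) if K else np.empty((n, 0))
    if K:
        X[R == 1] += config.confounding_shift
    mp = config.mediator_params
    eta = mp.intercepts[None, :] + np.outer(R, mp.exposure_effects)
    if K:
        eta = eta + X @ mp.covariate_effects.T
    gamma = np.exp(eta)
    M = np.empty((n, J))
    for i in range(n):
        M[i] = rng.dirichlet(gamma[i])
    # guard against numerical zeros from tiny concentrations
    M = np.clip(M, 1e-12, None)
    M /= M.sum(axis=1, keepdims=True)
    op = config.outcome_params
    logM = np.log(M)
    Y = (op.intercept + op.exposure_coef * R + X @ op.covariate_coefs
         + logM @ op.taxon_main + (logM @ op.taxon_interaction) * R
         + rng.normal(0, config.noise_sd, size=n))
    subjects = [f"S{i:04d}" for i in range(n)]
    comp = CompositionMatrix(values=M, subject_ids=subjects,
                             taxon_ids=[f"taxon_{j:02d}" for j in range(J)])
    frame = StudyFrame(exposure=R, outcome=Y, covariates=X,
                       covariate_names=[f"X{k+1}" for k in range(K)],
                       subject_ids=subjects)
    return MediationDataset(composition=comp, frame=frame)


def _covariate_sample(config: SimulationConfig, n: int, rng) -> np.ndarray:
    K = config.n_covariates
    if K == 0:
        return np.empty((n, 0))
    # pooled covariate distribution across the two groups
    X = rng.standard_normal((n, K))
    half = n // 2
    X[:half] += config.confounding_shift
    return X


def true_disparity(config: SimulationConfig, n_covariate_draws: int = 4000,
                   seed: int = 12345) -> DisparityEstimates:
    """Closed-form MDM/RDM/ODM at the true parameters, averaging the
    digamma expressions over a large covariate sample (exact when K=0)."""
    rng = np.random.default_rng(seed)
    n = n_covariate_draws if config.n_covariates else 2
    X = _covariate_sample(config, n, rng)
    frame = StudyFrame(exposure=np.resize([1, 0], n), outcome=np.zeros(n),
                       covariates=X,
                       covariate_names=[f"X{k+1}" for k in
                                        range(config.n_covariates)])
    return compute_disparity(config.outcome_params, config.mediator_params,
                             frame, profile="average_over_sample")


def mc_disparity(config: SimulationConfig, n_draws: int = 100_000,
                 n_covariate_draws: int = 50, seed: int = 0):
    """Direct counterfactual Monte-Carlo evaluation of MDM and RDM.

    For covariates x: draw compositions under gamma(1, x) and gamma(0, x),
    push both through the outcome equation at R = 1, and difference the
    means; that estimates MDM.  RDM is estimated analogously by holding
    the composition at its R=0 law and toggling R in the outcome equation.
    Returns (mdm, rdm, se_mdm, se_rdm).
    """
    rng = np.random.default_rng(seed)
    X = _covariate_sample(config, n_covariate_draws, rng)
    mp, op = config.mediator_params, config.outcome_params
    per_x = max(n_draws // max(len(X), 1), 100)
    a_sum = op.taxon_main + op.taxon_interaction
    mdm_draws, rdm_draws = [], []
    for x in X:
        g1 = mp.concentrations(1, x)
        g0 = mp.concentrations(0, x)
        M1 = np.clip(rng.dirichlet(g1, size=per_x), 1e-300, None)
        M0 = np.clip(rng.dirichlet(g0, size=per_x), 1e-300, None)
        # E[Y_{M(1)} | R=1, x] - E[Y_{M(0)} | R=1, x]: only log-contrast
        # terms differ
        mdm_draws.append(np.log(M1) @ a_sum - np.log(M0) @ a_sum)
        # E[Y_{M(0)} | R=1, x] - E[Y_{M(0)} | R=0, x]
        rdm_draws.append(op.exposure_coef + np.log(M0) @ op.taxon_interaction)
    mdm_draws = np.concatenate(mdm_draws)
    rdm_draws = np.concatenate(rdm_draws)
    return (float(mdm_draws.mean()), float(rdm_draws.mean()),
            float(mdm_draws.std(ddof=1) / np.sqrt(len(mdm_draws))),
            float(rdm_draws.std(ddof=1) / np.sqrt(len(rdm_draws))))


def operating_characteristics(configs, n_replicates: int = 50, B: int = 200,
                              seed: int = 0, alpha: float = 0.05):
    """Bias/RMSE of the disparity estimators and empirical OMD/CMD
    rejection rates per configuration; returns a pandas DataFrame."""
    import pandas as pd

    from .inference import permutation_test
    from .model import DisparityMediationModel

    rows = []
    rng = np.random.default_rng(seed)
    for ci, config in enumerate(configs):
        truth = true_disparity(config)
        errs = {"mdm": [], "rdm": [], "odm": []}
        rejected = {"OMD": 0, "CMD": 0}
        done = 0
        for _ in range(n_replicates):
            rep_seed = int(rng.integers(2 ** 31 - 1))
            data = generate_dataset(config, seed=rep_seed)
            try:
                res = DisparityMediationModel(data).fit()
                omd, cmd = permutation_test(data, B=B, seed=rep_seed,
                                            observed=res.disparity)
            except (RuntimeError, ValueError, np.linalg.LinAlgError):
                continue
            est = res.disparity
            errs["mdm"].append(est.mdm - truth.mdm)
            errs["rdm"].append(est.rdm - truth.rdm)
            errs["odm"].append(est.odm - truth.odm)
            rejected["OMD"] += omd.p_value <= alpha
            rejected["CMD"] += cmd.p_value <= alpha
            done += 1
        row = {"config": ci, "n_per_group": config.n_per_group,
               "n_taxa": config.n_taxa, "n_replicates_done": done,
               "true_mdm": truth.mdm, "true_rdm": truth.rdm,
               "true_odm": truth.odm}
        for k, v in errs.items():
            v = np.asarray(v)
            row[f"bias_{k}"] = float(v.mean()) if v.size else np.nan
            row[f"rmse_{k}"] = float(np.sqrt((v ** 2).mean())) if v.size else np.nan
        for k in rejected:
            row[f"reject_{k.lower()}"] = rejected[k] / done if done else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
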