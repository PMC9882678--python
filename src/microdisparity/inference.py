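"""Permutation tests and bootstrap intervals for the mediated disparity.

Two statistics probe whether the microbiome carries any of the disparity:

* OMD — the MDM point estimate itself (community-level; two-sided by
  absolute value);
* CMD — the sum of squared per-taxon MDM_j estimates (component-wise;
  non-negative, one-sided by construction).

Null distributions come from permuting the exposure labels across
subjects while keeping (outcome, composition, covariates) rows intact —
exchangeable post-matching, where the covariate distribution no longer
differs between groups — and refitting both models per permutation.
P-values use the add-one formula (1 + count) / (B + 1), whose floor
1/(B+1) matches reporting significance as p < 0.001 at B = 1000.

Per-taxon uncertainty comes from a stratified nonparametric bootstrap
(resampling subjects within exposure group, preserving group sizes) with
percentile intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import MediationDataset, StudyFrame
from .dirichlet import DirichletRegressionParams, fit_dirichlet_regression
from .disparity import DisparityEstimates, compute_disparity
from .logcontrast import fit_constrained_ols, fit_penalized


@dataclass
class FitSpec:
    """Settings held fixed across permutation/bootstrap refits."""
    penalized: bool = False
    lambda_l1: float = 0.0
    lambda_group: float = 0.0
    profile: str = "average_over_sample"
    warm_start: DirichletRegressionParams | None = None


@dataclass
class TestResult:
    statistic_name: str
    observed: float
    permutation_values: np.ndarray
    p_value: float
    n_permutations: int
    seed: int
    n_failed: int = 0


@dataclass
class BootstrapCI:
    taxon_ids: list
    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    n_bootstrap: int
    seed: int
    samples: np.ndarray | None = field(default=None, repr=False)


def _resample(dataset: MediationDataset, idx: np.ndarray) -> MediationDataset:
    """Subset with replacement: fresh subject labels for duplicated rows."""
    from .datasets import CompositionMatrix

    ids = [f"b{i:05d}" for i in range(len(idx))]
    comp = CompositionMatrix(values=dataset.composition.values[idx],
                             subject_ids=ids,
                             taxon_ids=dataset.composition.taxon_ids)
    f = dataset.frame
    frame = StudyFrame(exposure=f.exposure[idx], outcome=f.outcome[idx],
                       covariates=f.covariates[idx],
                       covariate_names=f.covariate_names, subject_ids=ids)
    return MediationDataset(composition=comp, frame=frame)


def omd_statistic(est: DisparityEstimates) -> float:
    """Community-level statistic: the MDM estimate."""
    return est.mdm


def cmd_statistic(est: DisparityEstimates) -> float:
    """Component-wise statistic: sum_j MDM_j^2."""
    return float(np.sum(est.mdm_by_taxon ** 2))


def _fit_and_measure(dataset: MediationDataset, spec: FitSpec) -> DisparityEstimates:
    med = fit_dirichlet_regression(dataset, start=spec.warm_start)
    if not med.converged:
        raise RuntimeError("mediator refit did not converge")
    if spec.penalized:
        out = fit_penalized(dataset, lambda_l1=spec.lambda_l1,
                            lambda_group=spec.lambda_group).params
    else:
        out = fit_constrained_ols(dataset).params
    return compute_disparity(out, med.params, dataset.frame,
                             profile=spec.profile,
                             taxon_ids=dataset.composition.taxon_ids)


def permutation_test(dataset: MediationDataset, fit_spec: FitSpec | None = None,
                     B: int = 1000, seed: int = 0,
                     observed: DisparityEstimates | None = None):
    """Permutation test of H0: MDM = 0 (OMD) and H0: all MDM_j = 0 (CMD).

    Returns a (TestResult, TestResult) pair for (OMD, CMD).  Replicates
    whose mediator refit fails are dropped and counted; more than 10%
    dropped raises.
    """
    if B < 1:
        raise ValueError("need at least one permutation")
    spec = fit_spec or FitSpec()
    if observed is None:
        observed = _fit_and_measure(dataset, spec)
    if spec.warm_start is None:
        # warm-start permutation refits from the observed-data fit
        spec = FitSpec(**{**spec.__dict__,
                          "warm_start": fit_dirichlet_regression(dataset).params})
    omd_obs = omd_statistic(observed)
    cmd_obs = cmd_statistic(observed)
    rng = np.random.default_rng(seed)
    omd_perm, cmd_perm = [], []
    failed = 0
    frame = dataset.frame
    for _ in range(B):
        perm = rng.permutation(dataset.n_subjects)
        pframe = StudyFrame(exposure=frame.exposure[perm],
                            outcome=frame.outcome,
                            covariates=frame.covariates,
                            covariate_names=frame.covariate_names,
                            subject_ids=frame.subject_ids)
        pdata = MediationDataset(composition=dataset.composition, frame=pframe)
        try:
            est = _fit_and_measure(pdata, spec)
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            failed += 1
            continue
        omd_perm.append(omd_statistic(est))
        cmd_perm.append(cmd_statistic(est))
    if failed > 0.1 * B:
        raise RuntimeError(
            f"{failed}/{B} permutation replicates failed to converge")
    omd_perm = np.array(omd_perm)
    cmd_perm = np.array(cmd_perm)
    Beff = len(omd_perm)
    p_omd = (1 + np.sum(np.abs(omd_perm) >= abs(omd_obs))) / (Beff + 1)
    p_cmd = (1 + np.sum(cmd_perm >= cmd_obs)) / (Beff + 1)
    return (
        TestResult("OMD", omd_obs, omd_perm, float(p_omd), Beff, seed, failed),
        TestResult("CMD", cmd_obs, cmd_perm, float(p_cmd), Beff, seed, failed),
    )


def bootstrap_ci(dataset: MediationDataset, fit_spec: FitSpec | None = None,
                 B: int = 50, level: float = 0.95, seed: int = 0) -> BootstrapCI:
    """Percentile bootstrap intervals for each MDM_j, stratified by
    exposure group so every resample keeps the two group sizes."""
    if B < 20:
        raise ValueError("need at least 20 bootstrap replicates for percentiles")
    spec = fit_spec or FitSpec()
    point_est = _fit_and_measure(dataset, spec)
    if spec.warm_start is None:
        spec = FitSpec(**{**spec.__dict__,
                          "warm_start": fit_dirichlet_regression(dataset).params})
    rng = np.random.default_rng(seed)
    groups = [np.where(dataset.frame.exposure == g)[0] for g in (1, 0)]
    samples = []
    failed = 0
    for _ in range(B):
        idx = np.concatenate([rng.choice(g, size=len(g), replace=True)
                              for g in groups])
        bdata = _resample(dataset, idx)
        try:
            est = _fit_and_measure(bdata, spec)
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            failed += 1
            continue
        samples.append(est.mdm_by_taxon)
    if failed > 0.1 * B:
        raise RuntimeError(f"{failed}/{B} bootstrap replicates failed")
    S = np.vstack(samples)
    alpha = (1 - level) / 2
    lower = np.quantile(S, alpha, axis=0)
    upper = np.quantile(S, 1 - alpha, axis=0)
    return BootstrapCI(taxon_ids=list(dataset.composition.taxon_ids),
                       point=point_est.mdm_by_taxon, lower=lower, upper=upper,
                       level=level, n_bootstrap=len(samples), seed=seed,
                       samples=S)
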