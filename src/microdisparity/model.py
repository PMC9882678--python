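"""Model/Results front end for the disparity mediation analysis.

`DisparityMediationModel` wraps a composition + metadata pair (optionally
pre-filtered, zero-replaced and propensity-matched) and `fit()` returns a
`DisparityMediationResults` carrying both fitted models, the disparity
decomposition, and methods for permutation tests, bootstrap intervals and
a text summary.

Example
-------
>>> from microdisparity import simulate, DisparityMediationModel
>>> data = simulate.generate_dataset(simulate.default_scenario(seed=1))
>>> res = DisparityMediationModel(data).fit()
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import datasets, matching
from .datasets import CompositionMatrix, MediationDataset, StudyFrame
from .dirichlet import MediatorFitReport, fit_dirichlet_regression
from .disparity import DisparityEstimates, compute_disparity
from .inference import (BootstrapCI, FitSpec, TestResult, bootstrap_ci,
                        permutation_test)
from .logcontrast import (OlsFitReport, PenalizedFitReport, fit_constrained_ols,
                          fit_penalized, select_tuning)


class DisparityMediationModel:
    """Mediation decomposition of a two-group disparity through the
    microbiome.

    Parameters
    ----------
    dataset : MediationDataset
        Aligned composition + study frame; zeros are replaced on entry if
        present.
    match : bool, default False
        Run propensity-score matching first and fit on the matched subset.
    caliper : float
        Matching caliper in logit-SD units.
    filter_kwargs : dict, optional
        Passed to :func:`datasets.filter_taxa` before fitting.
    seed : int
        Seed for the matching order.
    """

    def __init__(self, dataset: MediationDataset, match: bool = False,
                 caliper: float = 0.2, filter_kwargs: dict | None = None,
                 seed: int = 0):
        comp = dataset.composition
        if filter_kwargs:
            comp = datasets.filter_taxa(comp, **filter_kwargs)
        comp = datasets.replace_zeros(comp)
        dataset = MediationDataset(composition=comp, frame=dataset.frame)
        self.match_result = None
        self.propensity = None
        if match:
            dataset, self.match_result, self.propensity = \
                matching.match_dataset(dataset, caliper=caliper, seed=seed)
        report = datasets.validate(dataset)
        if not report:
            raise ValueError("invalid dataset: " + "; ".join(report.violations))
        self.dataset = dataset

    @classmethod
    def from_dataframes(cls, abundance: pd.DataFrame, metadata: pd.DataFrame,
                        exposure_col: str, outcome_col: str,
                        covariate_cols=(), reference_level=None,
                        **kwargs) -> "DisparityMediationModel":
        """Build from in-memory pandas objects (subjects as rows in both)."""
        common = [s for s in abundance.index.astype(str)
                  if s in set(metadata.index.astype(str))]
        abundance = abundance.loc[common]
        metadata = metadata.loc[common]
        values = abundance.to_numpy(dtype=float)
        values = values / values.sum(axis=1, keepdims=True)
        comp = CompositionMatrix(values=values,
                                 subject_ids=[str(s) for s in abundance.index],
                                 taxon_ids=[str(t) for t in abundance.columns])
        exposure = (metadata[exposure_col].astype(str)
                    == str(reference_level)).astype(int).to_numpy()
        cov = metadata[list(covariate_cols)].to_numpy(dtype=float) \
            if covariate_cols else np.empty((len(metadata), 0))
        frame = StudyFrame(exposure=exposure,
                           outcome=metadata[outcome_col].astype(float).to_numpy(),
                           covariates=cov,
                           covariate_names=list(covariate_cols),
                           subject_ids=[str(s) for s in metadata.index])
        return cls(MediationDataset(composition=comp, frame=frame), **kwargs)

    def fit(self, penalized: bool = False, lambda_grid=None,
            criterion: str = "bic", lambda_l1: float | None = None,
            lambda_group: float | None = None,
            seed: int = 0) -> "DisparityMediationResults":
        """Fit mediator and outcome models and compute the decomposition.

        With ``penalized=True`` the outcome model is the sparse-group fit;
        explicit ``lambda_l1``/``lambda_group`` skip tuning, otherwise the
        pair is selected on ``lambda_grid`` by ``criterion``.
        """
        med = fit_dirichlet_regression(self.dataset, compute_cov=True)
        penalized_report = None
        if penalized:
            if lambda_l1 is not None and lambda_group is not None:
                penalized_report = fit_penalized(self.dataset, lambda_l1,
                                                 lambda_group)
            else:
                penalized_report = select_tuning(self.dataset, grid=lambda_grid,
                                                 criterion=criterion, seed=seed)
            out_params = penalized_report.params
            ols_report = None
            spec = FitSpec(penalized=True,
                           lambda_l1=penalized_report.lambda_l1,
                           lambda_group=penalized_report.lambda_group)
        else:
            ols_report = fit_constrained_ols(self.dataset)
            out_params = ols_report.params
            spec = FitSpec()
        est = compute_disparity(out_params, med.params, self.dataset.frame,
                                taxon_ids=self.dataset.composition.taxon_ids)
        return DisparityMediationResults(
            model=self, mediator_fit=med, ols_fit=ols_report,
            penalized_fit=penalized_report, disparity=est, fit_spec=spec)


@dataclass
class DisparityMediationResults:
    """Estimates, diagnostics and inference for a fitted decomposition."""

    model: DisparityMediationModel
    mediator_fit: MediatorFitReport
    ols_fit: OlsFitReport | None
    penalized_fit: PenalizedFitReport | None
    disparity: DisparityEstimates
    fit_spec: FitSpec

    @property
    def outcome_params(self):
        return (self.penalized_fit or self.ols_fit).params

    @property
    def selected_taxa(self) -> list:
        if self.penalized_fit is not None:
            return self.penalized_fit.selected_taxa
        return list(self.model.dataset.composition.taxon_ids)

    def mdm_frame(self) -> pd.DataFrame:
        """Per-taxon MDM_j as a DataFrame indexed by taxon."""
        return pd.DataFrame(
            {"mdm_j": self.disparity.mdm_by_taxon},
            index=self.model.dataset.composition.taxon_ids)

    def permutation_test(self, B: int = 1000, seed: int = 0):
        """OMD and CMD permutation tests on the fitted dataset."""
        return permutation_test(self.model.dataset, fit_spec=self.fit_spec,
                                B=B, seed=seed, observed=self.disparity)

    def bootstrap_ci(self, B: int = 50, level: float = 0.95,
                     seed: int = 0) -> BootstrapCI:
        """Stratified percentile bootstrap intervals for each MDM_j."""
        return bootstrap_ci(self.model.dataset, fit_spec=self.fit_spec,
                            B=B, level=level, seed=seed)

    def summary(self, tests: tuple[TestResult, TestResult] | None = None) -> str:
        est = self.disparity
        n = self.model.dataset.n_subjects
        lines = [
            "Disparity mediation decomposition",
            "=" * 49,
            f"subjects: {n}    taxa: {self.model.dataset.n_taxa}"
            f"    covariates: {self.model.dataset.frame.n_covariates}",
        ]
        if self.model.match_result is not None:
            mr = self.model.match_result
            lines.append(
                f"matched pairs: {mr.n_pairs}    pooled SMD "
                f"{mr.smd_before['pooled']:.3f} -> {mr.smd_after['pooled']:.3f}")
        lines += [
            "-" * 49,
            f"ODM (overall disparity)        {est.odm:10.2f}",
            f"MDM (microbiome-manipulable)   {est.mdm:10.2f}",
            f"RDM (residual)                 {est.rdm:10.2f}",
        ]
        if est.percent_mediated is not None:
            lines.append(f"percent mediated               "
                         f"{est.percent_mediated:9.2f}%")
        if self.penalized_fit is not None:
            lines.append(f"selected taxa: {len(self.penalized_fit.selected_taxa)}"
                         f" (lambda_group={self.penalized_fit.lambda_group:.4g},"
                         f" lambda_l1={self.penalized_fit.lambda_l1:.4g})")
        if tests is not None:
            for t in tests:
                lines.append(f"{t.statistic_name}: observed {t.observed:.4f}, "
                             f"p = {t.p_value:.4g} ({t.n_permutations} perms)")
        lines.append(f"mediator loglik {self.mediator_fit.loglik:.2f} "
                     f"(converged={self.mediator_fit.converged})")
        return "\n".join(lines)
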