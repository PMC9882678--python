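"""Core data containers, readers, taxa filtering and zero replacement.

The mediator in this framework is a microbial composition: a vector of
relative abundances on the simplex (non-negative, summing to one).  All
downstream models take logs of the composition or evaluate a Dirichlet
likelihood, so zeros must be replaced before modelling; this module owns
that preprocessing along with prevalence/abundance filtering and dataset
validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLOSURE_TOL = 1e-8


class DataFormatError(ValueError):
    """Raised when an input table violates the format contract."""


@dataclass
class CompositionMatrix:
    """Subjects x taxa relative abundances on the simplex.

    Parameters
    ----------
    values : ndarray, shape (n_subjects, n_taxa)
        Relative abundances; each row sums to 1 after closure.
    subject_ids : list of str
    taxon_ids : list of str
    """

    values: np.ndarray
    subject_ids: list
    taxon_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.subject_ids = list(self.subject_ids)
        self.taxon_ids = list(self.taxon_ids)
        if self.values.ndim != 2:
            raise DataFormatError("composition values must be a 2-D array")
        if self.values.shape != (len(self.subject_ids), len(self.taxon_ids)):
            raise DataFormatError("composition shape does not match identifier lists")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise DataFormatError("duplicated subject identifiers")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise DataFormatError("duplicated taxon identifiers")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.taxon_ids)

    def is_strictly_positive(self) -> bool:
        return bool(np.all(self.values > 0))


@dataclass
class StudyFrame:
    """Per-subject exposure, outcome and covariates.

    ``exposure`` is coded 1 for the reference group and 0 for the
    comparison group.  Categorical covariates are expected to be expanded
    to indicator columns upstream (``read_metadata`` does this).
    """

    exposure: np.ndarray
    outcome: np.ndarray
    covariates: np.ndarray
    covariate_names: list
    subject_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.exposure = np.asarray(self.exposure, dtype=int)
        self.outcome = np.asarray(self.outcome, dtype=float)
        cov = np.asarray(self.covariates, dtype=float)
        if cov.size == 0:
            cov = np.empty((self.exposure.shape[0], 0))
        elif cov.ndim == 1:
            cov = cov[:, None]
        self.covariates = cov
        self.covariate_names = list(self.covariate_names)
        if not self.subject_ids:
            self.subject_ids = [f"S{i}" for i in range(len(self.exposure))]
        self.subject_ids = list(self.subject_ids)

    @property
    def n_subjects(self) -> int:
        return len(self.exposure)

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    def subset(self, idx) -> "StudyFrame":
        idx = np.asarray(idx)
        return StudyFrame(
            exposure=self.exposure[idx],
            outcome=self.outcome[idx],
            covariates=self.covariates[idx],
            covariate_names=self.covariate_names,
            subject_ids=[self.subject_ids[i] for i in idx],
        )


@dataclass
class MediationDataset:
    """Aligned composition + study frame pair consumed by the models."""

    composition: CompositionMatrix
    frame: StudyFrame

    @property
    def n_subjects(self) -> int:
        return self.composition.n_subjects

    @property
    def n_taxa(self) -> int:
        return self.composition.n_taxa

    def subset(self, idx) -> "MediationDataset":
        idx = np.asarray(idx)
        comp = CompositionMatrix(
            values=self.composition.values[idx],
            subject_ids=[self.composition.subject_ids[i] for i in idx],
            taxon_ids=self.composition.taxon_ids,
        )
        return MediationDataset(composition=comp, frame=self.frame.subset(idx))


@dataclass
class ValidationReport:
    passed: bool
    violations: list

    def __bool__(self):
        return self.passed


def _close_rows(values: np.ndarray) -> np.ndarray:
    sums = values.sum(axis=1, keepdims=True)
    return values / sums


def read_abundance_table(path, fmt: str = "tsv",
                         orientation: str = "subjects_as_rows") -> CompositionMatrix:
    """Read a taxa table from TSV/CSV and close rows to the simplex.

    Counts are auto-detected by row sums (rows all ~1 mean the table is
    already closed) and converted to relative abundances by row closure.
    Subjects with an all-zero row are dropped with a warning.
    """
    if fmt not in {"tsv", "csv"}:
        raise DataFormatError(f"unsupported format: {fmt!r} (expected 'tsv' or 'csv')")
    sep = "\t" if fmt == "tsv" else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "taxa_as_rows":
        df = df.T
    elif orientation != "subjects_as_rows":
        raise DataFormatError(f"unknown orientation: {orientation!r}")
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        raise DataFormatError("negative entries in abundance table")
    row_sums = values.sum(axis=1)
    zero_rows = row_sums == 0
    if zero_rows.any():
        dropped = [str(s) for s in df.index[zero_rows]]
        logger.warning("dropping %d all-zero subjects: %s", len(dropped), dropped)
        df = df.loc[~zero_rows]
        values = values[~zero_rows]
        row_sums = row_sums[~zero_rows]
    already_closed = np.allclose(row_sums, 1.0, atol=1e-4)
    if not already_closed:
        logger.info("input rows do not sum to 1; treating as counts and closing")
    values = _close_rows(values)
    return CompositionMatrix(
        values=values,
        subject_ids=[str(s) for s in df.index],
        taxon_ids=[str(t) for t in df.columns],
    )


def write_abundance_table(comp: CompositionMatrix, path, fmt: str = "tsv") -> None:
    sep = "\t" if fmt == "tsv" else ","
    comp.to_frame().to_csv(path, sep=sep)


def read_metadata(path, exposure_col: str, outcome_col: str,
                  covariate_cols=(), reference_level=None,
                  fmt: str | None = None) -> StudyFrame:
    """Read subject metadata and code it as a :class:`StudyFrame`.

    The exposure column must have exactly two levels; subjects at
    ``reference_level`` get R=1.  Categorical covariates are one-hot
    encoded with the first level dropped.
    """
    if fmt is None:
        fmt = "csv" if str(path).endswith(".csv") else "tsv"
    sep = "\t" if fmt == "tsv" else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    covariate_cols = list(covariate_cols)
    needed = [exposure_col, outcome_col] + covariate_cols
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise DataFormatError(f"metadata is missing columns: {missing_cols}")
    sub = df[needed]
    na_mask = sub.isna().any(axis=1)
    if na_mask.any():
        offenders = [str(s) for s in df.index[na_mask]]
        raise DataFormatError(
            f"missing values in used metadata columns for subjects: {offenders}")
    levels = sorted(sub[exposure_col].astype(str).unique())
    if len(levels) != 2:
        raise DataFormatError(
            f"exposure column {exposure_col!r} must have exactly 2 levels, got {levels}")
    if reference_level is None:
        reference_level = levels[0]
        logger.info("reference_level not given; using %r", reference_level)
    if str(reference_level) not in levels:
        raise DataFormatError(
            f"reference_level {reference_level!r} not among exposure levels {levels}")
    exposure = (sub[exposure_col].astype(str) == str(reference_level)).astype(int).to_numpy()
    outcome = sub[outcome_col].astype(float).to_numpy()
    cov_parts = []
    for col in covariate_cols:
        s = sub[col]
        if pd.api.types.is_numeric_dtype(s):
            cov_parts.append(s.astype(float).to_frame())
        else:
            dummies = pd.get_dummies(s.astype(str), prefix=col, drop_first=True)
            cov_parts.append(dummies.astype(float))
    if cov_parts:
        cov = pd.concat(cov_parts, axis=1)
        covariates = cov.to_numpy(dtype=float)
        covariate_names = list(cov.columns)
    else:
        covariates = np.empty((len(df), 0))
        covariate_names = []
    return StudyFrame(
        exposure=exposure,
        outcome=outcome,
        covariates=covariates,
        covariate_names=covariate_names,
        subject_ids=[str(s) for s in df.index],
    )


def filter_taxa(comp: CompositionMatrix, min_prevalence: float = 0.2,
                min_mean_abundance: float = 1e-4) -> CompositionMatrix:
    """Keep taxa present in >= min_prevalence of subjects with mean
    relative abundance >= min_mean_abundance; re-close surviving rows."""
    if not (0 <= min_prevalence <= 1 and 0 <= min_mean_abundance <= 1):
        raise ValueError("filter thresholds must lie in [0, 1]")
    prevalence = (comp.values > 0).mean(axis=0)
    mean_ab = comp.values.mean(axis=0)
    keep = (prevalence >= min_prevalence) & (mean_ab >= min_mean_abundance)
    if keep.sum() < 2:
        raise ValueError(
            f"only {int(keep.sum())} taxa survive filtering "
            f"(min_prevalence={min_prevalence}, min_mean_abundance={min_mean_abundance}); "
            "loosen the thresholds")
    values = _close_rows(comp.values[:, keep])
    kept_ids = [t for t, k in zip(comp.taxon_ids, keep) if k]
    logger.info("filter_taxa kept %d of %d taxa", len(kept_ids), comp.n_taxa)
    return CompositionMatrix(values=values, subject_ids=comp.subject_ids,
                             taxon_ids=kept_ids)


def replace_zeros(comp: CompositionMatrix, strategy: str = "multiplicative_pseudocount",
                  pseudo_fraction: float = 0.5) -> CompositionMatrix:
    """Replace zeros with pseudo_fraction x (smallest nonzero relative
    abundance in the table) and re-close each row.

    Required before any log or Dirichlet operation; positive tables pass
    through unchanged.
    """
    if strategy != "multiplicative_pseudocount":
        raise ValueError(f"unknown zero-replacement strategy: {strategy!r}")
    values = comp.values
    if np.any(values.sum(axis=1) == 0):
        raise ValueError("all-zero subject row; drop it at read time")
    if np.all(values > 0):
        return comp
    pseudo = pseudo_fraction * values[values > 0].min()
    out = np.where(values == 0, pseudo, values)
    out = _close_rows(out)
    return CompositionMatrix(values=out, subject_ids=comp.subject_ids,
                             taxon_ids=comp.taxon_ids)


def validate(dataset: MediationDataset) -> ValidationReport:
    """Check all dataset invariants; returns an itemized report."""
    violations = []
    comp, frame = dataset.composition, dataset.frame
    row_sums = comp.values.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=CLOSURE_TOL):
        bad = int(np.sum(np.abs(row_sums - 1.0) > CLOSURE_TOL))
        violations.append(f"closure violated in {bad} rows (rows must sum to 1)")
    if np.any(comp.values < 0):
        violations.append("negative abundances present")
    if comp.subject_ids != frame.subject_ids:
        violations.append("subject ordering differs between composition and frame")
    levels = set(np.unique(frame.exposure))
    if not levels <= {0, 1}:
        violations.append(f"exposure takes values outside {{0,1}}: {sorted(levels)}")
    elif levels != {0, 1}:
        violations.append("one exposure group is empty")
    if np.any(~np.isfinite(frame.outcome)):
        violations.append("non-finite outcome values")
    if frame.covariates.size and np.any(~np.isfinite(frame.covariates)):
        violations.append("non-finite covariate values")
    J, K = comp.n_taxa, frame.n_covariates
    if J < 2:
        violations.append(f"need at least 2 taxa, got {J}")
    if dataset.n_subjects <= J + K + 2:
        violations.append(
            f"need n > J + K + 2 = {J + K + 2} subjects for the unpenalized fit, "
            f"got {dataset.n_subjects}")
    return ValidationReport(passed=not violations, violations=violations)
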