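"""Propensity-score matching and covariate-balance diagnostics.

Exposure groups in disparity studies (race, region) cannot be randomized,
so confounding control is a mandatory preprocessing stage: a logistic
propensity model of exposure on covariates, 1:1 greedy nearest-neighbor
matching on the logit of the score without replacement (caliper in
logit-SD units), and standardized-mean-difference diagnostics before and
after.  An SMD below 0.1 is read as covariate balance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .datasets import MediationDataset, StudyFrame


@dataclass
class PropensityFit:
    coefficients: np.ndarray   # [intercept, covariates...]
    scores: np.ndarray         # P(R=1 | x) per subject, in subject order

    def logit_scores(self) -> np.ndarray:
        s = np.clip(self.scores, 1e-12, 1 - 1e-12)
        return np.log(s / (1 - s))


@dataclass
class MatchResult:
    pairs: list                       # (reference idx, comparison idx)
    smd_before: dict                  # per-covariate + "pooled"
    smd_after: dict

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def matched_indices(self) -> np.ndarray:
        return np.sort(np.array([i for p in self.pairs for i in p], dtype=int))


def estimate_propensity(frame: StudyFrame) -> PropensityFit:
    """Logistic regression of exposure on covariates by maximum likelihood."""
    if frame.n_covariates == 0:
        raise ValueError("propensity model needs at least one covariate")
    counts = np.bincount(frame.exposure, minlength=2)
    if counts.min() == 0:
        raise ValueError("both exposure groups must be non-empty")
    X = sm.add_constant(frame.covariates, has_constant="add")
    try:
        res = sm.Logit(frame.exposure, X).fit(disp=False, maxiter=200)
    except PerfectSeparationError as exc:
        raise ValueError(
            "perfect separation in the propensity model; prune covariates"
        ) from exc
    if not np.all(np.isfinite(res.params)) or np.max(np.abs(res.params)) > 50:
        raise ValueError(
            "propensity model did not stabilize (near separation); "
            "prune or rescale covariates")
    scores = np.clip(res.predict(X), 1e-12, 1 - 1e-12)
    return PropensityFit(coefficients=np.asarray(res.params), scores=scores)


def standardized_mean_difference(x, groups) -> float:
    """|mean1 - mean0| / sqrt((s1^2 + s0^2) / 2) with within-group sample
    variances; +inf when the pooled variance is zero but the means differ."""
    x = np.asarray(x, dtype=float)
    groups = np.asarray(groups)
    x1, x0 = x[groups == 1], x[groups == 0]
    if len(x1) < 2 or len(x0) < 2:
        raise ValueError("both groups need at least 2 subjects for an SMD")
    diff = abs(x1.mean() - x0.mean())
    pooled = np.sqrt((x1.var(ddof=1) + x0.var(ddof=1)) / 2)
    if pooled == 0:
        return 0.0 if diff == 0 else float("inf")
    return float(diff / pooled)


def _smd_table(frame: StudyFrame, scores: np.ndarray, idx=None) -> dict:
    if idx is None:
        idx = np.arange(frame.n_subjects)
    g = frame.exposure[idx]
    out = {}
    for k, name in enumerate(frame.covariate_names):
        out[name] = standardized_mean_difference(frame.covariates[idx, k], g)
    out["pooled"] = standardized_mean_difference(scores[idx], g)
    return out


def match_pairs(fit: PropensityFit, frame: StudyFrame, caliper: float = 0.2,
                seed: int = 0) -> MatchResult:
    """Greedy 1:1 nearest-neighbor matching on the logit propensity score.

    Without replacement; candidate pairs farther than caliper x SD(logit
    scores) are discarded; reference subjects are processed in an order
    randomized by ``seed``, and equidistant candidates break ties toward
    the lowest index after a seeded shuffle.
    """
    logit = fit.logit_scores()
    ref_idx = np.where(frame.exposure == 1)[0]
    cmp_idx = np.where(frame.exposure == 0)[0]
    sd = logit.std(ddof=1)
    max_dist = caliper * sd
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ref_idx))
    cmp_shuffled = rng.permutation(len(cmp_idx))
    # tie-break key: position after seeded shuffle
    tie_rank = np.empty(len(cmp_idx), dtype=int)
    tie_rank[cmp_shuffled] = np.arange(len(cmp_idx))
    available = np.ones(len(cmp_idx), dtype=bool)
    cmp_logit = logit[cmp_idx]
    pairs = []
    for oi in order:
        r = ref_idx[oi]
        if not available.any():
            break
        d = np.abs(cmp_logit - logit[r])
        d[~available] = np.inf
        best = np.lexsort((tie_rank, d))[0]
        if d[best] <= max_dist:
            pairs.append((int(r), int(cmp_idx[best])))
            available[best] = False
    if not pairs:
        lo = max(logit[ref_idx].min(), logit[cmp_idx].min())
        hi = min(logit[ref_idx].max(), logit[cmp_idx].max())
        raise ValueError(
            "no matched pairs formed: propensity-score overlap on the logit "
            f"scale is [{lo:.3f}, {hi:.3f}] with caliper {caliper} x SD = "
            f"{max_dist:.3f}; widen the caliper or prune covariates")
    matched = np.sort(np.array([i for p in pairs for i in p]))
    return MatchResult(pairs=pairs,
                       smd_before=_smd_table(frame, fit.scores),
                       smd_after=_smd_table(frame, fit.scores, matched))


def match_dataset(dataset: MediationDataset, caliper: float = 0.2,
                  seed: int = 0) -> tuple[MediationDataset, MatchResult, PropensityFit]:
    """Convenience wrapper: estimate scores, match, and subset the dataset
    to the matched subjects."""
    fit = estimate_propensity(dataset.frame)
    result = match_pairs(fit, dataset.frame, caliper=caliper, seed=seed)
    return dataset.subset(result.matched_indices()), result, fit
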