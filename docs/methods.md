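# Methods

## The problem

Health-disparity studies compare a continuous outcome (e.g. BMI) between
two groups defined by a non-manipulable exposure such as race or region.
No intervention on the exposure itself is conceivable, so the causally
actionable question shifts to the mediator: how much of the between-group
gap would disappear if the gut-microbiome composition of the comparison
group were set to that of the reference group?  `microdisparity`
estimates exactly that quantity.

## Model

Let `R ∈ {0,1}` be the exposure (1 = reference group), `X` a K-vector of
covariates, `M = (M_1, …, M_J)` the taxa relative abundances with
`Σ_j M_j = 1`, and `Y` the outcome.

**Outcome model (linear log-contrast).**

    Y = α0 + αR·R + αX'X + αM'·log M + αC'·(log M)·R + ε,   ε ~ N(0, σ²)
    subject to Σ_j αMj = 0 and Σ_j αCj = 0.

The zero-sum constraints make the log-contrast terms invariant to the
simplex closure and give the taxon coefficients a compositional
interpretation.

**Mediator model (Dirichlet regression).**

    M | (R, X) ~ Dirichlet(γ_1(R,X), …, γ_J(R,X)),
    log γ_j(r, x) = β0j + βRj·r + βXj'x.

There is no separate precision parameter; the total concentration
`Σ_j γ_j` carries dispersion implicitly.

**Disparity decomposition.**  With `E[log M_j | R=r, x] = ψ(γ_j(r,x)) −
ψ(Σ_m γ_m(r,x))` (ψ the digamma function),

    MDM_j = (αMj + αCj) · { E[log M_j | R=1, x] − E[log M_j | R=0, x] }
    MDM   = Σ_j MDM_j
    RDM   = αR + Σ_j αCj · E[log M_j | R=0, x]
    ODM   = MDM + RDM.

ODM is the overall expected outcome gap at covariates `x`; MDM is the
portion removable by equalizing microbiome profiles; RDM is what remains.
`MDM_j` is non-zero only when taxon j sits on both legs of the mediation
path.  The identities `ODM = MDM + RDM` and `MDM = Σ_j MDM_j` hold by
construction and are asserted on every computation.

**Identifying assumptions.** `Y ⊥ R | X` and `Y ⊥ M | R, X` — no
unmeasured exposure–outcome or mediator–outcome confounding given the
covariates.  No sensitivity analysis for their violation is implemented.

**Covariate profile.**  The definitions carry an outer expectation over
`x`.  The default averages the per-subject measures over the analysis
sample's empirical covariate rows; after matching, the two groups share
one covariate distribution, so pooling all matched subjects is the
natural choice.  A `fixed_x` profile evaluates at a user-supplied vector.
Where the two give different numbers, the profile used is recorded in the
estimate object.

**A note on label swaps.**  Because MDM and RDM are evaluated in the
reference group, swapping the group coding negates all three measures
only when `αC = 0`; with exposure×taxon interactions the decomposition is
deliberately reference-group-centric, not antisymmetric.  Choose the
reference level explicitly.

## Estimation

1. *Mediator*: exact maximum likelihood by L-BFGS with the analytic
   gradient of the Dirichlet log-likelihood; moment-based start
   (intercepts from the mean composition and a crude method-of-moments
   total concentration, other effects zero); convergence at max-abs
   gradient 1e-6; standard errors from the analytic observed information.
   The fit is unpenalized — sparsity enters only through the outcome
   side, and a taxon's MDM_j inherits a zero from `αMj + αCj = 0`.
2. *Outcome, unpenalized*: least squares after eliminating the two
   constraints with an orthonormal (Helmert) basis of the zero-sum
   subspace, so the solution is unique and taxon-order invariant;
   `σ² = RSS/(n − 2 − K − 2(J−1))`.
3. *Outcome, penalized*: minimizes

       RSS/(2n) + λ_g Σ_j ‖(αMj, αCj)‖₂ + λ_1 Σ_j |αCj|

   under the constraints, by ADMM with a consensus split on
   `(αM, αC)`.  The z-update is the sparse-group proximal operator
   (soft-threshold the interaction coordinate, then radially shrink the
   pair); the θ-update is a KKT solve with the equality constraints.
   ADMM runs to primal/dual residuals below 1e-10 (max 5000 iterations,
   ρ=1); the active support is then re-centred to satisfy the zero-sum
   constraints exactly and near-zero coefficients are exact zeros.
   Heredity (`αCj ≠ 0 ⇒ αMj ≠ 0`) usually emerges from the group
   penalty; any violation is zeroed and the problem re-solved with those
   coordinates fixed.  At `λ_g = λ_1 = 0` the fit short-circuits to the
   constrained OLS.
4. *Tuning*: BIC (default) or seeded 5-fold CV over a log-spaced
   `(λ_g, λ_1)` grid; the BIC degrees of freedom count the non-zero
   coefficients less one per non-empty constrained block; ties break
   toward the larger total penalty (the sparser model).

## Confounding control

Propensity scores come from a maximum-likelihood logistic regression of
exposure on covariates.  Matching is greedy 1:1 nearest-neighbor on the
logit of the score, without replacement, processing order randomized by
seed, discarding candidate pairs farther than `caliper × SD(logit
scores)` (default caliper 0.2).  Balance is summarized by the
standardized mean difference, `|mean₁ − mean₀| / √((s₁² + s₀²)/2)`, per
covariate and pooled (the SMD of the propensity score itself); SMD < 0.1
is read as balanced.

Greedy matching without replacement at a tight caliper discards subjects
whose remaining candidates all sit outside the window: even with
identically distributed scores, the default caliper retains roughly
80–90% of the smaller group (local depletion near the distribution edges
forces distant matches that the caliper rejects).  Loosening the caliper
toward 1–2 SD retains essentially everyone at the cost of worse pair
distances.  The caliper is a configurable trade-off, not a fitted
quantity.

## Inference

* **OMD** (= the MDM estimate; two-sided by absolute value) and **CMD**
  (= Σ_j MDM_j²; one-sided, non-negative) are tested by permuting the
  exposure labels across subjects, keeping (Y, M, X) rows intact, and
  refitting both models per permutation.  This scheme is valid when
  labels are exchangeable under the null — i.e. after matching has
  removed covariate imbalance; running it on unmatched confounded data
  conflates confounding with mediation.  P-values use the add-one
  formula `(1 + count)/(B + 1)`, with floor `1/(B+1)`; default B = 1000.
  Tuning parameters are held at the values selected on the observed data
  (re-tuning per replicate is disproportionately expensive and makes the
  permutation distribution noisier).
* **Per-taxon intervals**: nonparametric bootstrap resampling subjects
  within exposure group (preserving group sizes), percentile intervals,
  default B = 50 at level 0.95 — percentile is the least
  assumption-laden choice that small replicate counts support.
* Permutation/bootstrap replicates whose mediator refit fails are
  dropped and counted; more than 10% failures aborts.

## Synthetic data

`simulate.default_scenario` emulates a two-group observational study
drawn exactly from the model above: J = 20 taxa of which 3 are true
mediators (alternating-sign effect patterns, zero-sum within the active
set), K = 2 standard-normal covariates with small effects on both
models, n = 150 per group, outcome noise σ = 1, baseline concentrations
totalling ≈ 30.  Confounding, when requested, is a per-covariate mean
shift between groups, so matching has a well-defined target.
`null_scenario` sets βR = 0 and αC = 0 (no mediation path) while keeping
taxon main effects.  `true_disparity` evaluates the closed forms at the
true parameters over a large covariate sample; `mc_disparity` estimates
the same quantities by direct counterfactual simulation (draw M under
each exposure law, push through the outcome equation, difference the
means).  Closed form and Monte Carlo agreeing is the standing
end-to-end check of the whole pipeline.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: multinomial sequencing/count
noise, zero inflation (zeros here arise only from numerical underflow of
tiny Dirichlet draws), phylogenetic or co-occurrence correlation beyond
the Dirichlet's intrinsic negative covariance, model misspecification of
either regression, and longitudinal structure.

## Numerical choices and degenerate inputs

* Compositions must be strictly positive before any log or Dirichlet
  operation; zeros are replaced by `0.5 × (smallest non-zero relative
  abundance in the table)` followed by row re-closure.  All-zero subject
  rows are dropped at read time with a warning.
* Taxa filtering keeps taxa present in ≥ 20% of subjects with mean
  relative abundance ≥ 1e-4 (both configurable); fewer than 2 survivors
  is an error.
* Count tables are auto-detected by row sums and closed to the simplex.
* Closure is checked at 1e-8; decomposition identities at 1e-10.
* Equidistant matching candidates break ties toward the lowest index
  after a seeded shuffle, making every run reproducible from its seed.
* Degenerate designs (collinear covariates, rank deficiency, a single
  exposure group, perfect separation in the propensity model) raise
  informative errors rather than fitting.

## Problem sizes used in the shipped checks

Simulation-based checks run at desk scale, chosen to keep the full suite
in minutes on one core while leaving Monte-Carlo error well below the
tested effect sizes: estimator bias over 50 replicates of the reference
scenario; RMSE consistency across total n ∈ {100, 300, 1000}; test size
over 200 replicates × 200 permutations (100 × 100 in the acceptance
script); oracle comparisons at 1e5 draws.

## Known limitations

* Continuous outcomes only; no categorical/binary outcome model.
* No zero-inflated or Dirichlet-multinomial mediator variants; no
  longitudinal or clustered designs.
* No IPW, full/optimal matching, or doubly-robust estimation; matching
  is the only confounding-control strategy.
* No multiplicity adjustment across per-taxon intervals.
* Selection consistency of the sparse fit degrades when true mediators
  are highly correlated with non-mediators, as for any lasso-type
  penalty.
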