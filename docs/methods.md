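# Methods

## Model

`peann` estimates the hazard function h(t; x) of right-censored survival data
as a single-hidden-layer feed-forward network on the log-hazard scale:

    h(t; x) = exp( β₀⁽²⁾ + Σ_{k=1..H} z_k β_k⁽²⁾ ),
    z_k     = logistic( β₀ₖ⁽¹⁾ + Σ_{l=1..p} x_l β_{lk}⁽¹⁾ + t β_{p+1,k}⁽¹⁾ ).

Positivity of the hazard is automatic through the exponential output; the
log-hazard is a smooth, non-additive function of time and covariates, so
time-dependent effects and covariate interactions need no explicit terms.

Estimation uses the piecewise exponential device: follow-up is cut into
intervals (a_{j-1}, a_j] (default 3-month intervals up to a 72-month
administrative horizon) and each subject contributes one person-period row per
interval at risk, carrying the event indicator d_ij, the exposure τ_ij in
months, and the interval midpoint t_j at which the hazard is evaluated.
The fitted objective is the penalized negative log-likelihood

    E = -Σ_ij [ d_ij log h(t_j; x_i) - h(t_j; x_i) τ_ij ]  +  λ Σ β²,

which is, up to the parameter-free constant Σ d log τ, a Poisson regression
likelihood with offset log τ (a test asserts this equivalence against
`scipy.stats.poisson` to 1e-10). The quadratic penalty runs over **all**
coefficients, biases included. The sum over hidden-unit index k runs 1..H for
the first layer (a k = 0 first-layer term would reference a hidden unit that
does not exist in this architecture).

## Data conventions

* Intervals are left-open right-closed; an event exactly on a boundary
  belongs to the interval that ends there (life-table convention).
* Follow-up beyond the horizon a_J is administratively censored at a_J.
* Categorical covariates are dummy-coded against a reference level;
  continuous covariates are min-max scaled to [0, 1]; the time input is
  t_j / a_J ∈ (0, 1]. Logistic hidden units saturate on month-scale inputs
  and a quadratic penalty is scale-dependent, so unscaled inputs would make
  the decay parameter uninterpretable. All scaling metadata is stored with
  the model; prediction APIs take months and raw covariate values.
* Missing values and undeclared categorical levels are rejected, never
  repaired.

## Optimization

The objective is minimized by quasi-Newton BFGS (`scipy.optimize.minimize`)
with the exact analytic gradient (residual h·τ − d propagated through the
output layer and the logistic derivative z(1−z); verified against central
finite differences to < 1e-6 relative error). Defaults: gradient tolerance
1e-8 (infinity norm), 2000 iterations, initialization U(−0.5, 0.5).
Failure to meet the tolerance is recorded in diagnostics as a warning, not an
error — scipy's BFGS frequently reports "precision loss" after reaching the
optimum. A guard clips the output-layer linear predictor at ±50 before
exponentiation; a test checks it never binds at moderate coefficients.

Because the objective is non-convex, an **ensemble** of `n_starts` (default
10) independently initialized fits is kept and prediction averages the member
hazard functions on the hazard scale — never the coefficients, which are not
identified across restarts (hidden units permute). All members enter the
average; no selection or trimming, since discarding fits would change the
estimator that the bootstrap resamples.

## Hyperparameter selection

H (hidden units) and λ (decay) are chosen jointly by subject-level tenfold
cross-validation over the default grid H ∈ {3, 6, 9} × λ ∈ {0.001, 0.005,
0.02, 0.1}. The criterion is the negative mean held-out log-likelihood per
person-period row; smaller is better, and overfitted cells blow up by orders
of magnitude because held-out hazards collapse where the training folds had
no events. λ values outside the advised explorative range 10⁻³–10⁻¹ trigger
a warning. Ties break toward fewer hidden units, then stronger decay.
Per-fold ensembles reuse the configured restart count; whether restarts are
per fold or total is genuinely ambiguous in the underlying procedure, so it
is a configuration knob (default: restarts per fold).

## Inference

Pointwise confidence bands come from a nonparametric bootstrap (default
B = 2000; the test suite and examples use smaller B): subjects are resampled
with replacement *before* person-period expansion, each base-ensemble member
is refitted on the resample warm-started from its final coefficients, and the
replicate statistic is the ensemble-averaged curve. Intervals are
bias-corrected (BC) percentiles: z₀ = Φ⁻¹(fraction of replicates below the
point estimate), bounds at the empirical quantiles Φ(2z₀ + z_{α/2}),
Φ(2z₀ + z_{1−α/2}). BC rather than BCa: the acceleration constant would
require jackknife machinery that the procedure being implemented does not
use. Empirical quantiles are nearest-rank (type 1) for bit-reproducibility.
The below-estimate fraction is clamped to [1/(B+1), B/(B+1)] so z₀ stays
finite when all replicates fall on one side.

## Standardized curves and rule extraction

An *adjusted* hazard curve imposes a treatment level on every subject of a
subgroup, keeps their other covariates as observed, and averages the ensemble
hazard over subjects — direct standardization to the subgroup's empirical
covariate distribution, so treated and control curves are comparable and
their log ratio is an adjusted log hazard ratio. (Averaging only
observed-arm subjects is available via `treatment_level=None`.) Cumulative
incidence by a horizon is 1 − exp(−Λ) with Λ integrated piecewise-constantly
at interval midpoints, the same discretization the likelihood uses.

The rule tree is a minimal CART regression tree on per-subject predicted
six-year cumulative incidence: greedy binary splits on categorical level
subsets (or continuous thresholds), maximal SSE reduction, stopping when a
child would fall below `min_node_size` (default 10) or the reduction falls
below `min_improvement` (default 1%) of the root SSE. No cost-complexity
pruning: the tree is an exploratory summary. Log cumulative hazard can be
used as an alternative response.

## Synthetic cohorts

The simulator generates trial-like cohorts with categorical prognostic
factors (two-arm treatment, two grade categories, three T-stage and three
nodal categories, drawn independently), a baseline hazard (constant, Weibull,
piecewise constant, or additive mixture for multi-peak shapes), multiplicative
covariate effects, interactions, and optional sign-switching time-dependent
treatment effects with a change point. Event times are drawn by inverting the
subject-specific cumulative hazard — exactly, segment-by-segment, with
closed-form baseline inverses where they exist and bisection (1e-9 months)
otherwise. Censoring is independent uniform(0, c_max) plus administrative
truncation at the horizon.

Default scenario catalogue (`null`, `proportional`, `interaction`,
`changepoint`): Weibull baseline with shape 0.8 and scale 170 months (gently
decreasing; roughly 40% event probability by 72 months for a reference
subject), censoring c_max = 144 months (median follow-up around five years),
prognostic log-HRs of 0.4 (high grade), 0.2/0.5 (T stage), 0.4/0.8 (nodal
categories), treatment log-HR −0.3 (proportional), ±(0.4/−0.8) by nodal group
(qualitative interaction), or +0.5 switching to −0.5 at 24 months
(changepoint). These emulate a long-follow-up adjuvant trial in structure
only: covariates are drawn independently (no confounding), censoring is
independent of covariates, and there is no measurement error or missingness —
so passing recovery tests demonstrates correctness of the estimator chain
under the model's own assumptions, not robustness to real-data violations.

## Problem sizes and numerical choices in the test suite

Statistical end-to-end checks run at deliberately chosen reduced scales:
constant-hazard recovery at n = 500 with 10 restarts; Weibull shape recovery
at n = 500 vs 2000 (two seeds each); CV selection on null cohorts of n = 200
with 3 restarts per fold and a 300-iteration cap; bootstrap coverage with
n = 300, B = 200 over 50 Monte-Carlo repetitions with 2-member base
ensembles and 100-iteration warm refits. Warm-started replicate refits need
far fewer iterations than cold fits, which is what makes the bootstrap
affordable.

## Known limitations

* Constrained late-follow-up behavior: with little exposure near the
  horizon, the fitted log-hazard extrapolates its trend; pointwise bands
  widen accordingly, but point estimates at exposure-thin midpoints inherit
  the sampling noise of that trend (see the hazard-recovery tests, which
  quantify exactly this).
* A finite sigmoid expansion can leave a sub-percent non-monotone ripple
  when approximating steeply decreasing hazards.
* No left truncation, interval censoring, competing risks, or time-varying
  covariates; single hidden layer and logistic activations only.
* The CV criterion's absolute value is data-scale dependent; only
  comparisons across the grid are meaningful.
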