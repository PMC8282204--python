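# Methods

## The model

`growthmc` studies a three-level linear growth model: repeated measures
(level 1, occasions `t = 0 … T−1`) nested in individuals (level 2)
nested in groups (level 3).  One standard-normal covariate `x` acts at
the individual level and one (`z`) at the group level.  The combined
single-equation form of the generating and fitted model is

```
y_tij = (g000 + g001 z_j + u00_j) + (g010 + u01_j) x_ij + r0_ij
        + [ (g100 + g101 z_j + u10_j) + (g110 + u11_j) x_ij + r1_ij ] t
        + e_tij
```

with mean-zero normal random effects: residuals `e_tij ~ N(0, σ²_e)` at
level 1, individual intercept/slope deviations `(r0, r1)` with
variances `σ²_r0, σ²_r1` at level 2, and four group-level deviations
`(u00, u01, u10, u11)` with variances `σ²_u00 … σ²_u11` at level 3.
All covariances between random effects are zero in the default
generating and fitted model (options exist to free them).  Time is
coded `0, 1, 2, 3`, so the intercept is initial status at the first
occasion.

## Parameters, units and defaults

Fixed effects (outcome units): grand intercept `g000 = 0.5`; every
regression slope `0.3`, a medium standardized effect given unit-variance
covariates.

Variance components are anchored by intraclass correlations of the
*intercept pathway* — the proportions of the covariate-free intercept
variance `σ²_e + σ²_r0 + σ²_u00` at each level.  Two ICC sets are
studied: `(0.45, 0.50, 0.05)` and `(0.35, 0.50, 0.15)` for levels
1/2/3.  The absolute scale is pinned by setting the level-2 intercept
variance to 2.0, so the intercept-pathway total is 4.0 under both sets
and the components are `(1.8, 2.0, 0.2)` and `(1.4, 2.0, 0.6)`.  The
phrase "residual variance at the individual level" is ambiguous between
the level-1 and level-2 variance; the level-2 reading is the default
because it produces these exactly-round component sets under both ICC
sets, and the level-1 reading remains available
(`ICCSpec.anchor_level=1`, `StudyConfig.anchor_level=1`).

The slope-pathway variances are **not pinned down by the ICC
specification** and are free design parameters.  Defaults: `σ²_r1 =
0.5` (a quarter of the intercept variance — individual growth rates
vary, but less than levels), `σ²_u10 = σ²_r1 · icc3/icc2` (the
group-level share of slope variation mirrors the intercept-pathway
ratio: 0.05 / 0.15 for the two sets), and `σ²_u01 = σ²_u11 = 0.1` for
the group-level covariate-slope variances (half the low-ICC group
intercept variance).  Every one of these is overridable through
`StudyConfig.slope_variances`; conclusions about slope-pathway
quantities should be read as conditional on these choices.

Design grid: 2 ICC sets × {30, 50, 100} groups × group sizes drawn
uniformly from [5, 15] (nominal 10) or [15, 45] (nominal 30), T = 4
occasions, 500 replications per condition by default.

## Estimation

The marginal likelihood of a group's stacked outcomes is normal with
covariance

```
V_j = Z3_j G3 Z3_j' + blockdiag_i( Z2 G2 Z2' ) + σ²_e I
```

where `Z2 = [1, t]` (identical for every individual) and `Z3` has
columns `(1, x, t, x·t)`.  Fixed effects are concentrated out by
generalized least squares, and the profiled log-likelihood is maximized
over the variance parameters by a BFGS quasi-Newton iteration with
central-difference gradients and a backtracking (Armijo) line search,
so accepted iterates never decrease the likelihood.  Convergence is two
consecutive accepted steps with relative log-likelihood change below
1e-6 (configurable), with a cap of 500 iterations.

Numerical design choices:

- **Unconstrained variance scale.**  Variances are optimized without a
  positivity transform, so negative estimates are reachable; this is
  deliberate, because the study's convergence accounting counts
  "no negative variance" and a log-scale optimizer could never produce
  the inadmissible outcomes being counted.  Points where the implied
  covariance loses positive definiteness are rejected by the line
  search (the likelihood evaluation reports them as infeasible), with a
  relative margin of 1e-6 on the critical eigenvalues because the
  log-likelihood and its numerical derivatives are meaningless in the
  last few ulps before the boundary.
- **Fast evaluation.**  Each likelihood evaluation uses the Woodbury
  identity and matrix determinant lemma over the rank-4 group-level
  update, with per-dataset sufficient statistics precomputed once; an
  evaluation costs a few small batched tensor contractions independent
  of the number of observations.  Agreement with a naive dense
  multivariate-normal oracle is tested to 1e-8 relative (observed
  ~1e-14).
- **Starting values.**  Per-individual OLS growth lines give the
  level-1 variance; within/between-group moments of the per-individual
  intercepts and slopes (noise-corrected, floored at 1e-4) seed the
  level-2/3 variances; group covariate-slope variances start at 0.05.
- **Standard errors.**  Fixed effects: GLS covariance at the optimum.
  Variance parameters: inverse of a central-difference observed
  information of the profiled log-likelihood (step 1e-3 relative,
  shrunk adaptively near feasibility boundaries).  Wald z-tests use the
  standard-normal reference — matching common ML software rather than a
  t/Satterthwaite correction, because small-sample SE behavior is part
  of what the study measures — and all 95% intervals are symmetric,
  `estimate ± 1.959964 · SE`, including variance parameters.
- **Convergence classification.**  A replication is *converged* when
  the optimizer succeeded, the observed information is invertible, and
  no variance estimate is negative; optimizer success with a negative
  variance is *inadmissible*; anything else is *failed*.  Only
  converged replications enter the bias/MSE/coverage/power summaries;
  the convergence rate is reported over all replications.

REML, sandwich standard errors, profile-likelihood intervals and
Bayesian estimation are out of scope.

## What the generator does and does not emulate

The generator reproduces the study's stated conditions exactly where
stated: normal residuals at all three levels, standard-normal
covariates, unbalanced group sizes drawn independently and uniformly
from the stated ranges, four complete occasions per individual.  It
does not emulate missing data, non-normal outcomes, time-varying
covariates, or covariate distributions other than N(0, 1) — so passing
tests certify the estimator and the Monte Carlo machinery under the
model's own assumptions, not robustness to their violation.

## Reproducibility

Every replication's seed is `base_seed + r` with per-condition base
seeds derived deterministically from one master seed (all seeds kept
below 2³¹).  Replications are independent, so results are invariant to
execution order and worker count, and any single replication can be
re-run bit-identically from the manifest.

## Known behavior and limitations

- **Convergence rates at 30 groups are far below those reported by
  constrained ML software for comparable designs.**
  With `σ²_u00 = 0.2` pinned by the low-ICC set, the ML sampling SD of
  its estimate at J = 30 groups is ≈ 0.14, so an *unconstrained*
  estimator produces a negative estimate in ~5–7% of replications from
  that parameter alone, and the small free slope variances add more
  (in total roughly 40% of replications at J = 30, nominal size 10,
  are inadmissible).  Near-100% convergence under the same stated
  conditions is only consistent with estimation constrained to
  nonnegative variances; this package deliberately keeps the
  unconstrained scale (see above) and reports the resulting rates
  honestly.
- **Converged-only summaries are truncated samples at small J.**
  Excluding inadmissible replications conditions on variance estimates
  being positive, which induces the positive small-sample bias in the
  level-3 variance and depresses power for the group-covariate effect
  at J = 30.  At J ≥ 50 the effect is negligible.
- **Group-level fixed-effect precision.**  The exact ML sampling
  variance of `g000`/`g001` at J = 30, nominal size 10, under the
  default conditions is ≈ 0.019–0.021 (verified against both the
  analytic GLS covariance and brute-force simulation), about 15–20%
  larger than some published MSE values for comparable designs; the
  package reports what the stated conditions actually imply.
- Degenerate near-singular likelihood spikes can occur for very small
  groups (2–4 individuals); the feasibility margin stops the optimizer
  there and such fits are classified failed via the information-matrix
  check.  Study-grid conditions (≥5 individuals per group) are
  unaffected.

## Problem sizes used in the shipped checks

The test suite runs reduced replication counts (200–400 per condition,
with tolerances widened to ~3 binomial SEs at those counts) and the
acceptance script runs 500 replications for the 30- and 50-group
conditions and 300 for the 100-group conditions — enough that every
reported proportion has Monte Carlo SE below ~0.03.
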