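# Methods

## Overview

`cogreserve` couples two models of the same scientific question — why some
people's cognition is better than their brain scans suggest — at two levels
of abstraction:

1. a **lifespan trajectory simulator** that makes the distinction between
   *reserve* (stable between-person offsets), *maintenance* (between-person
   differences in rate of decline) and *cognitive reserve* (the residual of
   cognition given one measured brain property) concrete and testable;
2. a **stacked multimodal prediction pipeline** that asks how much variance
   in a fluid-intelligence-like score is explained by successive feature
   blocks (confounds, grey-matter volume, white-matter integrity, functional
   connectivity), against a noise ceiling set by the score's test-retest
   reliability — validated end to end by parameter recovery on a synthetic
   generator with known variance structure.

## Trajectory model

Each individual *i* and brain property *p* follows

    y_ip(a) = I_ip + S_ip * (a - a0) + Q_p * (a - a0)^2

with `a0` the youngest age of the grid (default 18; grid 18–88 in 1-year
steps) and `Q_p = 0` by default.  `(I, S)` across properties is multivariate
normal: slopes correlate across properties (default off-diagonal 0.5, the
cross-modal coupling of rates of decline one would expect from processes
such as Wallerian degeneration), intercepts are independent across
properties, and each property's intercept–slope correlation is a scalar
(default 0).  Correlation is induced through an eigen square-root of the
correlation matrix, so degenerate cases (zero SDs, correlation exactly 1)
are exact rather than failing a Cholesky factorisation.

Defaults are illustrative, in arbitrary units: intercept mean 100, SD 5;
slope mean −0.5/yr, SD 0.15/yr.  With these, at age 88 the residual of
cognition (the equal-weight average of two properties) regressed on
property 1 correlates ≈ 0.91 with property 2 in closed form — the
qualitative point (the residual *is* the unmeasured property's
contribution) is insensitive to these choices.

The two named scenarios are parameter limits: `slope_sd = 0` gives pure
reserve (all trajectories parallel; differences constant over the lifespan),
`intercept_sd = 0` gives pure maintenance (all trajectories intersect at
`a0`; differences emerge with age).  A configurable screening cut-off
(default: 1 population SD below the mean at `a0`) is used only to report
crossing ages.

## Synthetic multimodal generator

The generator emulates the *structure* of a large cross-sectional adult
cohort (N = 586, ages 18–88 uniform), not any real data: one standardized
target score and four feature blocks — `con` (2 confound features: a binary
sex-like variable and a continuous polygenic-like score), `GMV` (98
region-of-interest volumes), `WMI` (48 tract-integrity features) and `rFC`
(153 connectivity features, the number of unordered pairs of 17 networks,
n(n+1)/2).

All latents are standard normal.  The target is

    y = sqrt(s_con) L_con + sqrt(c2) L_shared + Σ_b sqrt(s_b) L_b
        + sqrt(r - s) L_stable + sqrt(1 - r) ε

where `s = c2 + Σ s_b` is the total explainable share, `r` the configured
test reliability, `L_stable` a stable but unmeasured person-level component
and `ε` measurement noise redrawn on retest.  Two realisations of `y` from
the same latents therefore correlate at exactly `r`, so the noise ceiling is
true by construction, and the model requires `s ≤ r` (validated).  Brain
block features are sparse ±1 loadings (default: half the features) on the
block's unique latent and on a shared latent that is partly age-driven
(`L_shared = 0.6 z(age) + 0.8 ξ`), plus i.i.d. feature noise (default SD
0.5, i.e. per-feature signal-to-noise of roughly 2–4:1 in variance).  The
confound features are observed noiselessly and combine into `L_con`
directly — confounds act on the target without passing through brain
latents.

`oracle_r2(subset)` is the closed-form explainable variance of a block
subset: the sum of its unique shares, plus `c2` once the subset touches any
brain block.  It is the reference for parameter recovery.

**Default shares.** con 0.11, GMV 0.31, WMI 0.06, rFC 0.04, shared target
share `c2 = 0`, reliability 0.56 — so the cumulative staircase over the
default order is 11% / 42% / 48% / 52% against a 56% ceiling, an
illustrative shape of diminishing multimodal increments; it is not a claim
about any cohort.

**Why the shared latent carries no target share by default.**  If a latent
common to k stacked brain blocks carries target share `c²`, every
block-optimal first-level prediction contains that component, and the best
*linear* stack of those predictions undershoots the oracle by exactly

    c² (k − 1)² / (1 + c² T),   T = Σ_b 1 / s_b

(minimising the stack's residual over weights).  For staircase-like shares
this deficit is ~0.07 — a property of the stacking architecture, not an
implementation artefact.  The default therefore keeps cross-modal
correlation in the *features* (the age-driven shared latent still loads on
every brain block, so modalities are correlated and age-patterned) while
routing all target variance through block-unique latents.  Nonzero
`shared_share` is fully supported and tested; users comparing stacked R² to
`oracle_r2` under a shared target component should expect the deficit above.

## Prediction pipeline

Per block, a linear model with a combined L1 + L2 penalty

    (1/2n) ||y − Xβ||² + λ (α ||β||₁ + (1 − α)/2 ||β||²)

is fit in nested cross-validation: 10 outer folds produce out-of-fold
predictions; 5 inner folds select `(α, λ)` from a grid of mixing weights
{0.01, 0.25, 0.5, 0.75, 1} × 20 log-spaced strengths in [1e-2, 10]
(strengths below 1e-2 on standardized features are never competitive here
and only slow coordinate descent on near-collinear designs).  Ties in inner
validation error break toward the stronger total penalty.  Feature means/SDs
and the target mean are estimated on training subjects only, at every level
(inner folds included); binary columns are centred but not scaled.  Mixed
penalties use scikit-learn coordinate descent (path tolerance 1e-4 inside
the inner CV, 1e-8 for the final per-fold refit); pure-L2 candidates are
solved exactly by penalized normal equations.

Stacking is nonnegative least squares with a free intercept on the blocks'
out-of-fold predictions, itself cross-fitted over the outer folds, so the
stacked prediction of a subject never involves that subject in any fitting
step.  Nonnegativity stabilises weights across strongly correlated modality
predictions; with one block it reduces to affine recalibration.

The whole procedure is repeated (default 20 times) with re-randomized outer
fold assignments; the across-repeat spread gives the error bars of the
staircase.  These repeats share the one dataset, so they quantify
fold-assignment variability only — the paired one-sided Wilcoxon
signed-rank p-value attached to each increment (exact null for ≤ 25
repeats) is accordingly labelled descriptive, and no multiple-testing
correction is applied across increments.  All randomness flows from
explicit `(seed, repeat)` pairs; identical inputs give bit-identical
outputs.

The noise ceiling is `100 × r` by default (the proportion of observed-score
variance that is true-score variance equals the reliability); `r²` is
available as a config option for users who prefer the
correlation-with-true-score-squared convention.

The residual cognitive-reserve score is `y` minus the OLS-recalibrated
out-of-fold prediction of the clinical block (grey-matter by default):
positive values mean better cognition than the clinical measure predicts.
On synthetic data this score correlates positively with the other blocks'
unique latents, closing the loop with the trajectory simulation.

## Problem sizes and numerical choices

- Full-scale validation (n = 586, blocks 2/98/48/153, 20 repeats, 10 outer
  × 5 inner folds) takes on the order of 8 minutes on one CPU; unit tests
  use smaller instances (n = 60–1000, reduced grids).
- A single cohort realisation at n = 586 moves the sample explainable
  variance of a prefix by ±0.03 (1 SD) around the closed-form value; the
  recovery tolerance of ±0.05 absorbs this plus first-level estimation
  error.  Averaging over fold-assignment repeats does *not* average this
  away — it is a property of the realisation, not of the CV.
- Degenerate inputs are rejected with diagnostics rather than propagated:
  non-PSD correlation matrices, constant targets or predictors, shares
  exceeding 1 or the reliability, fewer subjects than folds, mismatched
  fold assignments at stacking (a leakage guard), subject-id mismatches
  between CSV blocks.
- Identical increment vectors give a Wilcoxon p of exactly 1 (no evidence
  of improvement) instead of an undefined test on all-zero differences.

## Limitations

- The generator's features are linear in Gaussian latents with homoscedastic
  noise; real imaging-derived features have site/motion structure, outliers
  and non-linear age effects.  Passing recovery here shows the pipeline's
  accounting is correct, not that real-data R² values are attainable.
- Cross-sectional only: the trajectory simulator shows why longitudinal
  slopes are needed to separate reserve from maintenance, but the prediction
  pipeline itself never sees age or change scores.
- The stacking deficit under a target-level shared component (derived above)
  means cumulative stacked R² is a conservative estimate of jointly
  explainable variance whenever modalities share predictive signal.
- Multiplicative interactions between brain properties are deliberately not
  modelled (a config hook exists in the roadmap, not in the code).
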