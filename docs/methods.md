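# Methods

`kinconn` implements a multivariate brain–behavior association pipeline for
case-control connectome studies with robotic (Kinarm) cognitive
phenotyping, together with the univariate statistics layer such studies
report and a synthetic cohort generator with planted ground truth.  This
note documents the models, the numerical choices, and what the synthetic
experiments do and do not establish.

## Data model

Each subject contributes a symmetric `N x N` connectivity matrix (default
`N = 116`: 100 cortical parcels labelled with the seven Yeo resting-state
networks plus 16 subcortical structures) in one of two modalities:
structural connectivity (SC; nonnegative streamline-type weights, zero
diagonal) or functional connectivity (FC; correlations in `[-1, 1]`, unit
diagonal).  The strict upper triangle is flattened row-major into
`N(N-1)/2` edge features (6670 for 116 nodes).  Behavior is a vector of
nine task scores (VGR, RVGR, OH, OHA, TMA, TMB, PAL, BOB, APM): each task's
Z-Task Score is the root-mean-square of its parameter z-scores against a
normative model, and the one-sided Task Score maps the two-sided tail onto
the positive half-normal (|z| under a standard-normal Z-Task; the device's
internal transform is proprietary, so only the stated convention — 0 best,
monotone worse — is implemented).

## Pipeline stages

1. **Residualization.** Every edge feature is replaced by the residual of
   its OLS fit on `[1, age, sex, education]`, fit jointly over controls and
   patients.  Group is deliberately not a covariate (group differences are
   the signal).  Behavior scores are not residualized.  Residual columns
   are orthogonal to each covariate to machine precision, and the
   operation is idempotent.
2. **Standardization + PCA.** Columns are z-scored (`ddof = 1`), so PCA of
   the feature matrix is PCA of the sample correlation matrix; eigenpairs
   come from the thin SVD of the `n x p` matrix (the only tractable route
   when `p >> n`).  Loadings are sign-fixed (largest-magnitude entry
   positive) for determinism.
3. **Retention.** Components with eigenvalue >= 1 are retained
   (Guttman–Kaiser), floored at one component with a warning.  Stability
   is assessed by refitting on random subject subsamples (default 90%,
   5000 resamples at production scale; 200 in tests) and taking the modal
   Kaiser count, reported with the agreement fraction and the mean
   principal-angle cosine between subsample and full-sample subspaces.
   The modal count is the operational reading of "consistently
   identified"; the aggregation rule is a package choice.
4. **Sparse CCA.** See below.
5. **Interpretation.** Modes are read through loadings: Pearson
   correlations of each canonical variate with the original variables —
   task scores for the behavior side, residualized (pre-PCA) edge values
   for the brain side.  Top-K edges per sign (K = 15 by default) are
   reported with network/hemisphere annotation and an intra/inter-
   hemispheric flag; a Jaccard/containment table documents selection
   consistency across K.  A moderation regression of the brain variate on
   `[1, behavior variate, education, duration]` (complete cases) checks
   that the coupling survives covariate adjustment.

## The sparse CCA estimator

With standardized views `X (n x k)` and `Y (n x q)` and sample covariances
`Sxx, Syy, Sxy`, the leading mode solves, by alternating updates,

    u <- sparsify[(Sxx + ridge I)^-1 Sxy v]
    v <- sparsify[(Syy + ridge I)^-1 Syx u]

where `sparsify` soft-thresholds to an L1 bound and renormalizes to unit
Euclidean norm.  Each update is a ridge-regularized regression of one
view's variate on the other's variables with an elastic-net (L1 + L2)
penalty.  Properties that follow:

* **Unpenalized limit.** With the L1 bound inactive and `ridge -> 0` the
  iteration is power iteration on the classical CCA operator
  `Sxx^-1 Sxy Syy^-1 Syx`, so the solution coincides with the
  generalized-eigenvalue solution (verified against that oracle to 1e-6).
* **Penalty parameterization.** A grid value `c` in `[0, 1]` per view maps
  to the L1 bound `1 + c (sqrt(d) - 1)` on a unit-norm `d`-vector: `c = 0`
  forces a one-hot weight vector, `c = 1` is unpenalized.  The threshold
  achieving a given bound is found by binary search (48 halvings).
* **Determinism.** Initialization is the leading singular pair of `Sxy`;
  there is no internal randomness.  Convergence is declared when both
  sign-aligned weight changes fall below 1e-6 (at most 500 iterations;
  non-convergence sets a flag rather than raising).  Inside
  cross-validated tuning, fits use a looser stop (1e-5, 60 iterations)
  with warm starts carried across adjacent grid cells; selection is
  insensitive to this and the cost of re-tuning inside every permutation
  is what makes exact re-tuned permutation inference affordable.
* **Ridge.** Fixed at 1e-3 by default.  Besides making the within-view
  solves well-posed at `k` close to `n`, it is the L2 half of the elastic
  net; sparsity is carried by the L1 bound.

**Tuning.** Both penalties are selected by 3-fold cross-validated grid
search over the 11 x 11 grid `{0.0, 0.1, ..., 1.0}^2`: the objective is
the mean held-out canonical correlation (train-fitted weights applied to
test subjects standardized with training statistics), with ties broken
toward sparser pairs.  Fold assignment is a deterministic function of the
seed.

**Permutation inference.** Behavior rows are shuffled and the entire
procedure — including the grid search, when re-tuning is enabled (the
default) — is re-run per shuffle, with the fold assignment held fixed so
observed and null statistics are the same functional of exchangeable
data.  A mode is significant when its correlation exceeds the 95th
percentile of the null; the reported p-value is the add-one estimator
`(1 + #{null >= observed}) / (1 + permutations)`.  Production default is
5000 permutations; tests and the acceptance study use 199, which resolves
`alpha = 0.05` exactly (rejection probability 9/200 = 0.045 under the
null).

**Sequential modes.** After a significant mode, its two variates are
projected out of every column of their respective views and the next mode
is the leading mode of the residual views; the next permutation null
shuffles the rows of the residual behavior view.  An alternative —
Hotelling deflation of the cross-covariance while permuting the original
data — was implemented first and measured to be anti-conservative for
later modes (a spurious third mode at p = 0.01 on pure-noise residuals of
a two-factor instance): the observed statistic is the maximum over
residual noise while the null is a lower order statistic of shuffled
noise.  Variate projection restores per-step exchangeability up to the
estimation of the projection itself.  Penalties are re-tuned per
deflation step on the observed residual.  Extraction stops at the first
non-significant mode, which is still returned with its p-value.

**Generalizability.** Repeated cross-validation: per repeat a fresh
3-fold split; per fold, inner tuning on the training two-thirds, fit, and
canonical correlation on the held-out third.  All `3 x repeats` held-out
correlations are returned (median and IQR summarized); production default
1000 repeats, tests use 50.

## Synthetic cohort generator

The generator emulates the study the pipeline targets (its clinical data
are confidential): 24 controls / 33 patients by default, 116-node
matrices, nine tasks.

* **Planted mode.** Per-view latents `u_x = sqrt(r) s + sqrt(1-r) g_x`
  (likewise `u_y`) share a factor `s`, so `corr(u_x, u_y) = r`.  Active
  edges are `w_j u_x + sigma eps`, tasks are `b_k u_y + sigma eps`, with
  unit-norm loadings `w, b` drawn once per seed.  The best linear readout
  of a view attenuates its latent by `1 / sqrt(1 + sigma^2)`, so the
  generator sets `r = min(1, canonical_rho (1 + sigma^2))`, making the
  population canonical correlation of the observed blocks equal
  `canonical_rho` exactly (up to the cap and the near-linear modality
  squashing).  Stored "true weights" are the population-optimal directions
  on the standardized observables (`b_k sd_k`, normalized).
* **Background structure.** All edges additionally load on a small number
  of shared background factors (default 5, per-edge strength 0.7).  Real
  connectome edges are strongly inter-correlated; without this the edge
  correlation matrix is near-identity and the Kaiser rule retains the
  entire Marchenko–Pastur bulk, which both misrepresents real data and
  removes the power of every downstream stage.
* **Covariates and group.** Age/sex/education distributions bracket the
  study's demographics (patients older, less educated); epilepsy duration
  is log-normal with mean 9.58 and SD 11.04 years, controls missing.
  Covariates leak linearly into edges with strength `covariate_effect`.
  Patients receive additive per-task shifts, by default derived from the
  published case-control effect sizes via
  `delta = sqrt(2) Phi^-1((1+r)/2)` (in task-SD units).
* **Modality squashing.** SC: `25 softplus(3 + z)` (nonnegative,
  streamline-like magnitudes); FC: `tanh(base + 0.35 z)` with a per-edge
  baseline.  Both are near-linear over the latent's range so the planted
  correlation structure survives.
* **Null degradation.** `degrade_to_null` permutes behavior rows as whole
  units against the rest of the cohort, preserving all behavior marginals
  while breaking every brain-behavior link.

**What the synthetic experiments do not show.**  The generator is linear
with Gaussian noise after monotone squashing; real connectivity has
heavy-tailed weights, motion artifacts, and site effects, and real task
scores are bounded and skewed.  Passing tests demonstrate that the
pipeline recovers the structure it models and that its inference is
calibrated under its own null — not that the clinical effect sizes or the
published canonical correlations are reproduced (the study data are
confidential by design).

## Known limitations and regime notes

* **Retention at `p >> n`.**  The correlation-matrix trace equals the edge
  count and is spread over at most `n - 1` nonzero eigenvalues, so with
  6670 edges and ~57 subjects the eigenvalue >= 1 rule keeps essentially
  every component regardless of structure, and the multivariate stage
  loses power (tuned in-sample correlations saturate for observed and
  permuted data alike).  The analysis drivers therefore run the sCCA
  stage in the `p < n` regime (reduced parcellation), where retention is
  informative; a handful-of-components outcome at `p >> n` implies a
  different eigenvalue scale (covariance-scale PCA of unstandardized
  features), which is units-dependent and not implemented.
* **Sequential p-values** are exact only up to the estimated projection
  used for deflation.
* **Problem sizes.**  Tests and the acceptance study use 199 permutations,
  200 stability resamples, 50 CV repeats, 8–16-node parcellations and
  cohorts of 57–200 subjects; production defaults (5000 permutations, 5000
  resamples, 1000 repeats) are the package's configured scale for real
  analyses.
* **Statistics layer choices.**  Mann-Whitney U uses exact enumeration for
  `n1 + n2 <= 12` without ties, otherwise the tie-corrected normal
  approximation with continuity correction; the normality gate is
  Shapiro-Wilk at alpha 0.05 per group (the threshold is a package
  choice); the chi-square uses the Yates continuity correction with
  per-cell clipping at zero, the variant that reproduces the published
  demographic statistics; the rank-biserial effect size is
  `r = 1 - 2U/(n1 n2)`, which reproduces every published per-task value
  at two decimals.
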