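# Methods

## Model class and estimation

`traitsem` fits recursive (acyclic) linear structural equation models with
optional latent variables measured by ≥ 2 observed indicators.  A model is a
set of directed paths, latent definitions and free residual covariances;
every variable carries one free variance (exogenous variance or disturbance
variance) and each latent's first indicator has its loading fixed to 1 to
set the latent's scale.  In reticular (RAM) form the implied covariance of
the observed vector is `Σ(θ) = F (I−A)⁻¹ S (I−A)⁻ᵀ Fᵀ`.

Estimation minimises the Gaussian ML discrepancy
`F = ln|Σ| − ln|S| + tr(SΣ⁻¹) − p` over the free parameters.  Choices that
matter:

- **Input moments.** Fits consume a moment matrix plus its sample size; a
  correlation matrix is treated as the covariance matrix of standardized
  data.  This is the only route available when a study prints correlations
  rather than raw data.  Caveat: standard errors computed from a
  fixed-correlation input are approximate (the rescaling by sample standard
  deviations is ignored); standardized point estimates are unaffected.
- **Optimisation.** Variance parameters are log-transformed (bounded below
  at 1e-6 on the original scale; hitting the bound is flagged as a Heywood
  case).  The gradient of `F` is analytic via the RAM derivative identities;
  minimisation is L-BFGS-B followed by an unbounded BFGS polish, from start
  values paths 0, loadings 1, variances 0.5, with 5 seeded restarts
  (perturbation SD 0.1) keeping the best objective.  Convergence requires a
  projected gradient ∞-norm < 1e-6.
- **Test statistic and indices.** χ² = (n−1)·F_min (the classical
  covariance-structure convention); p from the χ²_df upper tail with
  df = p(p+1)/2 − t.  RMSEA = √(max(χ²−df,0)/(df(n−1))), GFI/AGFI from the
  weighted-residual form, CFI against the closed-form independence baseline
  (F_b = −ln|R| for a correlation matrix), AIC = χ² + 2t.  With df = 0,
  RMSEA and AGFI are reported as undefined.
- **Standardization.** All variables (latents included) are rescaled to
  unit implied variance; each latent's sign is normalised so its first
  (anchor) indicator loads positively — for the study models both latents
  therefore align with specific leaf area.  R² of an endogenous variable is
  1 minus its standardized disturbance variance.
- **Standard errors.** Parameter covariance = (2/(n−1))·H⁻¹ with H the
  central-difference Hessian of F at the optimum (relative step 1e-5); z and
  two-sided normal p per parameter.  A singular Hessian leaves SEs
  unavailable rather than failing the fit.

## Effects and variance partitioning

On the standardized system, total effects are `(I−A*)⁻¹ − I`; direct effects
are `A*` and indirect effects the difference, so the decomposition
`total = direct + indirect` is an identity, cross-checked in the tests by
explicit enumeration of simple directed chains.  Significance is attached to
direct paths only; no delta-method or bootstrap distribution is computed for
composite effects.

Variance partitioning expresses each variable as a linear combination of
independent shocks, `x = (I−A*)⁻¹ u`, `cov(u) = S*`, and assigns to each
named shock group the quadratic form of the target's row over the group's
block of `S*`.  Cross-group shock covariances must vanish (the partition is
otherwise not additive and the call fails loudly); within-group covariances
— here the residual covariance of soil K and soil P, pooled into one
"TSK and TSP" group — stay inside the group's share.  Shares plus the
target's own disturbance sum to exactly 100%, and the shares alone to
100·R².  This exact orthogonal-shock decomposition is adopted as the
package's definition of "variance explained by predictor groups"; it
reproduces all published partition cells for this model class from the
published effect sizes.

## Model search

Backward elimination from a full prior model: at each step every droppable
structural path and free covariance (never loadings) is refit, and the drop
with the lowest AIC is accepted if it improves the current AIC, ties broken
lexicographically so the search is deterministic.  After a drop, observed
structural variables left with no outgoing paths (and that are neither the
outcome nor an indicator) are marginalised out — their equations constrain
nothing relevant to the outcome, and removing them shrinks the moment
matrix; because that changes the observed set, the AIC sequence restarts
there and is logged as non-comparable.  Non-convergent candidate fits are
skipped with a warning.  Indicator sets of latents are not searched: the two
study models' indicator pairs are fixtures.  Notably, a single factor over
all three leaf-morphology traits is infeasible for the study correlations
(the triad 0.35, −0.37, 0.69 forces a negative squared loading), which is
consistent with the published models keeping different two-indicator pairs.

## Synthetic data

Three generators make every stage testable without field data:

- `simulate_model` draws independent Gaussian shocks (with any free residual
  covariances), propagates them through (I−A)⁻¹ and discards latent columns.
  True values are given in the standardized metric; unspecified disturbance
  variances are filled so every variable has unit variance, and unspecified
  loadings default to 0.7.  Optional rescaling to the study's published
  per-variable mean and SD (SD reconstructed as mean·CV/100) is cosmetic —
  correlations are scale-free — and off by default.
- `exact_moment_sample` whitens a centred Gaussian draw with its own sample
  Cholesky factor and recolours with the target's, so the *in-sample*
  correlation matrix equals the target to ~1e-10.  Since the moments are
  sufficient for ML, fitting such a table is identical to fitting the matrix.
- `study_correlations` / `study_trait_summary` return the packaged study
  fixtures exactly as published.  The correlation matrix is positive
  definite as printed (smallest eigenvalue ≈ 0.0059), so no repair is
  needed; `nearest_psd` (iterated eigenvalue clipping with unit-diagonal
  rescaling, idempotent by construction) is available for rounded matrices
  that are not.  The published summary's leaf-dry-weight row is internally
  inconsistent (minimum = mean < maximum with CV 30%); it is stored verbatim
  and flagged, not repaired.

What the generators do *not* emulate: non-Gaussian trait distributions,
within-site dependence of trees sampled on the same mountain, measurement
error beyond the latent structure, and spatial autocorrelation.  Passing
recovery tests therefore validate the estimator under the model's own
assumptions, not the field-sampling process.

## Problem sizes used in the checks

The packaged study fits use the printed 10-variable matrix at n = 90.
Large-sample checks use n = 5000 (parameter recovery within ±0.03) and
n = 10⁶ (moment convergence with CLT-width tolerances); the SE calibration
uses 200 replicates at n = 500; the sampled search-recovery check uses 12
replicates at n = 90.  The independent estimation oracle is equation-wise
OLS with a from-scratch implied-covariance recursion, exact for recursive
observed-variable models with saturated exogenous blocks; latent-variable
correctness is covered by population-moment self-consistency (fitting a
model to its own implied covariance recovers the generating parameters).

## Known limitations

- Reproduction from printed two-decimal correlations is inherently
  approximate: path coefficients land within ~0.01 of the originally fitted
  values, but squared/derived quantities amplify the rounding — the refit
  gives R²(N_mass) ≈ 0.798 (published 82%), χ² ≈ 7.29 (published 5.788), and
  variance-partition shares within ~2 percentage points.  The area-based
  model reproduces more tightly (R² 0.830 vs 83%).
- Backward AIC search from the full prior retains a weak direct
  MAT→N_mass path (dropping it raises AIC by ~0.6) even though the published
  mass-based model excludes temperature entirely; with the area-based
  outcome the search does drop MAT and TSN, and additionally removes the
  direct soil-P path that the published model keeps — expected behaviour
  when the prior's three-indicator latent fits poorly (see above).  AIC
  pruning on sampled n = 90 data recovers a true topology in roughly half of
  replicates, as the χ²<2 acceptance probability per spurious path implies.
- Only ML estimation is provided (no robust/weighted least squares, no
  missing-data likelihood, no bootstrap); models must be recursive, single
  group, without mean structure.
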