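# Methods

## Model

`trajmoe` clusters N patients into K latent disease subtypes from two data
sources that play asymmetric roles:

- **Longitudinal clinical scores** (the outcomes). For patient i, visit j and
  clinical variable v, the observed score is modelled per subtype as a
  polynomial trajectory in visit time with Gaussian noise:

  y_iv(j) | z_i = k  ~  N( Σ_{p=0..P} α_vkp t_ij^p ,  σ_vk² ).

  Conditional on the subtype, cells are independent across visits, variables
  and patients: the subtype's typical trajectory is assumed to absorb the
  within-patient correlation, and the clinical variables are chosen to be as
  close to independent as the application allows.

- **Genetic markers** (the concomitants). An additively coded marker vector
  g_i ∈ {−1, 0, 1}^L enters only the prior over subtypes, through a
  multinomial logistic gate with the first class as reference:

  P(z_i = k | g_i) = exp(ω_k0 + ω_k′ g_i) / Σ_k′ exp(ω_k′0 + ω_k′′ g_i),
  with ω_10 = 0 and ω_1 ≡ 0.

Because L ≫ N in genetic applications, the gate coefficients carry an ℓ1
penalty: the markers the Lasso keeps are the method's genetic association
output.

## Inference

The penalized complete-data log-likelihood

  Σ_i Σ_k z_ik [ log η_k(g_i; ω) + Σ_v Σ_j log f_k(y_iv(j)) ] − N λ Σ_k ‖ω_k‖₁

is maximized by EM. The E step computes responsibilities τ_ik ∝ η_k · Π f_k
in log space; the default engine is the CEM variant, which replaces τ by its
row-wise argmax (ties to the lowest class) before the M step — faster and
with a natural partition-fixed-point stopping rule. The M step splits:

- (α, σ): per (variable, class) weighted least squares with the patient's
  τ_ik repeated over its visit cells, and the weighted maximum-likelihood
  variance (no degrees-of-freedom correction), floored at σ_min = 1e−4.
- ω: an ℓ1-penalized multinomial logistic regression maximizing
  (1/N) Σ_ik τ_ik log η_k − λ Σ_k ‖ω_k‖₁, intercepts unpenalized, reference
  class pinned. λ is re-selected **inside every M step** by 5-fold
  cross-validation maximizing the held-out weighted multinomial
  log-likelihood (patients are the CV unit; folds stratified by the τ-argmax
  and reseeded deterministically from the master seed and iteration index).
  The CV-optimal λ is used — no one-standard-error rule.

After convergence the selected coefficients are re-estimated without penalty
(constrained Newton on exactly the selected (class, marker) pairs plus all
intercepts) to remove shrinkage bias; 95% Wald intervals come from the
inverse observed information. If the restricted problem is (quasi-)separable
— detected by non-convergence or coefficients beyond ±15 on the genotype
scale — a ridge-stabilized fit is returned and flagged as non-Wald.

Multi-start: `n_init` (default 10) uniform random hard partitions; each is
run to convergence and scored by BIC computed after the debiased refit; the
lowest-BIC initialization wins. A degenerate cluster (responsibility mass
below `weight_floor`) restarts that initialization with a fresh seed, up to
three times. K and P are chosen by the same BIC over a grid (defaults
K ∈ {1..4}, P ∈ {1, 2}), with ties to the smaller model.

**BIC.** −2·loglik + ν·log N with ν = K·V·(P+1) + K·V + (K−1) + #nonzero(ω):
after Lasso selection only the surviving gate coefficients count as free
parameters (the effective degrees of freedom of the Lasso equal the expected
support size). An "all L·(K−1)" variant is not exposed; the counting rule is
applied identically across grid cells so cells are comparable.

## Numerical choices

- **Time rescaling.** Visit times are divided by `time_scale` (default: the
  cohort's maximum |t|) before powers are taken; day-scale times up to 4,000
  would otherwise put t² ≈ 1.6e7 into the design and destroy conditioning.
  Reported α are on the rescaled axis; `ModelParameters.alpha_user_scale()`
  converts back.
- **Missing clinical cells** are complete-case per cell: a missing
  visit-variable value contributes nothing to any likelihood sum or update.
- **Penalty scale.** Markers are standardized to unit variance inside the
  solver so the penalty treats them symmetrically; coefficients are returned
  on the original scale. Consequently the engine's monitored objective uses
  the matching standardized-scale ℓ1 norm (Σ_j sd_j |ω_kj|) — with any other
  norm the M step and the monitored objective would optimize different
  functions and the monotonicity guarantee would be lost.
- **Monitored objective.** For soft EM: the penalized observed-data
  log-likelihood (provably non-decreasing at fixed λ). For CEM: the
  classified complete-data penalized log-likelihood (likewise). With λ
  re-selected by CV each M step, monotonicity across λ changes is not
  guaranteed and not asserted; in practice the final objective exceeds the
  initial one.
- **Path solver.** The penalized gate fit is a numba-compiled proximal-Newton
  coordinate descent (per-class IRLS quadratic approximation with weight
  floor 1e−6, residual-maintained coordinate sweeps, glmnet-style
  curvature-scaled convergence at 1e−7). Each λ on the path is warm-started
  from the previous one, screened by the sequential strong rule, and finished
  with a full KKT check, so the returned point is a verified stationary point
  of the convex objective; a per-class objective backtracking step guards
  against the quadratic approximation overshooting. λ = 0 (and the toy-scale
  oracle comparisons) use L-BFGS on the smooth likelihood instead.
- **λ grid.** Geometric, 30 points from λ_max down to 1e−3 λ_max, recomputed
  from the current τ at every M step. During CV, a fold's path stops early
  once the support exceeds max(100, N/2) markers: near-saturated fits are
  never CV-optimal and dominate run time; λ values unsolved in any fold are
  excluded from selection. Ties in the CV score go to the larger λ.
- **Convergence.** Relative change of the monitored objective below 1e−6, an
  unchanged CEM partition, or 200 iterations.
- **Determinism.** All randomness (initial partitions, CV folds, restarts)
  derives from the master seed; identical configuration + seed reproduce
  byte-identical artifacts.

## Synthetic data

The generator draws, per patient: an additive genotype vector (independent
Hardy–Weinberg markers, allele frequency ~ U(0.05, 0.5)); a subtype from the
gate at the true ω; visit times uniform within per-visit day windows; and
scores from the subtype's polynomial trajectory plus N(0, σ²) noise. The
benchmark scenario uses N = 396 patients, V = 4 scores, K = 3 subtypes,
P = 1, three visits in (10, 410), (1800, 2200) and (3600, 4000) days, and
L = 2657 markers of which 10 are active: ω₂{2,3,4} = ω₃{5,6,7} = 2,
ω₂{5,6,7} = −1, ω₃{1,8,9,10} = −2 (class 1 reference, 1-based markers). Gate
intercepts default to cancelling the mean linear score so expected class
sizes are near-balanced.

The trajectory parameters of the reference study are not published, so the
generator ships documented "moderate separation" defaults chosen once:
shared zero baselines (patients alike at entry), slopes fanning out so
adjacent subtype means at the last visit differ by about two of the middle
subtype's standard deviations per variable, alternating sign across
variables (some scores worsen upward, some decline downward), and noise
scales growing across subtypes (σ = 1.0, 1.5, 2.0 for every variable) since
subtype differences partly lie in the variances.

What the generator deliberately does **not** emulate: linkage
disequilibrium or any inter-marker correlation, population structure,
constant or near-constant markers, missing genotypes, and irregular or
missing visits. These differences matter when comparing against results
obtained on real genotypes: with independent, always-varying markers, the
Lasso's pooled selection sensitivity is substantially higher than on real
data where active markers can be nearly constant or shadowed by correlated
neighbours, and the clinical separation of the default scenario lets both
the integrative method and the trajectory-only 2-step baseline recover
nearly the true partition, shrinking the gap between them. Passing tests on
these data therefore validate the estimation machinery, not field
performance on real cohorts.

## Scaled-down study sizes

The original protocol repeats every simulation 100 times with 10 random
initializations per fit. The bundled studies keep the data-generating design
at full size (N = 396, L = 2657) but scale the outer loops so a full run
completes in minutes on one CPU; all sizes live in one place
(`scripts/acceptance.py`, the acceptance tests) and are the package's own
choices:

- selection benchmark: 8 replicates, 3 initializations per fit;
- parameter-recovery check: 10 replicates, 2 initializations;
- BIC model-selection study: 8 replicates over K ∈ {1..4} at P = 1 with
  L reduced to 500 (the 10 active markers preserved), 2 initializations.

## Known limitations

- Only Gaussian experts ship; the expert interface admits Poisson/logistic
  drop-ins but none are implemented.
- The gate assumes markers enter linearly and additively; no epistasis, LD
  blocks, or grouped penalties.
- BIC's nonzero-coefficient ν understates model complexity when λ is chosen
  adaptively; this is the standard effective-df approximation.
- CEM maximizes the classification likelihood, which is known to bias
  parameters for overlapping clusters; the soft-EM mode is available where
  that matters.
- Post-selection Wald intervals do not account for the selection event; they
  match the usual practice of refitting the selected model and reading the
  Hessian.
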