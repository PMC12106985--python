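# Methods

## Model

`fgmspatial` fits a Bayesian hierarchical logistic regression for the
binary cut/uncut status of girls aged 0–14 sampled through a two-stage
cluster survey design. The linear predictor combines

1. **Fixed effects** — reference-coded categorical covariates. The
   reference level is the first in the declared category order (no
   education, currently married, does-not-support-continuation, uncut
   mother, poorest quintile, Fulani, Christian) and contributes no
   column. Priors are N(0, 1000), effectively vague on the log-odds
   scale.
2. **Smooth terms** — girl age (unit bins, 0–14, 15 grid points),
   mother age (unit bins, 15–49, 35 points), and the community
   proportions of women cut and of women supporting continuation (20
   equal-width bins on [0, 1], indexed by `floor(20p)` clamped to the
   last bin). Each smooth carries a random-walk-order-2 prior on the
   grid values with one sum-to-zero constraint. RW2-on-bins is a
   deliberate, transparent stand-in for a latent-Gaussian smooth; the
   basis is not an attempt to reproduce any particular package's
   default spline construction.
3. **Structured state effect** — intrinsic CAR (Besag): improper
   Gaussian with precision τ_str·Q, Q = D − A the Laplacian of the
   state contiguity graph. One sum-to-zero constraint per connected
   component identifies the field. Q is used raw (no generalized-
   variance scaling; the hyperprior absorbs scale; `scale_icar` exists
   as a config flag but is intentionally inert). Contiguity is queen
   (shared boundary point) by default because state polygons often
   meet at corners; rook is available. Island states keep a zero row in
   Q and trigger a logged warning, since only the constraint (and the
   iid effect, if present) identifies them.
4. **Unstructured state effect** — iid N(0, 1/τ_unstr) per state;
   together with the Besag term this is the BYM decomposition.
5. **Weight covariate** — the normalised sampling weight enters the
   predictor linearly (a representativeness adjustment). Weights do
   *not* enter the likelihood; consequently "duplicate every record and
   halve the weights" is not a posterior-invariant operation in this
   model, and no such invariance is asserted anywhere.

Specifications m1/m2/m3 drop/add the spatial terms (none / structured /
structured + unstructured); the covariate set can be individual-level,
community-level or both.

All precisions (per smooth, τ_str, τ_unstr) have Gamma(1, 5·10⁻⁵)
priors — a common spatial-epidemiology default that is close to flat on
the standard-deviation scale over the plausible range — and are
configurable through `Priors`.

## Sampler

The Bernoulli-logit likelihood is augmented with Pólya-Gamma latents
ω_i ~ PG(1, η_i), making every sweep conditionally Gaussian:

1. ω_i ~ PG(1, η_i) drawn exactly with the Devroye alternating-series
   rejection algorithm (numba-compiled; the numba RNG is seeded once
   per `fit`, so runs are bit-reproducible given the seed).
2. All linear blocks are drawn **jointly** from
   N(Λ⁻¹Xᵀκ, Λ⁻¹), Λ = XᵀΩX + P(τ), κ = y − ½, via a dense Cholesky
   factorisation (the coefficient count is ~90–150). The intrinsic
   penalty blocks (RW2, ICAR) receive a 10⁻⁶ diagonal jitter so Λ is
   positive definite; the draw is then projected exactly onto the
   constraint subspace by conditioning-by-kriging
   (θ ← θ − Λ⁻¹Aᵀ(AΛ⁻¹Aᵀ)⁻¹Aθ), which removes the only directions the
   jitter touches materially.
3. Precisions are updated from conjugate Gamma full conditionals using
   the penalty rank (k − 2 for RW2 on k bins, n − c for the ICAR field
   with c components) and the corresponding quadratic form; the ICAR
   quadratic form is evaluated as the pairwise edge sum Σ(u_i − u_j)².

Defaults are 4000 iterations, 1000 burn-in, thin 1; validation runs use
shorter chains (noted below). Per-draw deviance
D(θ) = −2Σ log Bern(y_i | p_i) is stored with probabilities clipped to
[10⁻¹², 1 − 10⁻¹²]; DIC uses the Spiegelhalter plug-in effective size
pD = D̄ − D(θ̄) with θ̄ the posterior mean of every block. Model
selection takes the lowest DIC unless it is within 2 of a simpler
specification, in which case the simpler one wins, applied from the
simplest upward.

Posterior odds ratios are exp(posterior-mean coefficient) with interval
endpoints exp of the 2.5/97.5% coefficient quantiles; an effect is
flagged significant when both endpoints fall on the same side of 1.
State prevalence estimates are, per posterior draw, the weighted mean of
p_i over the state's records; summaries (mean, SD, quantiles) are taken
over draws, and the national figure aggregates all records the same way.

## Cross-validation

Five-fold, five-repeat by default. Folds are blocked by cluster (all
girls of a cluster stay together, respecting the survey design) and
stratified by sorting clusters on their outcome prevalence and dealing
them snake-wise; fold assignments are re-drawn (up to 10 attempts) if a
training fold lacks an outcome class. Held-out records are scored by the
posterior-mean probability; accuracy/precision/recall use a 0.5
threshold, AUC is threshold-free with midrank ties (a constant score
gives 0.5). Precision is TP / predicted-positives; a config switch
(`precision_over_all`) instead reports TP over all predictions, a
variant retained for comparability with looser phrasings of the metric.

## Synthetic survey generator

The generator emulates what the model needs from a DHS/MICS-style
survey: a lattice of states with queen contiguity (six contiguous zone
blocks), clusters nested in states, inverse-inclusion-probability
weights from a two-stage design (a notional pool of clusters per state
with log-normal population sizes, sd 0.3 by default; dispersion 0 gives
a self-weighting sample), spatially clustered ethnicity (one dominant
group per state, share 0.7), zone-dependent religion mixtures, and
outcomes drawn from the exact model predictor. Cut girls receive an age
at cutting no greater than their age, with 70% mass at ≤ 1 year by
default. Randomness is split hierarchically per (seed, stage, state,
cluster), so enlarging a design never perturbs earlier draws, and
identical seeds give byte-identical CSVs.

Default generating coefficients are the published posterior odds ratios
of the fitted survey analyses (e.g. mother-cut OR 8.145 pre / 10.992
post; support-continuation 16.436 → 26.728); odds ratios printed as
0.000 (truncated) are represented by 0.01. Because the synthetic
covariate mixture differs from the real population, the intercept alone
cannot simultaneously reproduce the published intercept and the
observed national prevalence; the generator therefore calibrates the
intercept so the design-weighted population prevalence matches the
observed national figures (19.2% pre, 14.1% post) while keeping all
odds ratios fixed. Mother-level covariates are drawn independently
within a cluster — real surveys exhibit correlations (education with
wealth, support with own FGM status) that the generator does not
emulate, so passing tests demonstrate correctness of the machinery
under the stated model, not robustness to real-data confounding.
Household rosters, nonresponse and weight calibration are out of scope.

## Validation scenarios and problem sizes

The validation suite (and `scripts/acceptance.py`) uses a 3×4 state
lattice with 5 clusters × 50 girls per state (n = 3000 per period):

* **Recovery** — replicated simulate→fit under the individual-covariate
  true model (smooths restricted to the two ages), m2 fits at 2000
  iterations; interval coverage is counted over replicate × coefficient
  cells and the large-effect bias over replicates.
* **DIC discrimination** — τ_str = 0.2 (a strong Besag field, chosen to
  mirror the tens-of-points between-state spread of the real surveys),
  m1 vs m2 at 800 iterations.
* **Agreement** — one n ≈ 5000 run under the same strong-field true
  model; state-level R²/RMSE/MAE against the observed weighted state
  prevalences. With a weak field this ceiling is unattainable for any
  estimator: the observed values are then dominated by binomial noise
  around a nearly flat truth, which bounds the attainable correlation.
* **CV sanity** — a two-group scenario (only the mother-FGM covariate
  carries signal) whose Bayes accuracy is available in closed form.
* **Conjugate oracle** — the intercept-only model against the
  Beta-posterior of a Bernoulli proportion.

## Numerical choices and edge cases

* Probabilities clipped to [10⁻¹², 1 − 10⁻¹²] before Bernoulli draws and
  log-likelihoods.
* Modal community categories break ties by the declared category order.
* Covariates with a single observed level, and unobserved non-reference
  levels, are dropped from the design with a warning; undeclared levels
  are an error naming the level.
* Records with an unknown state label are an error; states with no
  records are omitted from prevalence tables with a warning.
* Scoring new records reuses the frozen training encoding; levels never
  seen in training fall back to the reference column.

## Known limitations

* Coefficients of levels with (near-)zero event counts have
  prior-dominated, extremely skewed posteriors; the PG chain mixes
  slowly in that regime, so their POR intervals are approximate.
* Posterior-mean log-odds ratios inherit the finite-sample
  away-from-zero bias of logistic estimation at moderate event counts;
  at n = 3000 this is visible (~0.05–0.1 on the log scale) for large
  effects.
* The sampler targets the exact posterior but is validated against
  conjugate and maximum-likelihood oracles, not against any specific
  approximate-inference implementation.
* DIC is the only information criterion implemented (no WAIC/LOO), and
  the two periods are fitted independently (no spatio-temporal joint
  model).
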