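# Methods

## The question the simulation answers

Longitudinal studies often publish analyses of their first waves while data
collection continues. With two waves, individual change can only be expressed
as a difference score (here, the latent change score model); with three or
more, a latent curve model recovers each person's trajectory parameters. The
framework quantifies, by Monte-Carlo simulation, how reliably each design
recovers (a) the *fixed* (group-mean) rate of change and (b) *individual
differences* in change, as the number of measurement waves grows.

## Generating model

Each replicant i carries growth factors η_i (intercept and slope, plus
curvature in the quadratic condition) and produces observations

    y_ti = Λ_t η_i + ε_ti,     ε_ti ~ N(0, σ²_t),

with Λ the polynomial loading matrix over time codes 0, 1, …, T−1 (unit
spacing; time 0 anchors the intercept and, for quadratic trajectories, the
instantaneous slope at wave 1).

**Exact-moment sampling.** Growth factors are drawn Gaussian and then
demeaned, whitened by the inverse Cholesky factor of their own sample
covariance, recolored with chol(Ψ) and shifted by α. Every generated cohort
therefore has *sample* mean exactly α and *sample* covariance (divisor n−1)
exactly Ψ. This removes sampling variability in the generating parameters, so
differences between replications reflect measurement noise and estimation
only — a deliberate design feature, and the reason across-replication spreads
of fixed-effect estimates are driven purely by the noise. Only the factors
(and W, below) are moment-exact; the per-wave noise is drawn stochastically,
since it carries the variability the study measures.

**Built-in populations.**

- linear: α = (3, 0.2), Ψ = [[1, 0.15], [0.15, 0.25]] (intercept–slope
  correlation 0.3), five waves;
- quadratic ("adolescent-emergent": initial rise that levels off):
  α = (3, 3, −0.2), Ψ = [[1, 0.15, −0.022], [0.15, 0.5, −0.079],
  [−0.022, −0.079, 0.05]], six waves. The printed lower-triangle covariances
  are taken as authoritative; note they imply corr(intercept, slope) ≈ 0.21
  while the companion standardized matrix states 0.3 — an inconsistency in
  the source that we do not silently repair.

**Noise scaling.** The target is 50 % explained variance per repeated measure
(R² = 0.50), configurable. Two dialects are exposed because the prose rule
("each repeated measure") and the published results pull in different
directions:

- `per_wave` (default): σ²_t = diag(ΛΨΛᵀ)_t · (1−R²)/R², so R² holds exactly
  at every wave. This dialect reproduces the published *linear*-condition
  statistics: across-replication fixed-effect SDs (0.118/0.069/0.045/0.036
  measured vs. 0.111/0.062/0.045/0.035 published for 2–5 waves) and the
  2-wave agreement ICC (0.282 vs. 0.28).
- `first_wave`: one constant σ² anchored to the wave-1 true-score variance.
  The published quadratic curvature-recovery medians (0.51/0.71/0.81 for
  4/5/6 waves) are *unattainable* under `per_wave` — the population
  factor-score determinacies, which upper-bound any estimator, are only
  0.35/0.52/0.64 there — but are approximately reproduced under `first_wave`
  (measured 0.45/0.75/0.88). The built-in quadratic condition therefore uses
  `first_wave`; the built-in linear conditions use `per_wave`. This is a
  calibration against the published numbers, stated openly; the switch is a
  first-class parameter for sensitivity analysis.

**Covariate W.** When requested, W is built from the in-sample standardized
factors plus an exactly orthogonalized residual so that its *sample*
correlations with the designated factors equal the targets exactly (default
r = 0.2 with the intercept, −0.1 with the slope). The augmented correlation
matrix must be positive definite or generation refuses. Note that W is exact
against the factors but not against the noise, so fitted W-correlations still
fluctuate at O(N^−1/2).

**Missingness overlays** (off by default, supplementary switches): `mcar`
masks cells independently at a given rate; `attrition` applies a per-wave
dropout hazard from wave 2 onward, monotone. Values are parameters, not
constants, because no canonical rates are printed.

## Models and estimation

Both models are mean-and-covariance structures μ(θ) = Λα,
Σ(θ) = ΛΨΛᵀ + Θ:

- **lcs2** — two-wave latent change score model: Λ = [[1,0],[1,1]] (level,
  latent difference), residuals fixed to 0. With two waves this model is
  just-identified (5 moments, 5 parameters); freeing residuals is not
  identified, and the fixed-zero choice matches the classic path diagram.
  The ML solution is the closed-form transform of the saturated moments:
  α̂ = (ȳ₁, mean difference), Ψ̂ = J S Jᵀ with J = [[1,0],[−1,1]], F = 0.
- **lcm** — latent curve model of degree 1 or 2, residual structure
  `free_per_wave` (default, matching the heteroscedastic generating noise),
  `equal_across_waves` (also the bridge to mixed-model software) or
  `fixed_zero`.

Estimation minimizes the normal-theory ML discrepancy
F = ln|Σ(θ)| − ln|S| + tr(SΣ(θ)⁻¹) − p + (ȳ−μ)ᵀΣ(θ)⁻¹(ȳ−μ) with an analytic
gradient, parameterizing Ψ by its Cholesky factor (hence Ψ̂ is positive
semi-definite by construction) and residual variances on the log scale.
L-BFGS-B runs first; if the gradient norm still exceeds 1e−6 a dense-BFGS
polish and then one jittered restart follow. Fits that remain above the
1e−6 gradient bar are flagged non-converged and excluded from aggregates
(with counts reported); at the built-in conditions none remain.

Numerical conventions worth knowing:

- The sample covariance uses divisor n−1 by default, consistent with the
  exact-moment generator (so noise-free exact-moment data are recovered
  *exactly*, F ≤ 1e−10). `cov_divisor="ml"` switches to divisor n, the
  textbook MLE, which matches lme4/MixedLM to numerical precision.
- A singular sample covariance is rejected as degenerate *unless* the panel
  is exactly factor-structured (zero projection residual), in which case the
  factor-space saturated fit is returned in closed form.
- A covariate is folded in as an extra latent with unit loading on its own
  indicator and zero residual; its covariances with all growth factors are
  free parameters of the augmented Cholesky block.
- Panels with a missingness mask are fit by pattern-wise full-information ML.

**Factor scores.** Default is the regression (empirical-Bayes) method,
η̂_i = α̂ + Ψ̂ΛᵀΣ̂⁻¹(y_i − μ̂); Bartlett scores are available whenever the
fitted residual variances are positive. For the just-identified lcs2 the
regression scores reduce exactly to (y₁, y₂ − y₁) per replicant — the raw
difference score.

## Recovery metrics

Per replication and model, estimated scores for the factor of interest (the
slope/difference; additionally curvature for the degree-2 fits) are compared
with the true generating values by

- Pearson correlation (rank/linear association only), and
- the two-way agreement intraclass correlation, average-measures form
  (MSR − MSE)/(MSR + (MSC − MSE)/n), which additionally penalizes mean and
  scale differences. The average-measures form is the default because it is
  the one consistent with the anchoring example (a +10 shift over 1..50
  gives 0.895; the single-measure form, also exposed, gives 0.810).

Aggregation reports per-model medians (of r, ICC, fixed estimates) and the
across-replication SD of the fixed estimate, over converged replications
only. Medians rather than means are the headline aggregate; full
distributions are retained in the tidy records table.

## Study conditions and ladder

Four built-in conditions, all 1000 replications at R² = 0.50: `linear_n200`,
`linear_n2000` (same population, N=2000), `quadratic_n200`, `covariate_n200`.
Each replication generates one sample; every ladder model is fit on the
*first* T waves of that same sample (within-sample comparison). The
quadratic ladder deliberately under-specifies the 2- and 3-wave entries as
degree-1 models — those designs cannot identify curvature — and scores them
against the true instantaneous linear slope; curvature recovery is reported
for 4+ waves only. Replications are seeded by a counter-based scheme
(master seed × replication index), so any single replication is regenerable
in isolation and results are bitwise reproducible.

## What the generator does and does not emulate

Passing tests show that the estimators behave correctly under the study's
idealized conditions: Gaussian noise, exactly known functional form, balanced
complete panels, zero sampling error in the generating moments. Real cohorts
violate all four (heavier-tailed noise, unknown functional form, missing
data, finite-population moments), and each violation degrades individual-
difference recovery further; the missingness and R² switches let users probe
those directions, but results here are best-case bounds, not forecasts.

## Known limitations

- The two-wave headline pair published for this design (median r = 0.41 with
  ICC = 0.28) cannot be produced jointly by any linear scoring of two-wave
  data in this framework: fixed-zero difference scores give r ≈ 0.30 with
  ICC ≈ 0.28, while shrinkage scores with residuals fixed at their
  generating values give r ≈ 0.45 with ICC ≈ 0.51. The default reproduces
  the ICC and the difference-score algebra; the correlation deviation is
  reported, not hidden.
- Under `first_wave` noise the quadratic curvature medians measure
  0.45/0.75/0.88 against the published 0.51/0.71/0.81: a flatter published
  profile than any constant- or proportional-noise dialect produces here.
  Our Ψ̂ is PSD by construction, whereas unconstrained SEM software admits
  improper solutions on minimally-identified fits, which plausibly shifts
  the 4-wave tail.
- Median recovery is not fully N-invariant for the minimally-identified
  3-wave model: estimated score weights at N=200 cost about 0.04 of median
  correlation relative to N=2000. All other ladder entries move ≤0.02.
- No fit indices, robust standard errors, bootstrap inference, categorical
  indicators, multi-group models, or individually-varying measurement
  occasions.
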