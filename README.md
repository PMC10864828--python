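# growthsim

Monte-Carlo parameter recovery for longitudinal growth models.

Developmental and epidemiological cohorts are often analyzed while data
collection is still under way, raising a practical question: **what can a
model fit to the first two or three waves of a longitudinal study tell you
about individual differences in change?** `growthsim` answers it by
simulation. It generates cohorts whose individual growth parameters
(intercept η₁, slope η₂, optionally curvature η₃) have *exactly* specified
population moments, fits the two-wave latent change score model (LCS) and
3+-wave latent curve models (LCM) by maximum likelihood, and measures how
well the fitted models recover both the fixed effect (the mean rate of
change α₂) and the individual parameter values.

The core objects are standard SEM mean-and-covariance structures,

    μ(θ) = Λα,     Σ(θ) = ΛΨΛᵀ + Θ,

with Λ the polynomial loading matrix over time codes 0…T−1 (or the unit-path
change-score structure [[1,0],[1,1]] for two waves), Ψ the growth-factor
covariance (individual differences) and Θ diagonal residual noise scaled so
each repeated measure carries 50 % explained variance. Recovery of
individual differences is scored per replication by the Pearson correlation
between factor scores and true parameters, and by the two-way agreement
ICC — which, unlike r, also penalizes errors in the mean and scale of the
recovered values (shift 1..50 by +10 and r stays 1.00 while the ICC drops to
0.895). An external variable W with fixed correlations to the growth factors
(r = 0.2 with intercept, −0.1 with slope) can be estimated simultaneously.

See `docs/methods.md` for the generating model, estimation details, and
known limitations.

## Worked example

```python
from growthsim import builtin_conditions, run_condition

cond = builtin_conditions()["linear_n200"]   # α=(3, 0.2), Ψ=[[1,.15],[.15,.25]], N=200
result = run_condition(cond, n_replications=1000, seed=1)
print(result.summary[["label", "median_fixed", "sd_fixed", "median_r", "median_icc2"]]
      .to_string(index=False))
```

```
 label  median_fixed  sd_fixed  median_r  median_icc2
lcs_2w      0.200577  0.117678  0.299471     0.282177
lcm_3w      0.199581  0.068644  0.565801     0.668184
lcm_4w      0.203229  0.045107  0.693534     0.787922
lcm_5w      0.200719  0.035959  0.768278     0.852053
```

Read it row by row: every design recovers the fixed effect (median ≈ 0.2,
the generating mean slope) without bias, but the two-wave model pays twice —
its fixed estimate varies almost twice as much from sample to sample
(SD 0.118 vs 0.069 at three waves), and its individual change scores
correlate with the true slopes at only r ≈ 0.30 in the median sample
(agreement ICC 0.28). Even the minimally-identified three-wave trajectory
model only reaches r ≈ 0.57; each added wave buys a substantial further
gain. Individual-difference questions, in short, need waves, not just
replicants: rerunning with `linear_n2000` leaves every median essentially
unchanged and only tightens the distributions.

The same interface runs from the shell:

```sh
growthsim list-conditions
growthsim run --condition quadratic_n200 --reps 200 --seed 7 --out-dir results/
growthsim summarize results/quadratic_n200_records.csv
```

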