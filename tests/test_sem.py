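"""Estimation contracts: implied moments, ML discrepancy, fits, factor scores."""

import json
import subprocess

import numpy as np
import pandas as pd
import pytest

from growthsim import (
    CohortSample,
    CovariateSpec,
    GrowthPopulation,
    ModelSpec,
    exact_moment_mvn,
    factor_scores,
    fit,
    fit_with_covariate,
    fml_discrepancy,
    generate_sample,
    implied_moments,
    loading_matrix,
)
from growthsim.sem import DegenerateSampleError, IdentificationError, _ParamMap


def _params(spec, alpha, psi, theta=None, time_codes=None):
    """Pack structural values into the flat parameter vector."""
    pm = _ParamMap(spec, time_codes)
    L = np.linalg.cholesky(np.asarray(psi, dtype=float) + 1e-15 * np.eye(pm.q))
    log_theta = np.log(theta) if theta is not None else np.empty(0)
    return pm.pack(np.asarray(alpha, dtype=float), L, log_theta)


def _noise_free_sample(pop, n=200, seed=0):
    eta = exact_moment_mvn(n, pop.alpha, pop.psi, seed=seed)
    lam = loading_matrix(pop.time_codes, pop.degree)
    return CohortSample(population=pop, true_factors=eta, observed=eta @ lam.T,
                        noise_variances=np.zeros(pop.n_waves))


class TestImpliedMoments:
    def test_linear_curve_mean_structure(self):
        spec = ModelSpec("lcm", 3, degree=1, residual_structure="free_per_wave")
        p = _params(spec, [3, 0.2], [[1, 0.15], [0.15, 0.25]], theta=[1e-8] * 3)
        mu, sigma = implied_moments(spec, p)
        assert np.allclose(mu, [3.0, 3.2, 3.4])
        lam = np.array([[1, 0], [1, 1], [1, 2]])
        assert np.allclose(sigma, lam @ [[1, 0.15], [0.15, 0.25]] @ lam.T, atol=1e-7)

    def test_change_score_mean_structure(self):
        spec = ModelSpec("lcs2", 2)
        p = _params(spec, [3, 0.2], np.eye(2))
        mu, _ = implied_moments(spec, p)
        assert np.allclose(mu, [3.0, 3.2])

    def test_pure_noise_covariance(self):
        spec = ModelSpec("lcm", 3, degree=1, residual_structure="free_per_wave")
        p = _params(spec, [0, 0], 1e-30 * np.eye(2), theta=[1.0] * 3)
        _, sigma = implied_moments(spec, p)
        assert np.allclose(sigma, np.eye(3))

    def test_dimension_mismatch_raises(self):
        spec = ModelSpec("lcm", 3, degree=1, residual_structure="free_per_wave")
        with pytest.raises(ValueError):
            implied_moments(spec, np.zeros(4))


class TestDiscrepancy:
    def test_saturated_match_is_zero(self):
        spec = ModelSpec("lcs2", 2)
        alpha = np.array([3.0, 0.2])
        psi = np.array([[1.0, 0.15], [0.15, 2.8]])
        p = _params(spec, alpha, psi)
        mu, sigma = implied_moments(spec, p)
        assert fml_discrepancy(spec, p, mu, sigma) == pytest.approx(0.0, abs=1e-10)

    def test_known_scalar_value_per_dimension(self):
        # Sigma = I against S = 2I with matched means: F = p (1 - ln 2),
        # the scalar ML discrepancy evaluated once per dimension
        spec = ModelSpec("lcs2", 2)
        psi = np.array([[1.0, -1.0], [-1.0, 2.0]])  # Lambda psi Lambda' = I
        p = _params(spec, [0.0, 0.0], psi)
        mu, sigma = implied_moments(spec, p)
        assert np.allclose(sigma, np.eye(2), atol=1e-12)
        f = fml_discrepancy(spec, p, mu, 2 * np.eye(2))
        assert f == pytest.approx(2 * (1 - np.log(2)), abs=1e-12)

    def test_nonnegative_with_matched_means(self):
        rng = np.random.default_rng(0)
        spec = ModelSpec("lcs2", 2)
        for _ in range(20):
            a = rng.standard_normal((2, 6))
            S = a @ a.T / 6
            psi = np.array([[1.0, 0.1], [0.1, 0.5]])
            p = _params(spec, [0.0, 0.0], psi)
            mu, _ = implied_moments(spec, p)
            assert fml_discrepancy(spec, p, mu, S) >= 0

    def test_singular_sample_cov_rejected(self):
        spec = ModelSpec("lcs2", 2)
        p = _params(spec, [0.0, 0.0], np.eye(2))
        with pytest.raises(DegenerateSampleError):
            fml_discrepancy(spec, p, np.zeros(2), np.ones((2, 2)))


class TestFit:
    def test_noise_free_recovery_is_exact(self, linear_pop):
        sample = _noise_free_sample(linear_pop, n=200, seed=1)
        fr = fit(ModelSpec("lcm", 5, degree=1, residual_structure="free_per_wave"),
                 sample)
        assert fr.converged
        assert fr.discrepancy <= 1e-10
        assert np.allclose(fr.alpha_hat, [3.0, 0.2], atol=1e-4)
        assert np.allclose(fr.psi_hat, linear_pop.psi, atol=1e-4)

    def test_lcs2_equals_difference_moments(self, linear_pop):
        sample = generate_sample(linear_pop, 200, seed=2)
        fr = fit(ModelSpec("lcs2", 2), sample)
        diff = sample.observed[:, 1] - sample.observed[:, 0]
        assert fr.alpha_hat[1] == pytest.approx(diff.mean(), abs=1e-6)
        assert fr.psi_hat[1, 1] == pytest.approx(diff.var(ddof=1), abs=1e-6)
        assert fr.discrepancy == pytest.approx(0.0, abs=1e-10)

    def test_moment_recovery_at_large_n(self, linear_pop):
        sample = generate_sample(linear_pop, 2000, seed=3)
        fr = fit(ModelSpec("lcm", 5, degree=1, residual_structure="free_per_wave"),
                 sample)
        assert fr.converged
        assert np.allclose(fr.alpha_hat, [3.0, 0.2], atol=0.05)
        assert np.allclose(fr.psi_hat, linear_pop.psi, atol=0.08)
        assert np.allclose(fr.theta_hat, [1.0, 1.55, 2.6, 4.15, 6.2], rtol=0.15)

    def test_implied_moments_recompute_from_estimates(self, linear_pop):
        sample = generate_sample(linear_pop, 200, seed=4)
        fr = fit(ModelSpec("lcm", 4, degree=1, residual_structure="free_per_wave"),
                 sample)
        lam = fr.loadings
        sigma = lam @ fr.psi_hat @ lam.T + np.diag(np.r_[fr.theta_hat])
        assert np.allclose(sigma, fr.implied_cov, atol=1e-10)
        assert np.allclose(lam @ fr.alpha_hat, fr.implied_mean, atol=1e-10)
        # psi_hat is PSD by the Cholesky parameterization
        assert np.linalg.eigvalsh(fr.psi_hat).min() >= -1e-12

    def test_identification_errors(self):
        with pytest.raises(IdentificationError):
            ModelSpec("lcm", 3, degree=2, residual_structure="free_per_wave")
        with pytest.raises(IdentificationError):
            ModelSpec("lcm", 2, degree=2, residual_structure="fixed_zero")
        with pytest.raises(IdentificationError):
            ModelSpec("lcs2", 3)
        # a ladder entry can also outrun the panel's waves
        spec = ModelSpec("lcm", 4, degree=1, residual_structure="free_per_wave")
        pop = GrowthPopulation("linear", [3, 0.2], [[1, 0.15], [0.15, 0.25]],
                               time_codes=[0, 1, 2])
        with pytest.raises(IdentificationError):
            fit(spec, generate_sample(pop, 50, seed=0))

    def test_scale_equivariance(self, linear_pop):
        sample = generate_sample(linear_pop, 200, seed=5)
        spec = ModelSpec("lcm", 4, degree=1, residual_structure="free_per_wave")
        fr1 = fit(spec, sample)
        c = 3.0
        scaled = CohortSample(population=linear_pop,
                              true_factors=sample.true_factors * c,
                              observed=sample.observed * c,
                              noise_variances=sample.noise_variances * c**2)
        fr2 = fit(spec, scaled)
        assert np.allclose(fr2.alpha_hat, c * fr1.alpha_hat, rtol=1e-4)
        assert np.allclose(fr2.psi_hat, c**2 * fr1.psi_hat, rtol=1e-3, atol=1e-5)
        assert np.allclose(fr2.theta_hat, c**2 * fr1.theta_hat, rtol=1e-3)
        s1 = factor_scores(fr1, spec, sample).scores[:, 1]
        s2 = factor_scores(fr2, spec, scaled).scores[:, 1]
        r1 = np.corrcoef(s1, sample.true_factors[:, 1])[0, 1]
        r2 = np.corrcoef(s2, scaled.true_factors[:, 1])[0, 1]
        assert r1 == pytest.approx(r2, abs=1e-6)

    def test_serializes_to_json(self, linear_pop):
        sample = generate_sample(linear_pop, 100, seed=6)
        fr = fit(ModelSpec("lcm", 3, degree=1, residual_structure="free_per_wave"),
                 sample)
        payload = json.loads(fr.to_json())
        assert payload["kind"] == "lcm"
        assert len(payload["alpha_hat"]) == 2
        assert payload["converged"] is True


class TestMixedModelOracle:
    def test_agrees_with_lme4_on_small_panels(self, linear_pop, tmp_path):
        """Equal-residual linear growth SEM is likelihood-identical to a
        random-intercept random-slope mixed model; the two ML fits must agree."""
        rows, ours = [], []
        for i in range(10):
            T = 3 + i % 3
            s = generate_sample(linear_pop, 40, seed=100 + i)
            fr = fit(ModelSpec("lcm", T, degree=1,
                               residual_structure="equal_across_waves"),
                     s, cov_divisor="ml")
            ours.append((fr.alpha_hat, fr.psi_hat, fr.theta_hat[0]))
            for pid in range(40):
                for t in range(T):
                    rows.append((i, pid, t, s.observed[pid, t]))
        pd.DataFrame(rows, columns=["panel", "id", "t", "y"]).to_csv(
            tmp_path / "panels.csv", index=False)
        script = tmp_path / "fit_lme4.R"
        script.write_text(f'''
suppressMessages(library(lme4))
d <- read.csv("{tmp_path / 'panels.csv'}")
out <- NULL
for (p in unique(d$panel)) {{
  dp <- d[d$panel == p,]
  m <- lmer(y ~ t + (t | id), data = dp, REML = FALSE,
            control = lmerControl(check.conv.singular = "ignore"))
  vc <- VarCorr(m)$id; fe <- fixef(m)
  out <- rbind(out, c(p, fe[1], fe[2], vc[1,1], vc[1,2], vc[2,2], sigma(m)^2))
}}
write.csv(as.data.frame(out), "{tmp_path / 'lme4_out.csv'}", row.names = FALSE)
''')
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "lme4_out.csv").to_numpy()
        for i, (a, P, th) in enumerate(ours):
            r = ref[ref[:, 0] == i][0]
            assert np.allclose(a, r[1:3], atol=1e-3)
            assert np.allclose([P[0, 0], P[0, 1], P[1, 1]], r[3:6], atol=1e-3)
            assert th == pytest.approx(r[6], abs=1e-3)


class TestFactorScores:
    def test_lcs2_scores_are_level_and_difference(self, linear_pop):
        sample = generate_sample(linear_pop, 100, seed=7)
        spec = ModelSpec("lcs2", 2)
        fr = fit(spec, sample)
        sc = factor_scores(fr, spec, sample).scores
        assert np.allclose(sc[:, 0], sample.observed[:, 0], atol=1e-8)
        assert np.allclose(sc[:, 1], sample.observed[:, 1] - sample.observed[:, 0],
                           atol=1e-8)

    def test_regression_scores_center_on_alpha(self, linear_pop):
        sample = generate_sample(linear_pop, 150, seed=8)
        spec = ModelSpec("lcm", 4, degree=1, residual_structure="free_per_wave")
        fr = fit(spec, sample)
        sc = factor_scores(fr, spec, sample).scores
        assert np.allclose(sc.mean(axis=0), fr.alpha_hat, atol=1e-8)

    def test_noise_free_scores_reproduce_true_factors(self, linear_pop):
        sample = _noise_free_sample(linear_pop, n=100, seed=9)
        spec = ModelSpec("lcm", 5, degree=1, residual_structure="free_per_wave")
        fr = fit(spec, sample)
        sc = factor_scores(fr, spec, sample).scores
        assert np.allclose(sc, sample.true_factors, atol=1e-6)

    def test_bartlett_requires_residual_variances(self, linear_pop):
        sample = generate_sample(linear_pop, 100, seed=10)
        spec = ModelSpec("lcs2", 2)
        fr = fit(spec, sample)
        with pytest.raises(ValueError):
            factor_scores(fr, spec, sample, method="bartlett")

    def test_bartlett_scores_are_unbiased_projections(self, linear_pop):
        sample = generate_sample(linear_pop, 2000, seed=11)
        spec = ModelSpec("lcm", 5, degree=1, residual_structure="free_per_wave")
        fr = fit(spec, sample)
        sc = factor_scores(fr, spec, sample, method="bartlett").scores
        # Bartlett scores = truth + independent noise, so regressing the
        # scores on the truth gives slope ~1 (conditional unbiasedness)
        slope = np.polyfit(sample.true_factors[:, 1], sc[:, 1], 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)


class TestCovariateModels:
    def test_recovers_w_correlations_at_large_n(self):
        # consistency check: the W-factor correlations are fixed in-sample,
        # but corr(W, noise) still fluctuates ~N^-1/2, so average a few fits
        pop = GrowthPopulation("linear", [3, 0.2], [[1, 0.15], [0.15, 0.25]],
                               covariate=CovariateSpec(r_intercept=0.2, r_slope=-0.1))
        spec = ModelSpec("lcm", 5, degree=1, residual_structure="free_per_wave",
                         include_covariate=True)
        est = np.array([fit(spec, generate_sample(pop, 2000, seed=s)).w_block["corr"]
                        for s in range(5)])
        assert est[:, 0].mean() == pytest.approx(0.2, abs=0.03)
        assert est[:, 1].mean() == pytest.approx(-0.1, abs=0.03)

    def test_independent_w_estimates_near_zero(self):
        pop = GrowthPopulation("linear", [3, 0.2], [[1, 0.15], [0.15, 0.25]],
                               covariate=CovariateSpec())
        sample = generate_sample(pop, 2000, seed=13)
        fr = fit_with_covariate(
            ModelSpec("lcm", 4, degree=1, residual_structure="free_per_wave"),
            sample)
        assert np.allclose(fr.w_block["corr"], 0.0, atol=0.05)

    def test_missing_w_rejected(self, linear_pop):
        sample = generate_sample(linear_pop, 100, seed=14)
        with pytest.raises(ValueError):
            fit_with_covariate(ModelSpec("lcm", 3, degree=1,
                                         residual_structure="free_per_wave"),
                               sample)


class TestMissingDataFit:
    def test_fiml_matches_complete_fit_without_missingness(self, linear_pop):
        from growthsim import impose_missingness
        sample = generate_sample(linear_pop, 200, seed=15)
        spec = ModelSpec("lcm", 4, degree=1, residual_structure="free_per_wave")
        fr_complete = fit(spec, sample)
        masked = impose_missingness(sample, "none")
        fr_masked = fit(spec, masked)
        assert np.allclose(fr_complete.alpha_hat, fr_masked.alpha_hat, atol=1e-8)
        assert not fr_masked.used_fiml

    def test_fiml_consistent_under_mcar(self, linear_pop):
        from growthsim import impose_missingness
        sample = generate_sample(linear_pop, 2000, seed=16)
        masked = impose_missingness(sample, "mcar", rate=0.2, seed=17)
        spec = ModelSpec("lcm", 4, degree=1, residual_structure="free_per_wave")
        fr = fit(spec, masked)
        assert fr.used_fiml
        assert np.allclose(fr.alpha_hat, [3.0, 0.2], atol=0.06)
        assert np.allclose(fr.psi_hat, linear_pop.psi, atol=0.1)
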