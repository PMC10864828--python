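"""Synthetic longitudinal cohorts with exactly specified growth-factor moments.

A cohort is generated in two stages.  First, per-individual growth factors
(intercept, slope and optionally curvature) are drawn multivariate-normal and
then transformed so that their *sample* mean and covariance equal the
population values exactly — the study design removes sampling variability in
the generating parameters so that differences between replications reflect
only measurement noise and estimation.  Second, observed repeated measures are
built as polynomial functions of time plus independent Gaussian noise scaled
so that each wave carries a target explained variance (R² = 0.50 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CovariateSpec",
    "GrowthPopulation",
    "CohortSample",
    "exact_moment_mvn",
    "loading_matrix",
    "true_score_variances",
    "add_noise",
    "sample_covariate",
    "impose_missingness",
    "generate_sample",
]

_FORM_DEGREE = {"linear": 1, "quadratic": 2}

#: noise-scaling dialects for the 50 %-explained-variance rule
NOISE_MODES = ("per_wave", "first_wave")


class NonPositiveDefiniteError(ValueError):
    """A covariance/correlation matrix required to be PD is not."""


class DegenerateSampleError(ValueError):
    """The requested sample cannot support the construction (e.g. n <= q)."""


@dataclass(frozen=True)
class CovariateSpec:
    """External variable W with fixed sample correlations to the growth factors.

    Correlations are imposed *exactly* in-sample, mirroring the exact-moment
    construction of the factors themselves.
    """

    r_intercept: float = 0.0
    r_slope: float = 0.0
    r_curvature: float = 0.0
    mean: float = 0.0
    variance: float = 1.0

    def r_vector(self, q: int) -> np.ndarray:
        r = np.array([self.r_intercept, self.r_slope, self.r_curvature])
        return r[:q]


@dataclass(frozen=True)
class GrowthPopulation:
    """The data-generating model for one simulation condition.

    Parameters
    ----------
    form:
        ``"linear"`` or ``"quadratic"`` trajectory.
    alpha:
        Factor means (length 2 for linear, 3 for quadratic), in units of the
        measured score.  The first time code is 0, so ``alpha[0]`` is the mean
        score at wave 1 and ``alpha[1]`` the mean instantaneous rate of change
        there.
    psi:
        Factor covariance matrix (individual differences), symmetric PD.
    time_codes:
        Measurement occasions; default ``0, 1, ..., T-1`` (unit spacing).
    r2_per_wave:
        Target explained variance of each repeated measure, in (0, 1).
    noise_mode:
        ``"per_wave"`` scales the noise variance to the true-score variance at
        every wave (R² holds at each wave); ``"first_wave"`` anchors a single
        constant noise variance to the wave-1 true-score variance.
    covariate:
        Optional external-variable specification.
    """

    form: str
    alpha: np.ndarray
    psi: np.ndarray
    time_codes: np.ndarray = None  # type: ignore[assignment]
    r2_per_wave: float = 0.50
    noise_mode: str = "per_wave"
    covariate: Optional[CovariateSpec] = None

    def __post_init__(self):
        if self.form not in _FORM_DEGREE:
            raise ValueError(f"unsupported trajectory form {self.form!r}")
        q = _FORM_DEGREE[self.form] + 1
        alpha = np.asarray(self.alpha, dtype=float)
        psi = np.asarray(self.psi, dtype=float)
        if alpha.shape != (q,):
            raise ValueError(f"alpha must have length {q} for form {self.form!r}")
        if psi.shape != (q, q):
            raise ValueError(f"psi must be {q}x{q} for form {self.form!r}")
        if not np.allclose(psi, psi.T, atol=1e-12):
            raise ValueError("psi must be symmetric")
        evals = np.linalg.eigvalsh(psi)
        if evals.min() <= 0:
            raise NonPositiveDefiniteError(
                f"psi is not positive definite (min eigenvalue {evals.min():.3e})"
            )
        tc = self.time_codes
        if tc is None:
            tc = np.arange(5.0 if self.form == "linear" else 6.0)
        tc = np.asarray(tc, dtype=float)
        if tc[0] != 0.0:
            raise ValueError("time_codes must start at 0 (anchors the intercept)")
        if np.any(np.diff(tc) <= 0):
            raise ValueError("time_codes must be strictly increasing")
        if len(tc) < q:
            raise ValueError("need at least degree+1 time codes")
        if not 0.0 < self.r2_per_wave < 1.0:
            raise ValueError("r2_per_wave must lie in (0, 1)")
        if self.noise_mode not in NOISE_MODES:
            raise ValueError(f"noise_mode must be one of {NOISE_MODES}")
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "psi", psi)
        object.__setattr__(self, "time_codes", tc)

    @property
    def degree(self) -> int:
        return _FORM_DEGREE[self.form]

    @property
    def n_factors(self) -> int:
        return self.degree + 1

    @property
    def n_waves(self) -> int:
        return len(self.time_codes)

    @property
    def psi_std(self) -> np.ndarray:
        """Correlation matrix implied by ``psi``."""
        d = np.sqrt(np.diag(self.psi))
        return self.psi / np.outer(d, d)

    @classmethod
    def from_config(cls, source) -> "GrowthPopulation":
        """Build a population from a YAML/JSON file path or a mapping.

        Keys: ``form``, ``alpha``, ``psi`` (full matrix or lower-triangle
        row-list), optional ``time_codes``, ``r2``, ``noise_mode``,
        ``covariate`` ({r_intercept, r_slope, ...}).
        """
        if isinstance(source, (str, Path)):
            text = Path(source).read_text()
            cfg = yaml.safe_load(text)  # YAML is a JSON superset
        else:
            cfg = dict(source)
        psi = _parse_psi(cfg["psi"])
        cov = cfg.get("covariate")
        return cls(
            form=cfg["form"],
            alpha=np.asarray(cfg["alpha"], dtype=float),
            psi=psi,
            time_codes=cfg.get("time_codes"),
            r2_per_wave=float(cfg.get("r2", 0.50)),
            noise_mode=cfg.get("noise_mode", "per_wave"),
            covariate=CovariateSpec(**cov) if cov else None,
        )


def _parse_psi(entry) -> np.ndarray:
    rows = [np.atleast_1d(np.asarray(r, dtype=float)) for r in entry]
    q = len(rows)
    if all(len(r) == q for r in rows):
        return np.asarray(rows, dtype=float)
    # lower-triangle row list, e.g. [[1], [0.15, 0.25]]
    psi = np.zeros((q, q))
    for i, r in enumerate(rows):
        if len(r) != i + 1:
            raise ValueError("psi rows must form a square matrix or lower triangle")
        psi[i, : i + 1] = r
    return psi + np.tril(psi, -1).T


@dataclass
class CohortSample:
    """One simulated balanced panel with known individual growth parameters."""

    population: GrowthPopulation
    true_factors: np.ndarray  # N x q
    observed: np.ndarray  # N x T
    noise_variances: np.ndarray  # length T
    w: Optional[np.ndarray] = None  # length N
    mask: Optional[np.ndarray] = None  # N x T bool, True = missing
    seed_record: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.true_factors.shape[0]

    @property
    def n_waves(self) -> int:
        return self.observed.shape[1]

    def to_wide_frame(self) -> pd.DataFrame:
        T = self.n_waves
        obs = self.observed.copy()
        if self.mask is not None:
            obs = np.where(self.mask, np.nan, obs)
        data = {"id": np.arange(self.n)}
        for t in range(T):
            data[f"y{t + 1}"] = obs[:, t]
        if self.w is not None:
            data["w"] = self.w
        return pd.DataFrame(data)

    def to_long_frame(self) -> pd.DataFrame:
        wide = self.to_wide_frame()
        ycols = [c for c in wide.columns if c.startswith("y")]
        long = wide.melt(
            id_vars=[c for c in wide.columns if c not in ycols],
            value_vars=ycols,
            var_name="wave",
            value_name="y",
        )
        long["wave"] = long["wave"].str.lstrip("y").astype(int)
        long["time"] = self.population.time_codes[long["wave"].to_numpy() - 1]
        order = ["id", "wave", "time", "y"] + (["w"] if self.w is not None else [])
        return long[order].sort_values(["id", "wave"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# generation primitives
# ---------------------------------------------------------------------------

def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def exact_moment_mvn(n: int, mean, cov, seed) -> np.ndarray:
    """Draw an n x q Gaussian sample whose *sample* moments equal (mean, cov).

    Raw normal deviates are demeaned, whitened with the inverse Cholesky
    factor of their own sample covariance (divisor n-1), recolored with the
    Cholesky factor of ``cov`` and shifted by ``mean``.  The result is
    Gaussian up to this moment-matching transform.
    """
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    q = len(mean)
    if cov.shape != (q, q):
        raise ValueError("mean/cov dimension mismatch")
    if not np.allclose(cov, cov.T, atol=1e-12):
        raise NonPositiveDefiniteError("cov must be symmetric")
    try:
        target_chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        evals = np.linalg.eigvalsh(cov)
        raise NonPositiveDefiniteError(
            f"cov is not positive definite (min eigenvalue {evals.min():.3e})"
        ) from exc
    if n <= q:
        raise DegenerateSampleError(
            f"need n > q for the whitening step (n={n}, q={q})"
        )
    rng = _rng(seed)
    raw = rng.standard_normal((n, q))
    raw -= raw.mean(axis=0)
    samp_cov = (raw.T @ raw) / (n - 1)
    white = raw @ np.linalg.inv(np.linalg.cholesky(samp_cov)).T
    return white @ target_chol.T + mean


def loading_matrix(time_codes, degree: int) -> np.ndarray:
    """Polynomial loading matrix: column j = time_codes ** j, j = 0..degree."""
    if degree not in (1, 2):
        raise ValueError(f"unsupported polynomial degree {degree}")
    t = np.asarray(time_codes, dtype=float)
    if len(t) < degree + 1:
        raise ValueError("need at least degree+1 occasions")
    return np.vander(t, degree + 1, increasing=True)


def true_score_variances(pop: GrowthPopulation, T: int) -> np.ndarray:
    """Per-wave variance of the noise-free trajectory: diag(Λ Ψ Λᵀ)."""
    if T > pop.n_waves:
        raise ValueError(f"T={T} exceeds the population's {pop.n_waves} occasions")
    lam = loading_matrix(pop.time_codes[:T], pop.degree)
    return np.einsum("ij,jk,ik->i", lam, pop.psi, lam)


def noise_variance_profile(pop: GrowthPopulation, T: Optional[int] = None) -> np.ndarray:
    """Per-wave residual variance implied by the R² rule and noise dialect."""
    T = pop.n_waves if T is None else T
    tsv = true_score_variances(pop, T)
    ratio = (1.0 - pop.r2_per_wave) / pop.r2_per_wave
    if pop.noise_mode == "per_wave":
        sigma2 = tsv * ratio
    else:  # first_wave: one constant variance anchored at wave 1
        sigma2 = np.full(T, tsv[0] * ratio)
    zero = tsv <= 0
    if np.any(zero) and pop.r2_per_wave < 1.0:
        warnings.warn(
            f"zero true-score variance at wave(s) {np.flatnonzero(zero) + 1}; "
            "noise variance set to 0 (degenerate wave)",
            stacklevel=2,
        )
        sigma2 = np.where(zero, 0.0, sigma2)
    return sigma2


def add_noise(true_scores: np.ndarray, pop: GrowthPopulation, seed):
    """Observed panel = Λ·factorsᵀ + Gaussian noise under the R² rule.

    Returns ``(observed, noise_variances)``.  Noise is drawn independently per
    cell; only the latent factors are moment-exact — the noise carries the
    sampling variability the study measures.
    """
    rng = _rng(seed)
    n, q = true_scores.shape
    T = pop.n_waves
    lam = loading_matrix(pop.time_codes, pop.degree)
    sigma2 = noise_variance_profile(pop)
    noise = rng.standard_normal((n, T)) * np.sqrt(sigma2)
    return true_scores @ lam.T + noise, sigma2


def sample_covariate(true_factors: np.ndarray, spec: CovariateSpec, pop: GrowthPopulation, seed) -> np.ndarray:
    """Draw W with *exact* sample correlations to the growth factors.

    The factors are standardized in-sample (their sample correlation matrix is
    exactly Ψstd by construction), W is built as the linear combination that
    realizes the target correlations plus an exactly-orthogonalized residual,
    so the augmented (η, W) sample correlation matrix equals the target
    exactly.  Raises if the augmented correlation matrix is not PD.
    """
    n, q = true_factors.shape
    r = spec.r_vector(q)
    R = pop.psi_std
    aug = np.empty((q + 1, q + 1))
    aug[:q, :q] = R
    aug[:q, q] = aug[q, :q] = r
    aug[q, q] = 1.0
    evals = np.linalg.eigvalsh(aug)
    if evals.min() <= 0:
        raise NonPositiveDefiniteError(
            "covariate correlations are incompatible with the factor "
            f"correlations (min eigenvalue of augmented matrix {evals.min():.3e})"
        )
    rng = _rng(seed)
    z = (true_factors - true_factors.mean(axis=0)) / np.sqrt(np.diag(pop.psi))
    lam = np.linalg.solve(R, r)
    c2 = 1.0 - r @ lam
    resid = rng.standard_normal(n)
    # regress the residual out of the factor space, exactly
    resid -= resid.mean()
    resid -= z @ np.linalg.lstsq(z, resid, rcond=None)[0]
    resid /= resid.std(ddof=1)
    w0 = z @ lam + np.sqrt(c2) * resid
    return spec.mean + np.sqrt(spec.variance) * w0


def impose_missingness(sample: CohortSample, mechanism: str = "none", rate: float = 0.0, seed=None) -> CohortSample:
    """Overlay a missingness mask on a complete sample.

    ``mcar`` masks cells independently at ``rate``; ``attrition`` applies a
    per-wave dropout hazard ``rate`` from wave 2 onward (monotone: once
    missing, missing at all later waves).
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    n, T = sample.observed.shape
    if mechanism == "none":
        mask = np.zeros((n, T), dtype=bool)
    elif mechanism == "mcar":
        mask = _rng(seed).random((n, T)) < rate
    elif mechanism == "attrition":
        drop = _rng(seed).random((n, T - 1)) < rate
        mask = np.zeros((n, T), dtype=bool)
        mask[:, 1:] = np.maximum.accumulate(drop, axis=1)
    else:
        raise ValueError(f"unknown missingness mechanism {mechanism!r}")
    out = replace(sample, mask=mask)
    out.seed_record = dict(sample.seed_record, missing_mechanism=mechanism, missing_rate=rate)
    return out


def generate_sample(pop: GrowthPopulation, n: int, seed: int,
                    missing_mechanism: str = "none", missing_rate: float = 0.0) -> CohortSample:
    """Generate one complete cohort sample (factors, noise, optional W).

    A single integer seed spawns independent child streams for the factors,
    the noise, the covariate and the missingness overlay, so the same seed
    always regenerates the identical sample.
    """
    ss = np.random.SeedSequence(seed)
    s_fac, s_noise, s_w, s_miss = [np.random.default_rng(c) for c in ss.spawn(4)]
    factors = exact_moment_mvn(n, pop.alpha, pop.psi, s_fac)
    observed, sigma2 = add_noise(factors, pop, s_noise)
    w = None
    if pop.covariate is not None:
        w = sample_covariate(factors, pop.covariate, pop, s_w)
    sample = CohortSample(
        population=pop,
        true_factors=factors,
        observed=observed,
        noise_variances=sigma2,
        w=w,
        seed_record={"seed": int(seed), "n": int(n)},
    )
    if missing_mechanism != "none":
        sample = impose_missingness(sample, missing_mechanism, missing_rate, s_miss)
    return sample
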