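"""Maximum-likelihood estimation of latent change score and latent curve models.

Both model families are mean-and-covariance structures on a balanced panel
y_i = (y_1 .. y_T) [, W]:

    mu(theta) = Lambda alpha          Sigma(theta) = Lambda Psi Lambda' + Theta

where Lambda is the fixed loading matrix (unit paths for the two-wave latent
change score model; polynomial time codes for the latent curve model), alpha
holds the factor means (fixed effects), Psi the factor covariance matrix
(individual differences) and Theta the diagonal residual covariance.  An
external covariate W is folded in as an extra "latent" with a unit loading on
its own indicator and zero residual, so its covariances with every growth
factor are free parameters of the augmented Psi.

Estimation minimizes the normal-theory ML discrepancy with an analytic
gradient, on an unconstrained parameterization (Cholesky factor for Psi, log
residual variances).  Per-individual factor scores are computed by the
regression (empirical Bayes) or Bartlett method.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .cohorts import CohortSample, loading_matrix

__all__ = [
    "ModelSpec",
    "FitResult",
    "FactorScores",
    "implied_moments",
    "fml_discrepancy",
    "fit",
    "fit_with_covariate",
    "factor_scores",
]

log = logging.getLogger("growthsim")

GRAD_TOL = 1e-6  #: convergence: max |gradient| at the optimum
_SINGULAR_TOL = 1e-10


class IdentificationError(ValueError):
    """The requested model is not identified by the available waves."""


class DegenerateSampleError(ValueError):
    """The sample covariance is singular and the panel is not factor-structured."""


@dataclass(frozen=True)
class ModelSpec:
    """A growth-model specification.

    ``kind="lcs2"`` is the two-wave latent change score model (level and
    latent difference, all structural paths fixed to 1, residuals fixed to
    zero — just-identified).  ``kind="lcm"`` is the latent curve model with
    polynomial degree 1 or 2.
    """

    kind: str  # "lcs2" | "lcm"
    waves_used: int
    degree: int = 1
    residual_structure: str = "free_per_wave"  # fixed_zero | free_per_wave | equal_across_waves
    include_covariate: bool = False

    def __post_init__(self):
        if self.kind == "lcs2":
            if self.waves_used != 2:
                raise IdentificationError("the two-wave change score model needs exactly 2 waves")
            object.__setattr__(self, "degree", 1)
            object.__setattr__(self, "residual_structure", "fixed_zero")
        elif self.kind == "lcm":
            if self.degree not in (1, 2):
                raise ValueError(f"unsupported degree {self.degree}")
            minimal = self.degree + 1
            if self.waves_used < minimal:
                raise IdentificationError(
                    f"degree-{self.degree} curve needs at least {minimal} waves"
                )
            if self.residual_structure == "free_per_wave" and self.waves_used < self.degree + 2:
                raise IdentificationError(
                    "free per-wave residuals need at least degree+2 waves"
                )
        else:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.residual_structure not in ("fixed_zero", "free_per_wave", "equal_across_waves"):
            raise ValueError(f"unknown residual structure {self.residual_structure!r}")

    @property
    def n_factors(self) -> int:
        return self.degree + 1

    @property
    def factor_names(self) -> tuple:
        if self.kind == "lcs2":
            return ("level", "delta")
        return ("intercept", "slope", "curvature")[: self.n_factors]

    def loadings(self, time_codes=None) -> np.ndarray:
        """Growth-factor loading matrix on the observed waves."""
        if self.kind == "lcs2":
            return np.array([[1.0, 0.0], [1.0, 1.0]])
        tc = np.arange(self.waves_used, dtype=float) if time_codes is None else np.asarray(time_codes, dtype=float)[: self.waves_used]
        return loading_matrix(tc, self.degree)


@dataclass
class FitResult:
    spec: ModelSpec
    alpha_hat: np.ndarray
    psi_hat: np.ndarray
    theta_hat: np.ndarray
    implied_mean: np.ndarray
    implied_cov: np.ndarray
    discrepancy: float
    converged: bool
    n_iter: int
    grad_norm: float
    n_obs: int
    w_block: Optional[dict] = None
    used_fiml: bool = False
    loadings: np.ndarray = None  # type: ignore[assignment]

    def to_json(self, **kwargs) -> str:
        payload = {
            "kind": self.spec.kind,
            "waves_used": self.spec.waves_used,
            "degree": self.spec.degree,
            "residual_structure": self.spec.residual_structure,
            "include_covariate": self.spec.include_covariate,
            "alpha_hat": self.alpha_hat.tolist(),
            "psi_hat": self.psi_hat.tolist(),
            "theta_hat": self.theta_hat.tolist(),
            "w_block": {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in self.w_block.items()} if self.w_block else None,
            "discrepancy": self.discrepancy,
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "grad_norm": self.grad_norm,
            "n_obs": int(self.n_obs),
            "used_fiml": self.used_fiml,
        }
        return json.dumps(payload, **kwargs)


@dataclass
class FactorScores:
    scores: np.ndarray  # N x q, columns follow spec.factor_names
    method: str
    factor_names: tuple

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=list(self.factor_names))
        df.insert(0, "id", np.arange(len(df)))
        return df


# ---------------------------------------------------------------------------
# parameter vector layout
# ---------------------------------------------------------------------------

class _ParamMap:
    """Pack/unpack (alpha, chol(Psi), log residual variances) <-> flat vector.

    With a covariate the latent vector is augmented: Lambda gains a row/column
    for W (unit loading, zero residual), Psi and alpha grow by one.
    """

    def __init__(self, spec: ModelSpec, time_codes=None):
        self.spec = spec
        q = spec.n_factors
        lam = spec.loadings(time_codes)
        if spec.include_covariate:
            q += 1
            T = lam.shape[0]
            aug = np.zeros((T + 1, q))
            aug[:T, : q - 1] = lam
            aug[T, q - 1] = 1.0
            lam = aug
        self.q = q
        self.lam = lam
        self.T_obs = lam.shape[0]
        self.T_waves = spec.waves_used
        self.tril = np.tril_indices(q)
        if spec.residual_structure == "fixed_zero":
            self.n_theta = 0
        elif spec.residual_structure == "equal_across_waves":
            self.n_theta = 1
        else:
            self.n_theta = self.T_waves
        self.n_params = q + len(self.tril[0]) + self.n_theta

    def unpack(self, params):
        params = np.asarray(params, dtype=float)
        if params.shape != (self.n_params,):
            raise ValueError(
                f"parameter vector has length {params.shape}, expected {self.n_params}"
            )
        q = self.q
        alpha = params[:q]
        L = np.zeros((q, q))
        L[self.tril] = params[q : q + len(self.tril[0])]
        theta = self.theta_diag(params)
        return alpha, L, theta

    def theta_diag(self, params) -> np.ndarray:
        """Residual variance per observed row (W row, if any, is 0)."""
        diag = np.zeros(self.T_obs)
        if self.n_theta == 1:
            diag[: self.T_waves] = np.exp(params[-1])
        elif self.n_theta > 1:
            diag[: self.T_waves] = np.exp(params[-self.n_theta:])
        return diag

    def pack(self, alpha, L, log_theta) -> np.ndarray:
        return np.concatenate([alpha, L[self.tril], log_theta])


def implied_moments(spec: ModelSpec, params, time_codes=None):
    """Model-implied (mean, covariance) of the observed vector."""
    pm = _ParamMap(spec, time_codes)
    alpha, L, theta = pm.unpack(params)
    psi = L @ L.T
    mu = pm.lam @ alpha
    sigma = pm.lam @ psi @ pm.lam.T + np.diag(theta)
    return mu, sigma


def fml_discrepancy(spec: ModelSpec, params, sample_mean, sample_cov, n: int = 0) -> float:
    """Normal-theory ML discrepancy F for a mean-and-covariance structure.

    F = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p + (ybar-mu)' Sigma^-1 (ybar-mu).
    Returns a large penalty when Sigma(theta) is numerically singular.
    """
    sample_mean = np.asarray(sample_mean, dtype=float)
    sample_cov = np.asarray(sample_cov, dtype=float)
    p = len(sample_mean)
    sign, logdet_s = np.linalg.slogdet(sample_cov)
    if sign <= 0:
        raise DegenerateSampleError("sample covariance is not positive definite")
    mu, sigma = implied_moments(spec, params)
    if mu.shape[0] != p:
        raise ValueError("sample moments do not match the model dimension")
    return _fml_core(mu, sigma, sample_mean, sample_cov, logdet_s)


def _fml_core(mu, sigma, ybar, S, logdet_s) -> float:
    p = len(ybar)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return 1e12
    inv = np.linalg.inv(sigma)
    d = ybar - mu
    return (
        2.0 * np.sum(np.log(np.diag(chol)))
        - logdet_s
        + np.trace(S @ inv)
        - p
        + d @ inv @ d
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _objective_complete(pm: _ParamMap, ybar, S, logdet_s):
    """F_ML and its analytic gradient on the unconstrained parameterization."""
    lam = pm.lam
    p = pm.T_obs

    def fun(params):
        alpha, L, theta = pm.unpack(params)
        psi = L @ L.T
        sigma = lam @ psi @ lam.T + np.diag(theta)
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return 1e12, np.zeros_like(params)
        inv = np.linalg.inv(sigma)
        mu = lam @ alpha
        d = ybar - mu
        inv_d = inv @ d
        f = (
            2.0 * np.sum(np.log(np.diag(chol)))
            - logdet_s
            + np.trace(S @ inv)
            - p
            + d @ inv_d
        )
        # dF/dSigma = inv (sigma - S - d d') inv   (symmetric)
        G = inv - inv @ (S + np.outer(d, d)) @ inv
        g_alpha = -2.0 * lam.T @ inv_d
        g_L = 2.0 * (lam.T @ G @ lam) @ L
        grad = [g_alpha, g_L[pm.tril]]
        if pm.n_theta == 1:
            theta_val = theta[0]
            grad.append(np.array([np.sum(np.diag(G)[: pm.T_waves]) * theta_val]))
        elif pm.n_theta > 1:
            grad.append(np.diag(G)[: pm.T_waves] * theta[: pm.T_waves])
        return f, np.concatenate(grad)

    return fun


def _objective_fiml(pm: _ParamMap, Y, patterns):
    """Pattern-wise full-information ML: mean deviance per observation.

    F = (1/N) sum_p n_p [ ln|Sigma_p| + tr(S_p Sigma_p^-1)
                          + (ybar_p - mu_p)' Sigma_p^-1 (ybar_p - mu_p) ].
    """
    lam = pm.lam
    N = Y.shape[0]

    def fun(params):
        alpha, L, theta = pm.unpack(params)
        psi = L @ L.T
        sigma_full = lam @ psi @ lam.T + np.diag(theta)
        mu_full = lam @ alpha
        f = 0.0
        G_full = np.zeros_like(sigma_full)
        gmu_full = np.zeros_like(mu_full)
        for obs_idx, rows in patterns:
            sub = np.ix_(obs_idx, obs_idx)
            sigma = sigma_full[sub]
            mu = mu_full[obs_idx]
            yb = Y[np.ix_(rows, obs_idx)]
            n_p = len(rows)
            ybar = yb.mean(axis=0)
            Sp = (yb - ybar).T @ (yb - ybar) / n_p
            try:
                chol = np.linalg.cholesky(sigma)
            except np.linalg.LinAlgError:
                return 1e12, np.zeros(pm.n_params)
            inv = np.linalg.inv(sigma)
            d = ybar - mu
            inv_d = inv @ d
            wt = n_p / N
            f += wt * (
                2.0 * np.sum(np.log(np.diag(chol)))
                + np.trace(Sp @ inv)
                + d @ inv_d
            )
            G = inv - inv @ (Sp + np.outer(d, d)) @ inv
            G_full[sub] += wt * G
            gmu_full[obs_idx] += wt * (-2.0 * inv_d)
        g_alpha = lam.T @ gmu_full
        g_L = 2.0 * (lam.T @ G_full @ lam) @ L
        grad = [g_alpha, g_L[pm.tril]]
        if pm.n_theta == 1:
            grad.append(np.array([np.sum(np.diag(G_full)[: pm.T_waves]) * theta[0]]))
        elif pm.n_theta > 1:
            grad.append(np.diag(G_full)[: pm.T_waves] * theta[: pm.T_waves])
        return f, np.concatenate(grad)

    return fun


def _observed_matrix(spec: ModelSpec, panel: CohortSample):
    T = spec.waves_used
    if T > panel.n_waves:
        raise IdentificationError(
            f"model needs {T} waves but the panel has {panel.n_waves}"
        )
    Y = panel.observed[:, :T]
    if spec.include_covariate:
        if panel.w is None:
            raise ValueError("include_covariate requires the panel to carry W")
        Y = np.column_stack([Y, panel.w])
    return np.asarray(Y, dtype=float)


def _start_values(pm: _ParamMap, Y, time_codes=None) -> np.ndarray:
    """OLS-trajectory starting values: moments of per-replicant least squares."""
    spec = pm.spec
    T = spec.waves_used
    lam_growth = spec.loadings(time_codes)
    eta_ols = Y[:, :T] @ np.linalg.pinv(lam_growth).T
    if spec.include_covariate:
        eta_ols = np.column_stack([eta_ols, Y[:, -1]])
    alpha0 = eta_ols.mean(axis=0)
    psi0 = np.cov(eta_ols, rowvar=False).reshape(pm.q, pm.q)
    psi0 = psi0 + 1e-3 * np.eye(pm.q)  # guard PD for the Cholesky start
    L0 = np.linalg.cholesky(psi0)
    if pm.n_theta == 0:
        log_theta = np.empty(0)
    else:
        v = np.maximum(0.5 * Y[:, :T].var(axis=0), 1e-4)
        log_theta = np.log(v if pm.n_theta > 1 else np.array([v.mean()]))
    return pm.pack(alpha0, L0, log_theta)


def _lcs2_closed_form(pm: _ParamMap, Y, ddof: int):
    """Just-identified two-wave change model: transform of the saturated moments.

    With unit paths and zero residuals, (level, delta) = (y1, y2 - y1); the ML
    estimates are the corresponding sample moments and F_ML is 0.
    """
    q = pm.q
    J = np.eye(q)
    J[1, 0] = -1.0  # delta row: y2 - y1 (covariate row, if any, untouched)
    ybar = Y.mean(axis=0)
    S = np.cov(Y, rowvar=False, ddof=ddof).reshape(q, q)
    alpha = J @ ybar
    psi = J @ S @ J.T
    return alpha, psi


def _factor_structured(Y, lam):
    """Exact factor solution if Y has no residual component, else None."""
    eta = Y @ np.linalg.pinv(lam).T
    resid = Y - eta @ lam.T
    if np.max(np.abs(resid)) < 1e-8:
        return eta
    return None


def fit(spec: ModelSpec, panel: CohortSample, seed: int = 0,
        cov_divisor: str = "unbiased") -> FitResult:
    """Estimate the model on the first ``spec.waves_used`` waves of ``panel``.

    Minimizes the ML discrepancy from OLS-trajectory starting values; declares
    convergence at max|gradient| <= 1e-6 and retries once from jittered starts
    otherwise.  Panels with a missingness mask are fit by pattern-wise
    full-information ML.

    ``cov_divisor`` selects the sample-covariance convention the discrepancy
    is applied to: ``"unbiased"`` (divisor n-1, consistent with the
    exact-moment generator) or ``"ml"`` (divisor n, the textbook MLE, matching
    mixed-model software).
    """
    if cov_divisor not in ("unbiased", "ml"):
        raise ValueError("cov_divisor must be 'unbiased' or 'ml'")
    ddof = 1 if cov_divisor == "unbiased" else 0
    tc = panel.population.time_codes
    pm = _ParamMap(spec, tc)
    Y = _observed_matrix(spec, panel)
    n = Y.shape[0]

    mask = panel.mask
    has_missing = mask is not None and bool(mask[:, : spec.waves_used].any())

    if not has_missing:
        ybar = Y.mean(axis=0)
        S = np.cov(Y, rowvar=False, ddof=ddof).reshape(pm.T_obs, pm.T_obs)
        sign, logdet_s = np.linalg.slogdet(S)
        singular = sign <= 0 or np.linalg.cond(S) > 1.0 / _SINGULAR_TOL

        if spec.kind == "lcs2" and not singular:
            alpha, psi = _lcs2_closed_form(pm, Y, ddof)
            return _finalize(pm, spec, alpha, psi, np.zeros(pm.T_obs), 0.0, True, 0, 0.0, n)

        if singular:
            eta = _factor_structured(Y, pm.lam)
            if eta is None:
                raise DegenerateSampleError(
                    "singular sample covariance and the panel is not exactly "
                    "factor-structured"
                )
            # noise-free panel: the factor-space saturated fit is exact
            alpha = eta.mean(axis=0)
            psi = np.cov(eta, rowvar=False, ddof=ddof).reshape(pm.q, pm.q)
            return _finalize(pm, spec, alpha, psi, np.zeros(pm.T_obs), 0.0, True, 0, 0.0, n)

        obj = _objective_complete(pm, ybar, S, logdet_s)
    else:
        if spec.kind == "lcs2":
            raise DegenerateSampleError(
                "the two-wave change model requires complete data on waves 1-2"
            )
        keep = ~mask[:, : spec.waves_used]
        if spec.include_covariate:
            keep = np.column_stack([keep, np.ones(n, dtype=bool)])
        pattern_codes = keep @ (1 << np.arange(keep.shape[1]))
        patterns = []
        for code in np.unique(pattern_codes):
            rows = np.flatnonzero(pattern_codes == code)
            obs_idx = np.flatnonzero(keep[rows[0]])
            if obs_idx.size == 0:
                continue
            patterns.append((obs_idx, rows))
        obj = _objective_fiml(pm, Y, patterns)

    x0 = _start_values(pm, Y, tc)
    res = minimize(obj, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-9})
    grad_norm = float(np.max(np.abs(res.jac)))
    if grad_norm > GRAD_TOL:
        # L-BFGS-B can stall on its ftol floor; a dense-Hessian polish
        # usually drives the gradient the last order of magnitude down
        res2 = minimize(obj, res.x, jac=True, method="BFGS",
                        options={"maxiter": 200, "gtol": 1e-8})
        if res2.fun <= res.fun or float(np.max(np.abs(res2.jac))) < grad_norm:
            res = res2
        grad_norm = float(np.max(np.abs(res.jac)))
    if grad_norm > GRAD_TOL:
        rng = np.random.default_rng(seed)
        x1 = res.x + rng.normal(scale=0.05, size=x0.shape)
        res2 = minimize(obj, x1, jac=True, method="L-BFGS-B",
                        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-9})
        if res2.fun < res.fun:
            res = res2
        grad_norm = float(np.max(np.abs(res.jac)))
        if grad_norm > GRAD_TOL:
            log.warning("fit did not converge (kind=%s, waves=%d, grad=%.2e)",
                        spec.kind, spec.waves_used, grad_norm)
    alpha, L, theta = pm.unpack(res.x)
    return _finalize(pm, spec, alpha, L @ L.T, theta, float(res.fun),
                     grad_norm <= GRAD_TOL, int(res.nit), grad_norm, n,
                     used_fiml=has_missing)


def _finalize(pm, spec, alpha_aug, psi_aug, theta_diag, f, converged, n_iter,
              grad_norm, n_obs, used_fiml=False) -> FitResult:
    mu = pm.lam @ alpha_aug
    sigma = pm.lam @ psi_aug @ pm.lam.T + np.diag(theta_diag)
    w_block = None
    q_growth = spec.n_factors
    if spec.include_covariate:
        cov_w = psi_aug[-1, :q_growth]
        sd = np.sqrt(np.abs(np.diag(psi_aug)))
        with np.errstate(divide="ignore", invalid="ignore"):
            corr_w = cov_w / (sd[:q_growth] * sd[-1])
        w_block = {
            "w_mean": float(alpha_aug[-1]),
            "w_variance": float(psi_aug[-1, -1]),
            "cov": cov_w.copy(),
            "corr": corr_w,
            "factor_names": spec.factor_names,
        }
    theta_hat = (np.empty(0) if spec.residual_structure == "fixed_zero"
                 else theta_diag[: spec.waves_used].copy())
    return FitResult(
        spec=spec,
        alpha_hat=alpha_aug[:q_growth].copy(),
        psi_hat=psi_aug[:q_growth, :q_growth].copy(),
        theta_hat=theta_hat,
        implied_mean=mu,
        implied_cov=sigma,
        discrepancy=f,
        converged=converged,
        n_iter=n_iter,
        grad_norm=grad_norm,
        n_obs=n_obs,
        w_block=w_block,
        used_fiml=used_fiml,
        loadings=pm.lam,
    )


def fit_with_covariate(spec: ModelSpec, panel: CohortSample, seed: int = 0) -> FitResult:
    """Fit the growth model and the W covariances simultaneously."""
    if panel.w is None:
        raise ValueError("panel carries no covariate W")
    if not spec.include_covariate:
        spec = ModelSpec(kind=spec.kind, waves_used=spec.waves_used,
                         degree=spec.degree,
                         residual_structure=spec.residual_structure,
                         include_covariate=True)
    return fit(spec, panel, seed=seed)


# ---------------------------------------------------------------------------
# factor scores
# ---------------------------------------------------------------------------

def factor_scores(fit_result: FitResult, spec: ModelSpec, panel: CohortSample,
                  method: str = "regression") -> FactorScores:
    """Per-replicant growth-factor estimates from a fitted model.

    regression (empirical Bayes):  eta_i = alpha + Psi Lambda' Sigma^-1 (y_i - mu)
    bartlett:  eta_i = alpha + (Lambda' Theta^-1 Lambda)^-1 Lambda' Theta^-1 (y_i - mu)
    """
    pm = _ParamMap(spec, panel.population.time_codes)
    Y = _observed_matrix(spec, panel)
    lam = pm.lam
    q_growth = spec.n_factors

    # reassemble the augmented (growth [+ W]) parameter blocks
    if spec.include_covariate:
        alpha = np.concatenate([fit_result.alpha_hat, [fit_result.w_block["w_mean"]]])
        psi = np.zeros((pm.q, pm.q))
        psi[:q_growth, :q_growth] = fit_result.psi_hat
        psi[-1, :q_growth] = psi[:q_growth, -1] = fit_result.w_block["cov"]
        psi[-1, -1] = fit_result.w_block["w_variance"]
    else:
        alpha = fit_result.alpha_hat
        psi = fit_result.psi_hat
    theta = np.zeros(pm.T_obs)
    if fit_result.theta_hat.size:
        theta[: spec.waves_used] = fit_result.theta_hat

    mu = lam @ alpha
    dev = Y - mu
    if method == "regression":
        sigma = lam @ psi @ lam.T + np.diag(theta)
        if np.linalg.cond(sigma) > 1.0 / _SINGULAR_TOL:
            weights = psi @ lam.T @ np.linalg.pinv(sigma)
        else:
            weights = psi @ lam.T @ np.linalg.inv(sigma)
        scores = alpha + dev @ weights.T
    elif method == "bartlett":
        if not fit_result.theta_hat.size or np.any(fit_result.theta_hat <= 0):
            raise ValueError(
                "Bartlett scores are undefined without positive residual variances"
            )
        inv_theta = 1.0 / theta[: spec.waves_used]
        lam_y = lam[: spec.waves_used, :q_growth]
        A = lam_y.T * inv_theta
        scores_growth = alpha[:q_growth] + dev[:, : spec.waves_used] @ np.linalg.solve(A @ lam_y, A).T
        scores = scores_growth
        return FactorScores(scores=scores, method=method, factor_names=spec.factor_names)
    else:
        raise ValueError(f"unknown factor score method {method!r}")
    return FactorScores(scores=scores[:, :q_growth], method=method,
                        factor_names=spec.factor_names)
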