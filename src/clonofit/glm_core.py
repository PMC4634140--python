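"""Self-contained numerical engine for quasi-Poisson and least-squares fits.

Implements the Poisson log-link generalized linear model with offset,
solved by iteratively reweighted least squares (IRLS), together with the
quasi-likelihood dispersion estimate, the nested-model ANOVA F-test, and
(weighted) ordinary least squares on log survival fractions.

Model, ML path
--------------
Colony counts y_i are Poisson with mean mu_i = exp(x_i' beta + o_i), the
offset o_i being log(cells seeded) (plus log plating efficiency when the
latter is held fixed).  IRLS solves the maximum-likelihood score equations
X'(y - mu) = 0.  Extra-Poisson variation between replicate experiments is
absorbed by the quasi-likelihood dispersion

    phi = Pearson chi^2 / (n - p),

and standard errors are scaled by sqrt(phi); phi ~ 1 indicates pure Poisson
scatter.  Nested models are compared by the F statistic

    F = [(D_reduced - D_full) / df_num] / phi_full,

with D the deviance and phi_full the dispersion of the richer model,
referred to F(df_num, n - p_full).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DesignSpec",
    "GLMFit",
    "LSFit",
    "NestedTest",
    "irls_poisson_log",
    "dispersion",
    "dispersion_test",
    "scaled_se",
    "f_test_nested",
    "ols_log",
    "wls_log",
    "f_test_nested_ls",
]


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix does not have full column rank."""


class UndefinedDispersionError(ValueError):
    """Dispersion requested on a fit with no residual degrees of freedom."""


@dataclass
class DesignSpec:
    """A fitting problem: design matrix, response, offset, optional weights.

    ``response`` holds counts for the ML path and log survival fractions for
    the LS path; ``offset`` enters the linear predictor with coefficient 1
    (zero for LS).  ``case_weights`` are used by weighted least squares only.
    """

    design_matrix: np.ndarray
    response: np.ndarray
    offset: np.ndarray | None = None
    case_weights: np.ndarray | None = None
    coefficient_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.design_matrix = np.asarray(self.design_matrix, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        n, p = self.design_matrix.shape
        if len(self.response) != n:
            raise ValueError("response length does not match design matrix")
        if self.offset is None:
            self.offset = np.zeros(n)
        self.offset = np.asarray(self.offset, dtype=float)
        if not np.all(np.isfinite(self.offset)):
            raise ValueError("offset must be finite")
        if self.case_weights is not None:
            self.case_weights = np.asarray(self.case_weights, dtype=float)
            if np.any(self.case_weights <= 0):
                raise ValueError("case weights must be positive")
        if n < p:
            raise RankDeficientError(f"more parameters ({p}) than records ({n})")
        if np.linalg.matrix_rank(self.design_matrix) < p:
            raise RankDeficientError("design matrix is rank deficient")
        if not self.coefficient_names:
            self.coefficient_names = [f"b{j}" for j in range(p)]

    @property
    def n(self) -> int:
        return self.design_matrix.shape[0]

    @property
    def p(self) -> int:
        return self.design_matrix.shape[1]


@dataclass
class GLMFit:
    """Result of a Poisson log-link IRLS fit."""

    coefficients: np.ndarray
    unscaled_covariance: np.ndarray
    deviance: float
    pearson_chi2: float
    df_residual: int
    fitted_means: np.ndarray
    converged: bool
    iterations: int
    spec: DesignSpec

    @property
    def dispersion(self) -> float:
        return dispersion(self)

    @property
    def coefficient_names(self) -> list[str]:
        return self.spec.coefficient_names

    def pearson_residuals(self) -> np.ndarray:
        return (self.spec.response - self.fitted_means) / np.sqrt(self.fitted_means)


@dataclass
class LSFit:
    """Result of an ordinary / weighted least-squares fit on log fractions."""

    coefficients: np.ndarray
    covariance: np.ndarray
    residual_ss: float
    total_ss: float
    df_residual: int
    fitted_values: np.ndarray
    spec: DesignSpec

    @property
    def r_squared(self) -> float:
        if self.total_ss == 0:
            return 1.0
        return 1.0 - self.residual_ss / self.total_ss

    @property
    def coefficient_names(self) -> list[str]:
        return self.spec.coefficient_names

    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))


@dataclass
class NestedTest:
    """ANOVA-type F comparison of a reduced model nested in a full model."""

    statistic: float
    df_num: int
    df_den: int
    p_value: float
    deviance_reduced: float
    deviance_full: float
    dispersion_used: float


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    # y = 0 terms contribute 2*mu (standard convention: y*log(y/mu) -> 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    return float(2.0 * np.sum(t - (y - mu)))


def irls_poisson_log(spec: DesignSpec, tol: float = 1e-8, max_iter: int = 25) -> GLMFit:
    """Fit the Poisson log-link GLM with offset by IRLS.

    Convergence is declared when the relative deviance change falls below
    ``tol``.  Starting values mu = y + 0.5 guard against zero counts.
    Non-convergence is flagged on the returned fit, not raised.
    """
    X, y, off = spec.design_matrix, spec.response, spec.offset
    if np.any(y < 0):
        raise ValueError("negative response in Poisson fit")
    if np.any(y != np.floor(y)):
        raise ValueError("Poisson response must be integer counts")

    mu = y + 0.5
    eta = np.log(mu)
    dev = _poisson_deviance(y, mu)
    beta = np.zeros(spec.p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = mu  # Poisson variance function; log link
        z = (eta - off) + (y - mu) / mu
        WX = X * w[:, None]
        xtwx = X.T @ WX
        beta = np.linalg.solve(xtwx, WX.T @ z)
        eta = X @ beta + off
        mu = np.exp(eta)
        dev_new = _poisson_deviance(y, mu)
        if abs(dev_new - dev) / (abs(dev_new) + 0.1) < tol:
            dev = dev_new
            converged = True
            break
        dev = dev_new

    xtwx = X.T @ (X * mu[:, None])
    cov = np.linalg.inv(xtwx)
    pearson = float(np.sum((y - mu) ** 2 / mu))
    return GLMFit(
        coefficients=beta,
        unscaled_covariance=cov,
        deviance=dev,
        pearson_chi2=pearson,
        df_residual=spec.n - spec.p,
        fitted_means=mu,
        converged=converged,
        iterations=it,
        spec=spec,
    )


def dispersion(fit: GLMFit) -> float:
    """Quasi-likelihood dispersion: Pearson chi^2 over residual d.f."""
    if fit.df_residual < 1:
        raise UndefinedDispersionError(
            "dispersion undefined: no residual degrees of freedom"
        )
    return fit.pearson_chi2 / fit.df_residual


def dispersion_test(fit: GLMFit) -> float:
    """Upper-tail chi^2 p-value for excess dispersion (H0: pure Poisson)."""
    if fit.df_residual < 1:
        raise UndefinedDispersionError(
            "dispersion test undefined: no residual degrees of freedom"
        )
    return float(stats.chi2.sf(fit.pearson_chi2, fit.df_residual))


def scaled_se(fit: GLMFit) -> np.ndarray:
    """Standard errors scaled by the square root of the dispersion."""
    return np.sqrt(np.diag(fit.unscaled_covariance) * dispersion(fit))


def _check_nested(n_red, n_full, df_red, df_full, y_red, y_full):
    if n_red != n_full or not np.array_equal(y_red, y_full):
        raise ValueError("nested test requires the same response vector")
    df_num = df_red - df_full
    if df_num < 1:
        raise ValueError("models are not strictly nested (df_num < 1)")
    return df_num


def f_test_nested(reduced: GLMFit, full: GLMFit) -> NestedTest:
    """ANOVA F-test between nested quasi-Poisson fits.

    The denominator dispersion is estimated from the full (richer) model.
    """
    df_num = _check_nested(
        reduced.spec.n, full.spec.n,
        reduced.df_residual, full.df_residual,
        reduced.spec.response, full.spec.response,
    )
    if not np.array_equal(reduced.spec.offset, full.spec.offset):
        raise ValueError("nested test requires the same offset")
    phi = dispersion(full)
    drop = max(reduced.deviance - full.deviance, 0.0)
    f = (drop / df_num) / phi
    p = float(stats.f.sf(f, df_num, full.df_residual))
    return NestedTest(
        statistic=float(f),
        df_num=df_num,
        df_den=full.df_residual,
        p_value=p,
        deviance_reduced=reduced.deviance,
        deviance_full=full.deviance,
        dispersion_used=phi,
    )


def _weighted_ls(spec: DesignSpec) -> LSFit:
    X, y = spec.design_matrix, spec.response - spec.offset
    if not np.all(np.isfinite(y)):
        raise ValueError(
            "non-finite response in least squares: exclude zero-colony plates "
            "or use the ML method"
        )
    w = spec.case_weights if spec.case_weights is not None else np.ones(spec.n)
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    rss = float(np.sum(w * resid**2))
    ybar = float(np.sum(w * y) / np.sum(w))
    tss = float(np.sum(w * (y - ybar) ** 2))
    df = spec.n - spec.p
    xtwx_inv = np.linalg.inv(X.T @ (X * w[:, None]))
    sigma2 = rss / df if df > 0 else np.nan
    return LSFit(
        coefficients=beta,
        covariance=sigma2 * xtwx_inv,
        residual_ss=rss,
        total_ss=tss,
        df_residual=df,
        fitted_values=fitted,
        spec=spec,
    )


def ols_log(spec: DesignSpec) -> LSFit:
    """Ordinary least squares on log survival fractions."""
    if spec.case_weights is not None:
        raise ValueError("use wls_log for weighted fits")
    return _weighted_ls(spec)


def wls_log(spec: DesignSpec) -> LSFit:
    """Weighted least squares on log survival fractions.

    Case weights are the observed colony counts: the delta-method Poisson
    variance of log y is 1/y, so weighting by y is inverse-variance
    weighting on the log scale.
    """
    if spec.case_weights is None:
        raise ValueError("wls_log requires case weights")
    return _weighted_ls(spec)


def f_test_nested_ls(reduced: LSFit, full: LSFit) -> NestedTest:
    """Classical ANOVA F-test on residual sums of squares of nested LS fits."""
    df_num = _check_nested(
        reduced.spec.n, full.spec.n,
        reduced.df_residual, full.df_residual,
        reduced.spec.response, full.spec.response,
    )
    drop = max(reduced.residual_ss - full.residual_ss, 0.0)
    s2 = full.residual_ss / full.df_residual
    f = (drop / df_num) / s2
    p = float(stats.f.sf(f, df_num, full.df_residual))
    return NestedTest(
        statistic=float(f),
        df_num=df_num,
        df_den=full.df_residual,
        p_value=p,
        deviance_reduced=reduced.residual_ss,
        deviance_full=full.residual_ss,
        dispersion_used=s2,
    )
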