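"""Quasi-Poisson log-linear model with population offset.

The monthly count y_t is modelled as overdispersed Poisson with

    log mu_t = b0 + bY * (year_t - center) + sum_M bM * I(month_t = M)
               + bU1 * u_t + bU2 * u_{t-1} + log(pop_t)

where the January month effect is fixed at zero, u is the unemployment
rate (%), and Var(y_t) = psi * mu_t.  Point estimates come from Poisson
maximum likelihood (quasi-likelihood estimates coincide); the dispersion
psi is estimated by the Pearson chi-square moment estimator and scales the
coefficient covariance.  When the Pearson estimate falls below 1 the
classical Poisson model is used instead (underdispersion is not modelled).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .panel_io import MonthCoord, MonthlyCountSeries, month_range

#: Design-matrix column names, in order.
COLUMNS = (
    "intercept",
    "year_centered",
    "month_2",
    "month_3",
    "month_4",
    "month_5",
    "month_6",
    "month_7",
    "month_8",
    "month_9",
    "month_10",
    "month_11",
    "month_12",
    "unemployment",
    "unemployment_lag1",
)

N_PARAMS = len(COLUMNS)

#: Relative singular-value threshold for declaring columns collinear.
RANK_TOL = 1e-8


class SingularDesignError(np.linalg.LinAlgError):
    """Design matrix is rank deficient."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_coefficients: np.ndarray):
        super().__init__(message)
        self.last_coefficients = last_coefficients


class DegreesOfFreedomError(ValueError):
    """Dispersion requested with n_obs <= n_params."""


@dataclass(frozen=True)
class ModelSpec:
    """Windows and fitting policy for the seasonal count model."""

    training_window: tuple[MonthCoord, MonthCoord]
    baseline_month: int = 1
    year_center: int = 2013
    dispersion_policy: str = "poisson_if_psi_below_1"
    nominal_level: float = 0.95

    def __post_init__(self) -> None:
        if self.baseline_month != 1:
            raise ValueError("the month baseline is fixed at January (month 1)")
        start, end = self.training_window
        if end < start:
            raise ValueError(f"training window end {end} precedes start {start}")


@dataclass
class DesignMatrix:
    """Rows of covariates with offset and response, ordered chronologically."""

    X: np.ndarray  # (n, 15)
    offset: np.ndarray  # log population, (n,)
    y: np.ndarray  # counts, (n,)
    coords: list[MonthCoord]
    year_center: int
    columns: tuple[str, ...] = COLUMNS

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_params(self) -> int:
        return self.X.shape[1]


@dataclass
class FitResult:
    """Fitted coefficients with dispersion-scaled covariance.

    ``covariance`` equals ``dispersion_used * unscaled_covariance`` where
    the unscaled part is (X' W X)^{-1} with W = diag(mu_hat).
    """

    coefficients: np.ndarray
    unscaled_covariance: np.ndarray
    dispersion_hat: float
    dispersion_used: float
    family_used: str
    converged: bool
    iterations: int
    n_obs: int
    n_params: int
    year_center: int
    columns: tuple[str, ...] = COLUMNS
    deviance_path: list[float] = field(default_factory=list)
    mu_hat: np.ndarray | None = None

    @property
    def covariance(self) -> np.ndarray:
        return self.dispersion_used * self.unscaled_covariance

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "coefficients": dict(zip(self.columns, map(float, self.coefficients))),
            "covariance": [[float(v) for v in row] for row in self.covariance],
            "dispersion_hat": self.dispersion_hat,
            "dispersion_used": self.dispersion_used,
            "family_used": self.family_used,
            "converged": self.converged,
            "iterations": self.iterations,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "year_center": self.year_center,
            "columns": list(self.columns),
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _design_rows(
    series: MonthlyCountSeries, coords: Sequence[MonthCoord], year_center: int
) -> tuple[np.ndarray, np.ndarray]:
    """Covariate rows and log-population offsets for the given months."""
    n = len(coords)
    X = np.zeros((n, N_PARAMS))
    offset = np.empty(n)
    for i, c in enumerate(coords):
        pos = series.position(c)
        X[i, 0] = 1.0
        X[i, 1] = c.year - year_center
        if c.month != 1:
            X[i, 1 + c.month - 1] = 1.0  # month m -> column index m (m >= 2)
        X[i, 13] = series.u_at(c)
        X[i, 14] = series.u_lag_at(c)
        offset[i] = np.log(series.population[pos])
    return X, offset


def build_design(
    series: MonthlyCountSeries,
    spec: ModelSpec,
    window: tuple[MonthCoord, MonthCoord] | None = None,
) -> DesignMatrix:
    """Build the training design matrix (response included).

    ``window`` defaults to the spec's training window; the series must
    cover it, and its unemployment series must cover one month before.
    """
    start, end = window if window is not None else spec.training_window
    n = end.months_since(start) + 1
    coords = month_range(start, n)
    try:
        positions = [series.position(c) for c in coords]
    except KeyError as e:
        raise ValueError(f"series does not cover the window: {e.args[0]}") from None
    X, offset = _design_rows(series, coords, spec.year_center)
    y = series.counts[positions].astype(np.int64)
    return DesignMatrix(
        X=X, offset=offset, y=y, coords=coords, year_center=spec.year_center
    )


def prediction_rows(
    series: MonthlyCountSeries, coords: Sequence[MonthCoord], year_center: int
) -> tuple[np.ndarray, np.ndarray]:
    """Covariate rows and offsets for held-out months (no response)."""
    return _design_rows(series, list(coords), year_center)


def poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def _check_rank(X: np.ndarray) -> None:
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[-1] < RANK_TOL * sv[0]:
        # name the columns involved in the near-null space
        _, _, vt = np.linalg.svd(X)
        null = np.abs(vt[-1])
        involved = [COLUMNS[i] for i in np.nonzero(null > 0.1)[0] if i < len(COLUMNS)]
        raise SingularDesignError(
            f"design matrix is rank deficient; collinear columns: {involved}"
        )


def fit_quasipoisson(
    design: DesignMatrix,
    spec: ModelSpec | None = None,
    *,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> FitResult:
    """Fit the log-linear count model by iteratively reweighted least squares.

    Convergence is declared when the relative change in Poisson deviance
    falls below ``tol``.  Steps that would increase the deviance are halved
    (up to 30 times), so the recorded deviance path is non-increasing.
    After fitting, the Pearson dispersion is estimated and the
    Poisson-fallback policy applied.
    """
    X, y, offset = design.X, design.y.astype(float), design.offset
    if np.any(y < 0):
        raise ValueError("response must be non-negative")
    _check_rank(X)

    # standard GLM start: working response from shrunk observed counts
    mu = y + np.mean(y) * 0.1 + 0.1
    eta = np.log(mu)  # on the full linear-predictor scale (offset included)
    beta = np.zeros(X.shape[1])
    deviance = np.inf  # first accepted step is never halved against the init
    path: list[float] = []
    converged = False
    iterations = 0
    for it in range(1, max_iter + 1):
        iterations = it
        mu = np.exp(eta)
        W = mu
        z = eta - offset + (y - mu) / mu
        WX = X * W[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            raise SingularDesignError(
                "weighted normal equations singular during IRLS"
            ) from None
        # step-halving keeps the deviance path monotone non-increasing
        step = beta_new - beta
        frac = 1.0
        for _ in range(30):
            cand = beta + frac * step
            dev_new = poisson_deviance(y, np.exp(X @ cand + offset))
            if np.isfinite(dev_new) and dev_new <= deviance + 1e-12:
                break
            frac *= 0.5
        beta = beta + frac * step
        eta = X @ beta + offset
        dev_new = poisson_deviance(y, np.exp(eta))
        path.append(dev_new)
        if abs(deviance - dev_new) < tol * (abs(dev_new) + 0.1):
            deviance = dev_new
            converged = True
            break
        deviance = dev_new
    if not converged:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations "
            f"(last deviance {deviance:.6g})",
            last_coefficients=beta,
        )

    mu = np.exp(X @ beta + offset)
    xtwx = X.T @ (X * mu[:, None])
    unscaled_cov = np.linalg.inv(xtwx)
    unscaled_cov = (unscaled_cov + unscaled_cov.T) / 2.0
    psi_hat = pearson_dispersion(design, mu)
    fit = FitResult(
        coefficients=beta,
        unscaled_covariance=unscaled_cov,
        dispersion_hat=psi_hat,
        dispersion_used=np.nan,
        family_used="",
        converged=converged,
        iterations=iterations,
        n_obs=design.n_obs,
        n_params=design.n_params,
        year_center=design.year_center,
        columns=design.columns,
        deviance_path=path,
        mu_hat=mu,
    )
    return apply_dispersion_policy(fit)


def pearson_dispersion(design: DesignMatrix, mu_hat: np.ndarray) -> float:
    """Pearson chi-square over residual degrees of freedom.

    psi_hat = sum_t (y_t - mu_t)^2 / mu_t / (n_obs - n_params).
    """
    mu_hat = np.asarray(mu_hat, dtype=float)
    if np.any(mu_hat <= 0):
        raise ValueError("fitted means must be strictly positive")
    dof = design.n_obs - design.n_params
    if dof <= 0:
        raise DegreesOfFreedomError(
            f"need n_obs > n_params for dispersion, got n={design.n_obs}, "
            f"p={design.n_params}"
        )
    chi2 = float(np.sum((design.y - mu_hat) ** 2 / mu_hat))
    return chi2 / dof


def apply_dispersion_policy(fit: FitResult) -> FitResult:
    """Fall back to the classical Poisson model when psi_hat < 1.

    "Less than 1" is read strictly: psi_hat == 1 stays quasi-Poisson.
    """
    if fit.dispersion_hat < 1.0:
        return replace(fit, family_used="poisson", dispersion_used=1.0)
    return replace(
        fit, family_used="quasipoisson", dispersion_used=float(fit.dispersion_hat)
    )


def predict_mean(
    fit: FitResult, new_design_rows: np.ndarray, new_offsets: np.ndarray
) -> np.ndarray:
    """Point predictions y_tilde = exp(x' beta_hat + offset)."""
    X = np.atleast_2d(np.asarray(new_design_rows, dtype=float))
    if X.shape[1] != len(fit.coefficients):
        raise ValueError(
            f"design rows have {X.shape[1]} columns, fit expects "
            f"{len(fit.coefficients)} ({fit.columns})"
        )
    offsets = np.asarray(new_offsets, dtype=float)
    return np.exp(X @ fit.coefficients + offsets)
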