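"""Simulation-based prediction intervals for held-out months.

Follows the Gelman–Hill simulation recipe: draw coefficient vectors from
the normal approximation to the posterior (mean = estimates, covariance =
psi * (X'WX)^{-1}, flat prior), push each draw through the inverse link to
a mean mu, then draw one count per coefficient draw — Poisson(mu) when the
dispersion is 1, otherwise gamma-Poisson (NB1) with gamma shape
mu / (psi - 1) and scale (psi - 1), whose marginal variance is psi * mu.
The interval is read off the order statistics of the count draws, so the
bounds are integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .glm_core import FitResult, predict_mean
from .panel_io import MonthCoord


class DecompositionError(np.linalg.LinAlgError):
    """Fit covariance is not positive semidefinite within tolerance."""


class PolicyViolationError(ValueError):
    """A dispersion below 1 reached the predictive sampler.

    The Poisson fallback must run before prediction, so dispersion_used
    is always >= 1 here.
    """


@dataclass(frozen=True)
class SimSettings:
    """Monte-Carlo settings for the predictive simulation."""

    seed: int
    n_draws: int = 10_000
    level: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError(f"level must be in (0,1), got {self.level}")
        if self.n_draws < 1:
            raise ValueError("n_draws must be positive")


@dataclass
class PredictionResult:
    """Point predictions and simulated interval bounds per held-out month."""

    coords: list[MonthCoord]
    predicted: np.ndarray  # y_tilde, point prediction from the estimates
    pi_lower: np.ndarray  # integer lower bounds
    pi_upper: np.ndarray  # integer upper bounds
    level: float
    n_draws: int
    seed: int
    count_draws: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": [c.year for c in self.coords],
                "month": [c.month for c in self.coords],
                "predicted": self.predicted,
                "pi_lower": self.pi_lower,
                "pi_upper": self.pi_upper,
                "level": self.level,
                "n_draws": self.n_draws,
                "seed": self.seed,
            }
        )


def draw_coefficients(
    fit: FitResult,
    settings: SimSettings,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n_draws`` coefficient vectors from N(beta_hat, covariance)."""
    cov = fit.covariance
    eig = np.linalg.eigvalsh(cov)
    if eig[0] < -1e-8 * max(eig[-1], 1.0):
        raise DecompositionError(
            f"fit covariance is not PSD (min eigenvalue {eig[0]:.3g})"
        )
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    return rng.multivariate_normal(
        fit.coefficients, cov, size=settings.n_draws, method="svd"
    )


def draw_predictive_counts(
    coef_draws: np.ndarray,
    new_design_row: np.ndarray,
    new_offset: float,
    dispersion_used: float,
    settings: SimSettings,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One predictive count per coefficient draw for a single month.

    Count given mu is Poisson(mu) at dispersion 1, else NB1 gamma-Poisson
    with Var = dispersion * mu.
    """
    if dispersion_used < 1.0:
        raise PolicyViolationError(
            f"dispersion_used={dispersion_used} < 1: the Poisson fallback "
            "must be applied before prediction"
        )
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    x = np.asarray(new_design_row, dtype=float)
    mu = np.exp(coef_draws @ x + new_offset)
    if dispersion_used == 1.0:
        return rng.poisson(mu)
    shape = mu / (dispersion_used - 1.0)
    lam = rng.gamma(shape=shape, scale=dispersion_used - 1.0)
    return rng.poisson(lam)


def prediction_interval(
    count_draws: Sequence[int] | np.ndarray, level: float
) -> tuple[int, int]:
    """Equal-tailed interval from order statistics of the count draws.

    lower is the k-th smallest draw with k = ceil((1-level)/2 * N) and
    upper the k-th smallest with k = ceil((1+level)/2 * N), 1-based.
    """
    draws = np.sort(np.asarray(count_draws))
    n = len(draws)
    if n == 0:
        raise ValueError("no predictive draws")
    # tiny epsilon guards the ceiling against float noise in (1-level)/2
    k_lo = max(1, math.ceil((1.0 - level) / 2.0 * n - 1e-9))
    k_hi = min(n, math.ceil((1.0 + level) / 2.0 * n - 1e-9))
    return int(draws[k_lo - 1]), int(draws[k_hi - 1])


def simulate_predictions(
    fit: FitResult,
    new_design_rows: np.ndarray,
    new_offsets: np.ndarray,
    coords: Sequence[MonthCoord],
    settings: SimSettings,
    keep_draws: bool = False,
) -> PredictionResult:
    """Full predictive simulation for a block of held-out months.

    One shared set of joint coefficient draws feeds every month, then each
    month gets its own predictive count draws; intervals are per month.
    """
    X = np.atleast_2d(np.asarray(new_design_rows, dtype=float))
    offsets = np.asarray(new_offsets, dtype=float)
    rng = np.random.default_rng(settings.seed)
    coef_draws = draw_coefficients(fit, settings, rng=rng)
    point = predict_mean(fit, X, offsets)
    lowers = np.empty(len(coords), dtype=np.int64)
    uppers = np.empty(len(coords), dtype=np.int64)
    all_draws = np.empty((len(coords), settings.n_draws), dtype=np.int64)
    for i in range(len(coords)):
        draws = draw_predictive_counts(
            coef_draws, X[i], float(offsets[i]), fit.dispersion_used, settings, rng=rng
        )
        all_draws[i] = draws
        lowers[i], uppers[i] = prediction_interval(draws, settings.level)
    return PredictionResult(
        coords=list(coords),
        predicted=point,
        pi_lower=lowers,
        pi_upper=uppers,
        level=settings.level,
        n_draws=settings.n_draws,
        seed=settings.seed,
        count_draws=all_draws if keep_draws else None,
    )


def write_predictions_csv(
    result: PredictionResult, path: str | Path, stratum_label: str = ""
) -> None:
    df = result.to_frame()
    if stratum_label:
        df.insert(0, "stratum", stratum_label)
    df.to_csv(path, index=False, float_format="%.6f")
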