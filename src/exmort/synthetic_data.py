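"""Synthetic monthly count panels with known generative truth.

The generator forward-simulates exactly the structure the analysis model
assumes: a log-linear year trend, twelve month effects (January fixed at
zero), unemployment effects at lag 0 and 1, a log-population offset, and
NB1 overdispersion Var(y) = psi * mu implemented as a gamma-Poisson
mixture.  The unemployment covariate is a stationary AR(1) around a
configured mean, with one leading month so the lag exists at t = 1.

Default parameters are shaped loosely like national monthly suicide
counts for one sex in 2010s Japan (roughly 1,000-1,900 deaths/month for
males, a declining year trend, mild spring-peaked seasonality, an
unemployment rate near 2.5-3%); the values are arbitrary and exist so
that synthetic output tables resemble real surveillance tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .glm_core import ModelSpec, build_design, fit_quasipoisson, prediction_rows
from .panel_io import MonthCoord, MonthlyCountSeries, PanelDataset, StratumKey, month_range
from .predictive_sim import SimSettings, simulate_predictions

MU_OVERFLOW = 1e9

#: Month effects for Feb..Dec (January = 0): mild spring peak, year-end dip.
DEFAULT_BETA_M = (0.00, 0.10, 0.08, 0.08, 0.04, 0.02, 0.00, 0.02, 0.00, -0.04, -0.10)


class SyntheticConfigError(ValueError):
    pass


@dataclass(frozen=True)
class UnemploymentProcess:
    """Stationary AR(1) for the unemployment rate, in percent."""

    mean: float = 2.7
    ar_coef: float = 0.8
    innovation_sd: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 <= self.ar_coef < 1.0:
            raise SyntheticConfigError(
                f"AR coefficient must be in [0,1), got {self.ar_coef}"
            )
        if self.innovation_sd < 0:
            raise SyntheticConfigError("innovation sd must be non-negative")


@dataclass(frozen=True)
class PandemicEffect:
    """Multiplicative shift on mu from ``cutoff`` onward (detection tests)."""

    cutoff: MonthCoord
    multiplier: float


@dataclass(frozen=True)
class SyntheticConfig:
    """True generative parameters for one stratum's series."""

    seed: int
    start: MonthCoord = MonthCoord(2013, 1)
    n_months: int = 90  # Jan 2013 .. Jun 2020
    beta0: float = -10.62  # log rate per person at center year, January
    betaY: float = -0.02  # per year
    betaM: tuple[float, ...] = DEFAULT_BETA_M  # Feb..Dec
    betaU1: float = 0.05  # per % unemployment, lag 0
    betaU2: float = 0.02  # per % unemployment, lag 1
    psi_true: float = 1.5
    population: float | tuple[float, ...] = 6.13e7  # persons
    unemployment: UnemploymentProcess = UnemploymentProcess()
    pandemic_effect: PandemicEffect | None = None
    year_center: int | None = None  # defaults to start.year

    def __post_init__(self) -> None:
        if self.psi_true < 1.0:
            raise SyntheticConfigError(f"psi_true must be >= 1, got {self.psi_true}")
        if len(self.betaM) != 11:
            raise SyntheticConfigError("betaM must give Feb..Dec (11 values)")
        if self.n_months < 1:
            raise SyntheticConfigError("n_months must be positive")

    @property
    def center(self) -> int:
        return self.year_center if self.year_center is not None else self.start.year

    def population_series(self) -> np.ndarray:
        if np.isscalar(self.population):
            return np.full(self.n_months, float(self.population))
        pop = np.asarray(self.population, dtype=float)
        if len(pop) != self.n_months:
            raise SyntheticConfigError(
                f"population sequence length {len(pop)} != n_months {self.n_months}"
            )
        return pop

    def month_effect(self, month: int) -> float:
        return 0.0 if month == 1 else float(self.betaM[month - 2])


@dataclass
class SyntheticSeries:
    """Generated series together with its recorded truth."""

    series: MonthlyCountSeries
    true_mu: np.ndarray
    config: SyntheticConfig
    n_unemployment_clips: int = 0


def generate_unemployment(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, int]:
    """AR(1) covariate of length n_months + 1 (one leading month).

    Initialized from the stationary distribution; values are clipped to
    [0, 100] and the number of clip events is returned alongside.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p = config.unemployment
    n = config.n_months + 1
    u = np.empty(n)
    if p.innovation_sd == 0.0:
        u.fill(p.mean)
        return u, 0
    stat_sd = p.innovation_sd / np.sqrt(1.0 - p.ar_coef**2)
    dev = rng.normal(0.0, stat_sd)
    for i in range(n):
        u[i] = p.mean + dev
        dev = p.ar_coef * dev + rng.normal(0.0, p.innovation_sd)
    clipped = int(np.sum((u < 0) | (u > 100)))
    np.clip(u, 0.0, 100.0, out=u)
    return u, clipped


def generate_counts(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    unemployment: np.ndarray | None = None,
) -> SyntheticSeries:
    """Forward-simulate one stratum's monthly counts.

    mu_t = pop_t * exp(beta0 + betaY*(year_t - center) + betaM(month_t)
    + betaU1*u_t + betaU2*u_{t-1}), times any pandemic multiplier; counts
    are Poisson(mu) at psi_true = 1, else NB1 gamma-Poisson with
    Var = psi * mu.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    clips = 0
    if unemployment is None:
        unemployment, clips = generate_unemployment(config, rng=rng)
    unemployment = np.asarray(unemployment, dtype=float)
    if len(unemployment) != config.n_months + 1:
        raise SyntheticConfigError(
            f"unemployment must have length n_months+1={config.n_months + 1}"
        )
    coords = month_range(config.start, config.n_months)
    pop = config.population_series()
    eta = np.array(
        [
            config.beta0
            + config.betaY * (c.year - config.center)
            + config.month_effect(c.month)
            + config.betaU1 * unemployment[i + 1]
            + config.betaU2 * unemployment[i]
            for i, c in enumerate(coords)
        ]
    )
    mu = pop * np.exp(eta)
    if config.pandemic_effect is not None:
        k = config.pandemic_effect.cutoff.months_since(config.start)
        if 0 <= k < config.n_months:
            mu[k:] *= config.pandemic_effect.multiplier
    if np.any(mu > MU_OVERFLOW):
        raise SyntheticConfigError(
            f"mu exceeds {MU_OVERFLOW:g}; check beta0/population scaling"
        )
    psi = config.psi_true
    if psi == 1.0:
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=mu / (psi - 1.0), scale=psi - 1.0)
        counts = rng.poisson(lam)
    series = MonthlyCountSeries(
        start=config.start,
        counts=counts,
        population=pop,
        unemployment=unemployment,
    )
    return SyntheticSeries(
        series=series, true_mu=mu, config=config, n_unemployment_clips=clips
    )


def default_panel_configs(seed: int, n_months: int = 90) -> dict[StratumKey, SyntheticConfig]:
    """Male and female national totals with distinct levels, shared window."""
    male = SyntheticConfig(seed=seed, n_months=n_months)
    female = replace(
        male,
        beta0=-11.83,  # ~470 deaths/month at 6.46e7 persons
        population=6.46e7,
        betaU1=0.03,
        betaU2=0.01,
    )
    return {
        StratumKey(sex="male"): male,
        StratumKey(sex="female"): female,
    }


def generate_panel(
    configs: dict[StratumKey, SyntheticConfig], seed: int
) -> tuple[PanelDataset, dict[StratumKey, np.ndarray]]:
    """Generate a multi-stratum panel sharing one unemployment series.

    Returns the panel and the per-stratum true means.
    """
    keys = sorted(configs)
    first = configs[keys[0]]
    master = np.random.SeedSequence(seed)
    u_ss, *count_ss = master.spawn(len(keys) + 1)
    unemployment, _ = generate_unemployment(
        first, rng=np.random.default_rng(u_ss)
    )
    series = {}
    truths = {}
    for key, child in zip(keys, count_ss):
        cfg = configs[key]
        if cfg.start != first.start or cfg.n_months != first.n_months:
            raise SyntheticConfigError("panel strata must share start and length")
        syn = generate_counts(
            cfg, rng=np.random.default_rng(child), unemployment=unemployment
        )
        series[key] = syn.series
        truths[key] = syn.true_mu
    panel = PanelDataset(
        series=series,
        unemployment=unemployment,
        start=first.start,
        n_months=first.n_months,
        metadata={"source": "synthetic", "seed": seed},
    )
    return panel, truths


def write_truth_csv(
    truths: dict[StratumKey, np.ndarray],
    configs: dict[StratumKey, SyntheticConfig],
    path: str | Path,
) -> None:
    """True means and coefficients alongside a generated panel."""
    rows = []
    for key in sorted(truths):
        cfg = configs[key]
        coords = month_range(cfg.start, cfg.n_months)
        for i, c in enumerate(coords):
            rows.append(
                {
                    "sex": key.sex,
                    "age_band": key.age_band,
                    "region": key.region,
                    "year": c.year,
                    "month": c.month,
                    "true_mu": truths[key][i],
                    "beta0": cfg.beta0,
                    "betaY": cfg.betaY,
                    "betaU1": cfg.betaU1,
                    "betaU2": cfg.betaU2,
                    "psi_true": cfg.psi_true,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def config_from_yaml(path: str | Path) -> SyntheticConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if "start" in raw:
        raw["start"] = MonthCoord.from_string(raw["start"])
    if "betaM" in raw:
        raw["betaM"] = tuple(raw["betaM"])
    if "unemployment" in raw:
        raw["unemployment"] = UnemploymentProcess(**raw["unemployment"])
    if raw.get("pandemic_effect"):
        pe = raw["pandemic_effect"]
        raw["pandemic_effect"] = PandemicEffect(
            cutoff=MonthCoord.from_string(pe["cutoff"]),
            multiplier=float(pe["multiplier"]),
        )
    return SyntheticConfig(**raw)


@dataclass
class RecoveryResult:
    """Per-replicate fit/prediction diagnostics from known-truth panels."""

    replicates: pd.DataFrame
    n_failures: int
    n_train: int
    n_test: int
    level: float

    def coverage(self) -> float:
        """Fraction of held-out true counts inside their intervals."""
        return float(
            self.replicates["n_covered"].sum()
            / (len(self.replicates) * self.n_test)
        )

    def summary(self) -> dict:
        reps = self.replicates
        n = len(reps)
        out = {
            "n_replicates": n,
            "n_failures": self.n_failures,
            "coverage": self.coverage(),
            "mean_bias_betaY": float(reps["betaY_err"].mean()),
            "mc_se_betaY": float(reps["betaY_err"].std(ddof=1) / np.sqrt(n)),
            "mean_bias_betaU1": float(reps["betaU1_err"].mean()),
            "mc_se_betaU1": float(reps["betaU1_err"].std(ddof=1) / np.sqrt(n)),
            "mean_psi_hat": float(reps["psi_hat"].mean()),
        }
        return out


def recovery_experiment(
    config: SyntheticConfig,
    n_replicates: int,
    settings: SimSettings,
    n_train: int = 86,
    n_test: int = 4,
) -> RecoveryResult:
    """Repeatedly generate, fit, and predict against known truth.

    Each replicate generates ``n_train + n_test`` months, fits the model
    on the training block, simulates prediction intervals for the
    held-out block, and records coefficient errors, the dispersion
    estimate, and whether each held-out (actually drawn) count fell
    inside its interval.  Fit failures are counted, never silently
    dropped.
    """
    if config.n_months < n_train + n_test:
        config = replace(config, n_months=n_train + n_test)
    master = np.random.SeedSequence(settings.seed)
    children = master.spawn(n_replicates)
    train_start = config.start
    train_end = train_start.add(n_train - 1)
    test_coords = month_range(train_start.add(n_train), n_test)
    model_spec = ModelSpec(
        training_window=(train_start, train_end), year_center=config.center
    )
    rows = []
    failures = 0
    for child in children:
        gen_ss, sim_ss = child.spawn(2)
        syn = generate_counts(config, rng=np.random.default_rng(gen_ss))
        sim_seed = int(sim_ss.generate_state(1)[0] % (2**31))
        try:
            design = build_design(syn.series, model_spec)
            fit = fit_quasipoisson(design, model_spec)
            X_new, offs = prediction_rows(syn.series, test_coords, config.center)
            pred = simulate_predictions(
                fit,
                X_new,
                offs,
                test_coords,
                SimSettings(
                    seed=sim_seed, n_draws=settings.n_draws, level=settings.level
                ),
            )
        except Exception:
            failures += 1
            continue
        held_out = np.array(
            [syn.series.counts[syn.series.position(c)] for c in test_coords]
        )
        inside = (held_out >= pred.pi_lower) & (held_out <= pred.pi_upper)
        rows.append(
            {
                "betaY_err": fit.coefficients[1] - config.betaY,
                "betaU1_err": fit.coefficients[13] - config.betaU1,
                "betaU2_err": fit.coefficients[14] - config.betaU2,
                "psi_hat": fit.dispersion_hat,
                "family_used": fit.family_used,
                "n_covered": int(inside.sum()),
                "n_below": int(np.sum(held_out < pred.pi_lower)),
                "n_above": int(np.sum(held_out > pred.pi_upper)),
            }
        )
    return RecoveryResult(
        replicates=pd.DataFrame(rows),
        n_failures=failures,
        n_train=n_train,
        n_test=n_test,
        level=settings.level,
    )
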